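gene	snp_id	polymorphism	population	n_cases	n_controls	or	reference
IL28RA	rs7525481	g.32349 G>A	Korean	267	559	0.74	Chae1
FCGR2A	rs1801274	R131R	Turkish	180	234	1.93	Gulen1
CD55 (DAF)	rs10746463		Japanese	684	346	0.73	Kawai1
CCR3	rs4987053	51T/C	Japanese	151	157	7.75	Nakamura1
IL2	rs2069762	-330T/G	German	318	322	1.29	Nieters1
IL13	rs1800925	C-1112T	Spanish	146	50	0.16	Llanes1
IL13	rs20541	R130Q	Spanish	146	50	1.52	Llanes1
HAVCR2	rs1036199	4259G>T	Korean	201	319	1.54	Chae2
CCL26	rs2302009	2497T>G	Korean	178	281	2.87	Chae3
CCL24	rs2302004	179T>C	Korean	178	281	1.10	Chae3
IL33	rs1929992		Japanese	170	100	1.41	Sakashita1
GATA3	rs1269486		Han Chinese	109	112	0.35	Zhang1
MS4A2	rs569108	Glu237Gly	Japanese	233	100	1.47	Nagata1
IL18	rs187238	-137G>C	Swiss	1105	2953	1.12	Imboden1
IL18	rs187238	-137C	German	25	80	2.72	Kruse1
RNASE3	rs2233860		Korean	440	478	1.36	Kang1
IL4R	rs1805010	Ile50Val	Japanese	145	206	0.62	Nakamura2
IL4R	rs1805011	Glu375Ala	Japanese	145	206	0.35	Nakamura2
NOD2	rs5743266		German	488	978	0.82	Weidinger1
NOD2	rs2066842		German	488	978	0.80	Weidinger1
NOD2	rs2066844	C2104T	German	154	1765	1.73	Kabesch1
NOD2	rs2066845	G2722C	German	154	1765	3.16	Kabesch1
CCL5	rs2280788	-28C/G	Korean	151	278	1.58	Kim1
CCL5	rs2107538	-403G/A	Korean	151	278	1.42	Kim1
EPX	rs2240815	3979A/G	Czech	294	319	1.28	Hrdlickova1
FOXJ1	rs3192453	g.3375G>C	Korean	295	418	0.62	Li1
FOXJ1	rs880213	g.-460C>T	Korean	295	418	0.64	Li1
ADAM33	rs2787094		Chinese Han	128	151	4.01	Su1
ADAM33	rs2280089	12540C/T	Japanese	95	95	0.32	Cheng1
ADAM33	rs2280089	12540C/T	Chinese Han	128	151	1.91	Su1
ADAM33	rs2280090	12462C/T	Japanese	95	95	0.28	Cheng1
ADAM33	rs2280090	12462C/T	Chinese Han	128	151	0.40	Su1
ADAM33	rs511898	7575G/A	Japanese	95	95	0.60	Cheng1
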