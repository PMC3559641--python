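# Methods

## Statistical model

The unit of analysis is one biallelic SNP in a case-control cohort.  Each
individual carries a minor-allele dosage `d ∈ {0, 1, 2}`; the minor allele
is defined by frequency in the combined case+control sample.  Cohorts that
arrive with the common allele coded are re-oriented per SNP (flagged
`recoded` in the results); at an exact 0.5 frequency tie the coded
orientation is kept, since dosage-coded data carry no allele labels to
break the tie lexicographically.

**Association.**  The allele-based test compares minor/major allele counts
(denominators `2N` per group) in a 2×2 Pearson χ² homogeneity test; the
genotype-based test uses the 2×3 genotype table.  All-zero rows/columns are
dropped before testing and the degrees of freedom adjust — rare homozygote
classes routinely vanish at cohort sizes in the hundreds, and erroring
there would make the scan brittle.  The Yates continuity correction is OFF
by default everywhere (the power simulation and its calibration tests use
the uncorrected statistic); it is exposed as a flag for 2×2 tables because
statistical environments differ in their default.

**Odds ratio.**  `OR = (minor_case · major_control)/(major_case ·
minor_control)` with the most common allele as referent, and a Woolf
log-scale CI, `exp(log OR ± z·√(Σ 1/cell))`.  A single empty cell triggers
the Haldane–Anscombe +0.5 on all cells (flagged); an empty row or column
leaves the OR undefined (missing, flagged) rather than inventing a number.

**Hardy–Weinberg.**  The 1-df χ² goodness-of-fit against `(q², 2pq, p²)`
with `p` the observed allele frequency.  This is the classical genotyping
quality check of the candidate-gene era; the exact test is deliberately out
of scope.  Monomorphic tables return statistic 0 / p 1 with a flag.

**SPT scores.**  Kruskal–Wallis across the (up to three) genotype groups
among individuals with a recorded score.  An all-tied input would divide by
zero in the tie correction; by convention it returns statistic 0 / p 1
(flagged), a degenerate but reachable case on small synthetic cohorts.

## Multiple testing and P-value diagnostics

Storey q-values: sort the m P-values, set `q(i) = min_{j≥i} π₀·m·p(j)/j`,
restore input order.  With `π₀ = 1` this is exactly Benjamini–Hochberg,
which the test suite uses as an oracle.  `π₀` comes from
`π₀(λ) = #{p > λ}/(m(1−λ))`, either at one fixed λ (default 0.5) or — the
default — as a cubic least-squares smoother of `π₀(λ)` over the grid
λ = 0.05, 0.10, …, 0.90, evaluated at the grid maximum.  The smoother is a
degree-3 polynomial fit; R's `smooth.spline(df = 3)` that the original
q-value software wraps is parameterised differently from scipy's smoothing
splines, and a cubic LS fit is the transparent equivalent at this grid
size.  Estimates are clipped to (0, 1], with a floor of `1/m` when the raw
estimate is nonpositive so heavily non-null inputs do not produce all-zero
q-values.

The bin table counts P-values in the ranges (0.1, 1], (0.05, 0.1],
(0.01, 0.05], (0.001, 0.01], [0, 0.001] — finer at the bottom, where
signal would live — against the uniform-null expectation `m × width`.
Bins are lower-open/upper-closed with the lowest closed at 0, so the five
default bins tile [0, 1] exactly and a boundary value such as p = 0.05
falls in (0.01, 0.05].  Expected counts are kept unrounded internally;
display rounding (round-half-up: nearest integer ≥ 10, one decimal ≥ 1,
two decimals below 1) is a separate renderer, chosen to match how such
tables are conventionally printed.

## Power engine

Power for a published OR is estimated by simulation at the allele level:
per replicate, case minor-allele counts `~ Binomial(2n_case, p₁)` with
`p₁ = OR·p₀/(1 − p₀ + OR·p₀)`, control counts `~ Binomial(2n_control,
p₀)`; the uncorrected 2×2 χ² is compared with the upper-tail critical
value (3.841 at α = 0.05, 10.828 at α = 0.001); power is the rejection
fraction.  Defaults: 10,000 replicates, α ∈ {0.05, 0.001}.  A replicate
whose table has an empty allele column gets the Haldane correction and is
still scored — redrawing would bias power upward at rare-allele
configurations.  Whether the original analyses simulated allele or
genotype counts is not knowable; allele-level is the minimal reading of a
power calculation "for the association tests of allele effects", and the
individual-level generator exists separately for cohort emulation.

A closed-form two-proportion z-test power (`analytic_power`, pooled SE
under the null, unpooled under the alternative) serves as an independent
oracle in tests only; simulation and closed form agree within 0.03
throughout the mid-power regime.

`expected_significant` treats per-SNP rejections as independent Bernoulli
trials: `E = Σ powerᵢ`, `SD = √(Σ powerᵢ(1−powerᵢ))`.

**MAF source precedence.**  Observed control MAFs are the right `p₀` when
available; the per-SNP precedence is explicit MAF table → cohort-estimated
control MAF → default `p₀ = 0.25`, a mid-range common-variant frequency.
Power at extreme ORs (≳ 4 or ≲ 0.3 at these sample sizes) is insensitive
to this choice — it saturates at 1.00 across the plausible MAF range —
which is why only such rows are used as reference points.  Low-power rows
depend strongly on the true MAFs and cannot be reproduced without them.
An explicit MAF entry of `None` (or a monomorphic 0/1) marks a SNP as
absent from that population and its power cells stay missing, mirroring
replication panels that drop non-polymorphic SNPs.

## Synthetic cohort generator

The generator emulates exactly the structure the analysis assumes: HWE
genotypes (dosage `~ Binomial(2, p)`, which is the HWE distribution
`(q², 2pq, p²)` on dosages 0/1/2) at `p₀` in controls and at the OR-shifted
`p₁` in cases; independent SNPs; SPT scores
`exp(Normal(baseline + shift·dosage, σ))` for cases only (controls are
SPT-negative by recruitment design).  Log-normal is one admissible choice
for a positive, right-skewed wheal-size ratio; only positivity and
right-skew are essential, and the Kruskal–Wallis analysis is rank-based, so
the family choice does not drive any downstream result.  The per-dosage
shift needs an anchoring SNP; the spec field defaults to the first SNP.

What the generator does **not** model: linkage disequilibrium between
SNPs, covariates (age, sex), population stratification, genotyping error,
or informative missingness.  Passing tests therefore demonstrate that the
pipeline is correct under its own assumptions — calibrated type-I error,
unbiased OR recovery, nominal CI coverage — not that those assumptions
hold in any real cohort.

**Reproducibility.**  One master seed; every SNP and every allergen draws
from a stream keyed by a SHA-256 hash of (seed, label), so the same SNP
gets the same genotypes regardless of catalog order, and identical specs
give byte-identical cohort files.  The power table derives one stream per
row the same way.

## Numerical and design choices

- χ² P-values come from the χ² upper tail at the adjusted df; no exact or
  permutation variants.
- Spearman correlation uses average ranks for ties and the two-sided
  t-approximation, except n ≤ 9 where the exact permutation distribution
  is enumerated (362,880 permutations at most).
- Sign concordance classifies a pair as concordant iff `(ORₐ−1)(OR_b−1) > 0`;
  a missing OR or an OR exactly 1 is excluded — the two defined classes are
  "both above 1" and "both below 1", and a null OR belongs to neither.
- The binomial sign test is the exact two-sided test at rate 0.5 (summing
  outcome probabilities not exceeding that of the observed count).
- Result tables render floats to 4 significant figures, P-values below
  1e-4 in scientific notation, missing values as `NA`; writers round only
  at the rendering step.

## Problem sizes used in the test suite

Calibration and coverage checks run at the replication cohorts' scale
where the property demands it (352/709 individuals for CI coverage, 500
cohorts; 10,000 replicates for power calibration) and at reduced scale
where the property is scale-free (e.g. 1,000 seeds for HWE calibration at
n = 200, 400 replicates for the SPT null).  The exhaustive χ² sweep covers
every 2×2 table with cells ≤ 6 and every 2×3 table with cells ≤ 3, plus a
randomized sweep of larger-margin tables against an independent
implementation.

## Known limitations

- Genotype-level (2×3) power, Kruskal–Wallis power and inverse power
  (sample-size solving) are not implemented.
- No covariate adjustment or genotype-model (dominant/recessive) ORs.
- π₀ estimation at small m (tens of tests) is noisy by nature; the fixed-λ
  method is more stable there and both are exposed.
- The packaged catalog records published ORs as printed; it does not
  attempt to recover the per-study MAFs, which were never published.
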