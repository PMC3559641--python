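"""Association statistics: chi-square tests, HWE, odds ratios, Kruskal-Wallis."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from scipy.stats.contingency import chi2_contingency

from snpreplicate import (
    CohortDataset,
    DegenerateTableError,
    SimulationSpec,
    SnpSpec,
    ValidationError,
    allele_table,
    chisq_homogeneity,
    hwe_chisq,
    kruskal_wallis,
    odds_ratio_ci,
    run_association,
    simulate_cohort,
)
from snpreplicate.catalog import GenotypeCountTable

from conftest import make_cohort_frame


def gct(group, a, b, c):
    return GenotypeCountTable(group, a, b, c)


class TestAlleleTable:
    def test_symmetric_counts(self):
        t = allele_table(gct("case", 10, 20, 10), gct("control", 10, 20, 10))
        np.testing.assert_array_equal(t, [[40, 40], [40, 40]])
        assert t[0].sum() == 80

    def test_monomorphic_control_group(self):
        t = allele_table(gct("case", 10, 20, 10), gct("control", 100, 0, 0))
        np.testing.assert_array_equal(t[1], [0, 200])

    def test_identical_rows_for_identical_genotypes(self):
        t = allele_table(gct("case", 25, 50, 25), gct("control", 25, 50, 25))
        np.testing.assert_array_equal(t[0], t[1])

    def test_zero_total_group_rejected(self):
        with pytest.raises(ValidationError):
            allele_table(gct("case", 0, 0, 0), gct("control", 1, 1, 1))


class TestChisqHomogeneity:
    def test_identical_proportions_give_zero(self):
        r = chisq_homogeneity([[30, 70], [30, 70]])
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # margins 40/160, expected 20/80 per row
        r = chisq_homogeneity([[30, 70], [10, 90]])
        assert r.statistic == pytest.approx(12.5)
        assert r.p_value == pytest.approx(0.000407, abs=1e-6)
        assert r.df == 1

    def test_zero_column_dropped_adjusts_df(self):
        r = chisq_homogeneity([[10, 20, 0], [15, 15, 0]])
        assert r.df == 1

    def test_degenerate_table_rejected(self):
        with pytest.raises(DegenerateTableError):
            chisq_homogeneity([[5, 5], [0, 0]])

    def test_yates_correction_only_on_2x2(self):
        plain = chisq_homogeneity([[12, 5], [6, 12]])
        corrected = chisq_homogeneity([[12, 5], [6, 12]], continuity_correction=True)
        assert corrected.statistic < plain.statistic
        ref = chi2_contingency(np.array([[12, 5], [6, 12]]), correction=True)
        assert corrected.statistic == pytest.approx(ref.statistic)
        # 2x3 tables are never corrected
        t3 = [[10, 5, 3], [4, 8, 9]]
        assert (
            chisq_homogeneity(t3, continuity_correction=True).statistic
            == pytest.approx(chisq_homogeneity(t3).statistic)
        )

    def test_exhaustive_small_2x2_matches_scipy(self):
        for cells in itertools.product(range(7), repeat=4):
            table = np.array(cells).reshape(2, 2)
            if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
                continue
            ref = chi2_contingency(table, correction=False)
            r = chisq_homogeneity(table)
            assert r.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert r.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_exhaustive_small_2x3_matches_scipy(self):
        for cells in itertools.product(range(4), repeat=6):
            table = np.array(cells).reshape(2, 3)
            kept = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
            if kept.shape[0] < 2 or kept.shape[1] < 2:
                continue
            ref = chi2_contingency(kept, correction=False)
            r = chisq_homogeneity(table)
            assert r.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert r.df == (kept.shape[0] - 1) * (kept.shape[1] - 1)

    def test_random_larger_margins_match_scipy(self):
        rng = np.random.default_rng(17)
        for _ in range(300):
            table = rng.integers(0, 51, size=(2, 2))
            if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
                continue
            ref = chi2_contingency(table, correction=False)
            assert chisq_homogeneity(table).statistic == pytest.approx(
                ref.statistic, abs=1e-9
            )


class TestHweChisq:
    def test_exact_hwe_at_half(self):
        r = hwe_chisq(gct("case", 25, 50, 25))
        assert r.statistic == pytest.approx(0.0)
        assert r.p_value == pytest.approx(1.0)

    def test_hand_computed_departure(self):
        # p_hat = 0.5, expected 25/50/25
        r = hwe_chisq(gct("case", 30, 40, 30))
        assert r.statistic == pytest.approx(4.0)
        assert r.p_value == pytest.approx(0.0455, abs=1e-4)

    def test_monomorphic_flagged(self):
        r = hwe_chisq(gct("control", 100, 0, 0))
        assert "monomorphic" in r.flags
        assert r.statistic == 0.0
        assert r.p_value == 1.0


class TestOddsRatioCI:
    def test_cross_product(self):
        or_, lo, hi, flags = odds_ratio_ci([[20, 80], [10, 90]])
        assert or_ == pytest.approx(2.25)
        assert lo < or_ < hi
        assert flags == ()

    def test_null_table(self):
        or_, lo, hi, _ = odds_ratio_ci([[50, 50], [50, 50]])
        assert or_ == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_haldane_correction_on_zero_cell(self):
        or_, lo, hi, flags = odds_ratio_ci([[0, 100], [10, 90]])
        assert "haldane" in flags
        assert or_ == pytest.approx((0.5 * 90.5) / (100.5 * 10.5))

    def test_zero_line_undefined(self):
        or_, lo, hi, flags = odds_ratio_ci([[0, 0], [10, 90]])
        assert or_ is None and lo is None and hi is None
        assert "undefined" in flags

    @given(
        a=st.integers(1, 60),
        b=st.integers(1, 60),
        c=st.integers(1, 60),
        d=st.integers(1, 60),
    )
    @settings(max_examples=200, deadline=None)
    def test_swapping_rows_inverts_or_and_reflects_ci(self, a, b, c, d):
        or1, lo1, hi1, _ = odds_ratio_ci([[a, b], [c, d]])
        or2, lo2, hi2, _ = odds_ratio_ci([[c, d], [a, b]])
        assert or2 == pytest.approx(1 / or1)
        assert lo2 == pytest.approx(1 / hi1)
        assert hi2 == pytest.approx(1 / lo1)

    def test_ci_level_widens_interval(self):
        _, lo95, hi95, _ = odds_ratio_ci([[20, 80], [10, 90]], level=0.95)
        _, lo99, hi99, _ = odds_ratio_ci([[20, 80], [10, 90]], level=0.99)
        assert lo99 < lo95 and hi99 > hi95


class TestKruskalWallis:
    def test_hand_computed_no_ties(self):
        # H = 12/(n(n+1)) * sum(R_j^2/n_j) - 3(n+1)
        #   = 12/42 * (9/2 + 49/2 + 121/2) - 21 = 32/7
        r = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
        assert r.statistic == pytest.approx(32 / 7)
        assert r.p_value == pytest.approx(sps.chi2.sf(32 / 7, 2), abs=1e-10)
        assert r.df == 2

    def test_all_tied_returns_zero(self):
        r = kruskal_wallis([[2.0, 2.0], [2.0], [2.0, 2.0]])
        assert r.statistic == 0.0
        assert r.p_value == 1.0
        assert "all-tied" in r.flags

    def test_empty_group_drops_df(self):
        r = kruskal_wallis([[1, 2, 5], [], [3, 4, 6]])
        assert r.df == 1

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(DegenerateTableError):
            kruskal_wallis([[1, 2, 3], []])

    @given(
        st.lists(
            st.lists(st.integers(-500, 500), min_size=2, max_size=6, unique=True),
            min_size=2,
            max_size=3,
        )
    )
    @settings(max_examples=100, deadline=None)
    def test_invariant_under_monotone_transform(self, int_groups):
        # integer lattice /10 keeps values exactly distinct under exp
        groups = [[x / 10 for x in g] for g in int_groups]
        flat = [x for g in groups for x in g]
        if len(set(flat)) < 2:
            return
        transformed = [[np.exp(x / 25) for x in g] for g in groups]
        r1 = kruskal_wallis(groups)
        r2 = kruskal_wallis(transformed)
        assert r1.statistic == pytest.approx(r2.statistic, rel=1e-9)


class TestRunAssociation:
    def test_null_cohort_type_one_error(self):
        # 49 null SNPs x 25 cohorts: allele-test rejection rate ~5%
        p_values = []
        for seed in range(25):
            spec = SimulationSpec(
                n_case=150,
                n_control=150,
                snps=tuple(SnpSpec(f"rs{i}", 0.3, 1.0) for i in range(49)),
                seed=seed,
            )
            results = run_association(simulate_cohort(spec))
            p_values += [r.p_allele for r in results if r.p_allele is not None]
        rate = np.mean([p < 0.05 for p in p_values])
        se = np.sqrt(0.05 * 0.95 / len(p_values))
        assert rate == pytest.approx(0.05, abs=3 * se)

    def test_monomorphic_snp_flagged_not_tested(self):
        frame = make_cohort_frame(
            n_case=3,
            n_control=3,
            dosages={"rs_poly": [0, 1, 2, 0, 1, 0], "rs_mono": [0, 0, 0, 0, 0, 0]},
        )
        results = run_association(CohortDataset(frame))
        by_id = {r.snp_id: r for r in results}
        assert "monomorphic" in by_id["rs_mono"].flags
        assert by_id["rs_mono"].p_allele is None
        assert by_id["rs_poly"].p_allele is not None

    def test_strong_effect_detected(self):
        spec = SimulationSpec(
            n_case=352, n_control=709, snps=(SnpSpec("rs1", 0.25, 7.75),), seed=3
        )
        results = run_association(simulate_cohort(spec))
        assert results[0].p_allele < 0.001

    def test_major_coded_snp_recoded_to_minor(self):
        # dosages code the common allele: MAF must still be the minor frequency
        frame = make_cohort_frame(
            n_case=3,
            n_control=3,
            dosages={"rs1": [2, 2, 1, 2, 1, 2]},
        )
        results = run_association(CohortDataset(frame))
        assert "recoded" in results[0].flags
        assert results[0].maf_case <= 0.5 and results[0].maf_control <= 0.5

    def test_ci_brackets_or(self, simulated_cohort):
        results = run_association(simulated_cohort)
        for r in results:
            if r.or_minor is not None:
                assert r.ci_low <= r.or_minor <= r.ci_high

    def test_spt_pvalue_present_for_effect_snp(self, simulated_cohort):
        by_id = {r.snp_id: r for r in run_association(simulated_cohort)}
        assert "birch" in by_id["rs_effect"].p_spt
        assert 0 <= by_id["rs_effect"].p_spt["birch"] <= 1

    def test_needs_cases_and_controls(self):
        frame = make_cohort_frame(n_case=4, n_control=0, dosages={"rs1": [0, 1, 2, 1]})
        with pytest.raises(ValidationError):
            run_association(CohortDataset(frame))
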