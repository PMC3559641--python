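"""Per-SNP association statistics for case-control cohorts.

Implements the classical toolkit of candidate-gene association studies:

* chi-square homogeneity test on allele (2x2) and genotype (2x3) count
  tables, with optional Yates continuity correction for 2x2 tables;
* Hardy-Weinberg equilibrium 1-df chi-square per group;
* minor-allele odds ratio with Woolf (log-scale) confidence interval and
  Haldane-Anscombe correction when a cell is empty;
* Kruskal-Wallis rank test of quantitative skin-prick-test scores across
  genotype groups.

Zero-count rows/columns are dropped before homogeneity testing (degrees of
freedom adjust), mirroring how rare homozygote classes vanish at realistic
sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .catalog import CohortDataset, GenotypeCountTable
from .errors import DegenerateTableError, ValidationError


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.p_value <= 1:
            raise ValidationError(f"p-value outside [0,1]: {self.p_value}")
        if self.statistic < 0:
            raise ValidationError(f"negative test statistic: {self.statistic}")


@dataclass(frozen=True)
class AssociationResult:
    """Per-SNP association summary (one row of the study's result table)."""

    snp_id: str
    maf_case: float | None
    maf_control: float | None
    p_allele: float | None
    p_genotype: float | None
    or_minor: float | None
    ci_low: float | None
    ci_high: float | None
    hwe_p_case: float | None
    hwe_p_control: float | None
    p_spt: dict = field(default_factory=dict)
    flags: tuple[str, ...] = ()


def allele_table(
    case_counts: GenotypeCountTable, control_counts: GenotypeCountTable
) -> np.ndarray:
    """Collapse genotype counts to a 2x2 allele table.

    Rows (case, control), columns (minor, major); each group contributes
    2 * genotype total alleles.
    """
    for t in (case_counts, control_counts):
        if t.n_total == 0:
            raise ValidationError(f"zero-total genotype table for group {t.group!r}")
    return np.array(
        [
            [case_counts.minor_allele_count,
             case_counts.allele_total - case_counts.minor_allele_count],
            [control_counts.minor_allele_count,
             control_counts.allele_total - control_counts.minor_allele_count],
        ]
    )


def chisq_homogeneity(table, continuity_correction: bool = False) -> TestResult:
    """Pearson chi-square homogeneity test on an r x c count table.

    All-zero rows and columns are dropped first and the degrees of freedom
    computed on the retained table.  The Yates correction (|O-E| reduced by
    0.5, floored at 0) applies only when requested and only to 2x2 tables.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2:
        raise ValidationError("expected a 2-D count table")
    if (obs < 0).any():
        raise ValidationError("counts must be nonnegative")
    obs = obs[obs.sum(axis=1) > 0][:, obs.sum(axis=0) > 0]
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DegenerateTableError(
            f"fewer than 2 non-empty rows/columns after dropping zeros "
            f"(shape {obs.shape})"
        )
    total = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    dev = np.abs(obs - expected)
    corrected = continuity_correction and obs.shape == (2, 2)
    if corrected:
        dev = np.maximum(dev - 0.5, 0.0)
    statistic = float((dev**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(statistic, df))
    return TestResult(
        statistic=statistic,
        df=df,
        p_value=p,
        method="chi-square homogeneity" + (" (Yates)" if corrected else ""),
    )


def hwe_chisq(counts: GenotypeCountTable) -> TestResult:
    """1-df chi-square goodness-of-fit to Hardy-Weinberg proportions.

    Expected genotype counts come from the observed allele frequency:
    (n*q^2, 2n*p*q, n*p^2) against observed (major hom, het, minor hom).
    Monomorphic input returns statistic 0, p = 1, flagged.
    """
    n = counts.n_total
    if n == 0:
        raise ValidationError("empty genotype table")
    p_hat = counts.maf
    if p_hat in (0.0, 1.0):
        return TestResult(0.0, 1, 1.0, "HWE chi-square", flags=("monomorphic",))
    q_hat = 1 - p_hat
    expected = np.array([n * q_hat**2, 2 * n * p_hat * q_hat, n * p_hat**2])
    observed = counts.as_array()
    statistic = float(((observed - expected) ** 2 / expected).sum())
    return TestResult(statistic, 1, float(sps.chi2.sf(statistic, 1)), "HWE chi-square")


def odds_ratio_ci(
    table, level: float = 0.95
) -> tuple[float | None, float | None, float | None, tuple[str, ...]]:
    """Minor-allele odds ratio with a Woolf log-scale confidence interval.

    ``table`` rows are (case, control), columns (minor, major); the major
    allele is the referent, so OR = (minor_case * major_control) /
    (major_case * minor_control).  If any cell is zero, 0.5 is added to all
    cells (Haldane-Anscombe) and the result flagged ``haldane``.  If a whole
    row or column is zero the OR is undefined and (None, None, None) is
    returned with flag ``undefined``.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValidationError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise ValidationError("counts must be nonnegative")
    if not 0 < level < 1:
        raise ValidationError(f"confidence level must lie in (0,1), got {level}")
    flags: tuple[str, ...] = ()
    if (t.sum(axis=1) == 0).any() or (t.sum(axis=0) == 0).any():
        return None, None, None, ("undefined",)
    if (t == 0).any():
        t = t + 0.5
        flags = ("haldane",)
    (a, b), (c, d) = t
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = sps.norm.isf((1 - level) / 2)
    log_or = np.log(or_)
    return (
        float(or_),
        float(np.exp(log_or - z * se)),
        float(np.exp(log_or + z * se)),
        flags,
    )


def kruskal_wallis(scores_by_genotype) -> TestResult:
    """Kruskal-Wallis rank-sum test of scores across genotype groups.

    Empty groups are dropped (df = non-empty groups - 1).  If every retained
    observation is identical the tie correction degenerates; by convention
    the statistic is 0 and p = 1, flagged ``all-tied``.
    """
    groups = [np.asarray(g, dtype=float) for g in scores_by_genotype]
    groups = [g for g in groups if g.size > 0]
    if len(groups) < 2:
        raise DegenerateTableError("Kruskal-Wallis needs >= 2 non-empty groups")
    total_n = sum(g.size for g in groups)
    if total_n < 3:
        raise DegenerateTableError("Kruskal-Wallis needs >= 3 observations")
    df = len(groups) - 1
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return TestResult(0.0, df, 1.0, "Kruskal-Wallis", flags=("all-tied",))
    statistic, p = sps.kruskal(*groups)
    return TestResult(float(statistic), df, float(p), "Kruskal-Wallis")


def run_association(
    cohort: CohortDataset,
    continuity_correction: bool = False,
    ci_level: float = 0.95,
) -> list[AssociationResult]:
    """Full per-SNP association scan of a cohort.

    For each SNP (complete-case for that SNP): allele-based 2x2 test,
    genotype-based 2x3 test, minor-allele OR with CI, HWE per group and
    Kruskal-Wallis of each allergen's SPT scores across genotype groups.
    Dosage orientation is normalised so the coded allele is the minor allele
    in the combined sample (flagged ``recoded`` if flipped); SNPs that are
    monomorphic in the combined sample are flagged and skipped.
    """
    if cohort.n_case == 0 or cohort.n_control == 0:
        raise ValidationError("association needs at least one case and one control")
    results = []
    for snp_id in cohort.snp_ids:
        case_t, control_t = cohort.genotype_counts(snp_id)
        flags: tuple[str, ...] = ()
        combined_minor = case_t.minor_allele_count + control_t.minor_allele_count
        combined_total = case_t.allele_total + control_t.allele_total
        if combined_total == 0 or combined_minor in (0, combined_total):
            results.append(
                AssociationResult(
                    snp_id=snp_id,
                    maf_case=None, maf_control=None,
                    p_allele=None, p_genotype=None,
                    or_minor=None, ci_low=None, ci_high=None,
                    hwe_p_case=None, hwe_p_control=None,
                    p_spt={}, flags=("monomorphic",),
                )
            )
            continue
        if combined_minor / combined_total > 0.5:
            # coded allele is actually major in the combined sample: flip
            case_t, control_t = (_flip(case_t), _flip(control_t))
            flags = flags + ("recoded",)
        al_table = allele_table(case_t, control_t)
        p_allele = _safe_p(lambda: chisq_homogeneity(al_table, continuity_correction))
        geno_table = np.vstack([case_t.as_array(), control_t.as_array()])
        p_geno = _safe_p(lambda: chisq_homogeneity(geno_table, continuity_correction))
        or_, lo, hi, or_flags = odds_ratio_ci(al_table, ci_level)
        flags = flags + or_flags
        hwe_case = hwe_chisq(case_t) if case_t.n_total else None
        hwe_control = hwe_chisq(control_t) if control_t.n_total else None
        p_spt = {}
        dos = cohort.dosages(snp_id)
        for allergen in cohort.allergens:
            scores = cohort.spt_scores(allergen)
            merged = dos.join(scores[["score"]], how="inner")
            groups = [
                merged.loc[merged["dosage"] == d, "score"].to_numpy()
                for d in (0.0, 1.0, 2.0)
            ]
            try:
                p_spt[allergen] = kruskal_wallis(groups).p_value
            except DegenerateTableError:
                p_spt[allergen] = None
        results.append(
            AssociationResult(
                snp_id=snp_id,
                maf_case=case_t.maf,
                maf_control=control_t.maf,
                p_allele=p_allele,
                p_genotype=p_geno,
                or_minor=or_,
                ci_low=lo,
                ci_high=hi,
                hwe_p_case=hwe_case.p_value if hwe_case else None,
                hwe_p_control=hwe_control.p_value if hwe_control else None,
                p_spt=p_spt,
                flags=flags,
            )
        )
    return results


def _flip(t: GenotypeCountTable) -> GenotypeCountTable:
    return GenotypeCountTable(
        group=t.group,
        n_major_hom=t.n_minor_hom,
        n_het=t.n_het,
        n_minor_hom=t.n_major_hom,
    )


def _safe_p(compute) -> float | None:
    try:
        return compute().p_value
    except DegenerateTableError:
        return None
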