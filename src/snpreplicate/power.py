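"""Monte-Carlo power for the allele-based chi-square association test.

For a SNP with control minor-allele frequency ``p0`` and allelic odds ratio
``OR``, each replicate draws case minor-allele counts Binomial(2*n_case, p1)
and control counts Binomial(2*n_control, p0), forms the 2x2 allele table and
compares the uncorrected chi-square statistic with the upper-tail critical
value for each significance level; power is the rejection fraction over
``n_reps`` replicates (default 10,000).  Replicates whose table has a zero
margin get the Haldane 0.5 correction rather than being redrawn, keeping the
denominator at ``n_reps``.

Given per-SNP power estimates, the expected number of significant tests is
E = sum(power_i) with standard deviation sqrt(sum(power_i * (1 - power_i)))
— the mean and SD of a sum of independent Bernoulli rejections.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .catalog import SnpCatalogEntry
from .errors import ValidationError
from .simulate import case_allele_freq, draw_allele_counts, substream

logger = logging.getLogger(__name__)

DEFAULT_ALPHAS = (0.05, 0.001)
DEFAULT_N_REPS = 10_000
DEFAULT_P0 = 0.25


@dataclass(frozen=True)
class PowerEstimate:
    """Monte-Carlo rejection rate for one SNP/alpha/population configuration."""

    snp_id: str
    population_label: str
    n_case: int
    n_control: int
    p0: float
    odds_ratio: float
    alpha: float
    n_reps: int
    power: float
    seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.power <= 1:
            raise ValidationError(f"power outside [0,1]: {self.power}")
        if self.n_reps < 1:
            raise ValidationError("n_reps must be >= 1")


@dataclass(frozen=True)
class ExpectedSignificanceSummary:
    """Expected vs observed number of significant tests at one alpha."""

    alpha: float
    expected_count: float
    sd: float
    observed_count: int | None = None


def _chisq_2x2_vec(minor_case, major_case, minor_control, major_control) -> np.ndarray:
    """Vectorised uncorrected 2x2 chi-square; Haldane 0.5 on zero-margin tables."""
    a = np.asarray(minor_case, float)
    b = np.asarray(major_case, float)
    c = np.asarray(minor_control, float)
    d = np.asarray(major_control, float)
    # row margins are fixed sample sizes (>0); only columns can vanish
    degenerate = ((a + c) == 0) | ((b + d) == 0)
    if degenerate.any():
        a = np.where(degenerate, a + 0.5, a)
        b = np.where(degenerate, b + 0.5, b)
        c = np.where(degenerate, c + 0.5, c)
        d = np.where(degenerate, d + 0.5, d)
    n = a + b + c + d
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    return num / den


def simulate_power(
    n_case: int,
    n_control: int,
    p0: float,
    odds_ratio: float,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    snp_id: str = "",
    population_label: str = "",
) -> list[PowerEstimate]:
    """Monte-Carlo power of the allele-based test, one estimate per alpha."""
    if not 0 < p0 < 1:
        raise ValidationError(f"p0 must lie strictly in (0,1), got {p0}")
    if not odds_ratio > 0:
        raise ValidationError(f"odds ratio must be > 0, got {odds_ratio}")
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if n_case < 1 or n_control < 1:
        raise ValidationError("sample sizes must be >= 1")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    case_minor, control_minor = draw_allele_counts(
        rng, n_case, n_control, p0, odds_ratio, n_reps
    )
    stat = _chisq_2x2_vec(
        case_minor,
        2 * n_case - case_minor,
        control_minor,
        2 * n_control - control_minor,
    )
    out = []
    for alpha in alphas:
        if not 0 < alpha < 1:
            raise ValidationError(f"alpha must lie in (0,1), got {alpha}")
        critical = sps.chi2.isf(alpha, 1)
        power = float((stat > critical).mean())
        out.append(
            PowerEstimate(
                snp_id=snp_id,
                population_label=population_label,
                n_case=n_case,
                n_control=n_control,
                p0=p0,
                odds_ratio=odds_ratio,
                alpha=float(alpha),
                n_reps=n_reps,
                power=power,
                seed=int(seed),
            )
        )
    return out


def analytic_power(
    n_case: int, n_control: int, p0: float, odds_ratio: float, alpha: float
) -> float:
    """Normal-approximation power of the two-proportion allele test.

    Closed-form companion to :func:`simulate_power` (pooled SE under the
    null, unpooled under the alternative, allele denominators 2n); intended
    as an independent check, not a replacement for simulation.
    """
    p1 = case_allele_freq(p0, odds_ratio)
    n1, n2 = 2 * n_case, 2 * n_control
    pbar = (n1 * p1 + n2 * p0) / (n1 + n2)
    se_null = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    se_alt = np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n2)
    z = sps.norm.isf(alpha / 2)
    delta = p1 - p0
    if se_alt == 0:
        return 1.0 if abs(delta) > z * se_null else float(alpha)
    return float(
        sps.norm.cdf((delta - z * se_null) / se_alt)
        + sps.norm.cdf((-delta - z * se_null) / se_alt)
    )


def power_table(
    catalog: Sequence[SnpCatalogEntry],
    populations: Mapping[str, tuple[int, int]],
    maf_source: Mapping | None = None,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
    default_p0: float = DEFAULT_P0,
) -> pd.DataFrame:
    """Per-SNP power for each catalog entry in each replication population.

    ``populations`` maps a label to (n_case, n_control).  ``maf_source``
    optionally maps ``(snp_id, label)`` or ``snp_id`` to the control MAF to
    use; an explicit value of None (or a monomorphic 0/1) marks the SNP as
    absent in that population and its power cells are left missing, mirroring
    how a replication panel drops SNPs that are not polymorphic there.
    SNPs without any MAF entry fall back to ``default_p0`` with a warning.
    """
    if not catalog:
        raise ValidationError("catalog must be nonempty")
    rows = []
    for i, entry in enumerate(catalog):
        for label, (n_case, n_control) in populations.items():
            p0, absent = _resolve_maf(maf_source, entry.snp_id, label, default_p0)
            row = {
                "gene": entry.gene,
                "snp_id": entry.snp_id,
                "population": entry.source_population,
                "source_n_cases": entry.source_n_cases,
                "source_n_controls": entry.source_n_controls,
                "or": entry.published_or,
                "cohort": label,
                "n_case": n_case,
                "n_control": n_control,
                "p0": None if absent else p0,
            }
            if absent:
                for alpha in alphas:
                    row[f"power_{alpha:g}"] = None
            else:
                est = simulate_power(
                    n_case,
                    n_control,
                    p0,
                    entry.published_or,
                    alphas=alphas,
                    n_reps=n_reps,
                    seed=_row_seed(seed, entry.snp_id, label, i),
                    snp_id=entry.snp_id,
                    population_label=label,
                )
                for e in est:
                    row[f"power_{e.alpha:g}"] = e.power
            rows.append(row)
    return pd.DataFrame(rows)


def _row_seed(seed: int, snp_id: str, label: str, index: int) -> int:
    # independent stream per table row, stable under catalog extension
    return int(substream(seed, "power", snp_id, label, str(index)).integers(2**31))


def _resolve_maf(maf_source, snp_id, label, default_p0) -> tuple[float, bool]:
    if maf_source is not None:
        for key in ((snp_id, label), snp_id):
            if key in maf_source:
                p0 = maf_source[key]
                if p0 is None or not 0 < p0 < 1:
                    return float("nan"), True
                return float(p0), False
        logger.warning(
            "no MAF for %s in %s; using default p0 = %s", snp_id, label, default_p0
        )
    return float(default_p0), False


def expected_significant(
    powers: Sequence[float], observed_count: int | None = None, alpha: float = 0.05
) -> ExpectedSignificanceSummary:
    """Expected number of significant tests given per-SNP powers.

    E = sum(power_i), SD = sqrt(sum(power_i * (1 - power_i))).
    """
    p = np.asarray(powers, dtype=float)
    if p.size == 0:
        raise ValidationError("expected_significant needs at least one power")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("powers must lie in [0,1]")
    return ExpectedSignificanceSummary(
        alpha=float(alpha),
        expected_count=float(p.sum()),
        sd=float(np.sqrt((p * (1 - p)).sum())),
        observed_count=observed_count,
    )
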