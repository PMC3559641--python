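"""High-level model/results API.

Three model classes, each fit against data and returning a results object
with the estimates, their uncertainties, diagnostics and a ``summary()``
table — the idiom of the mainstream statistical-modelling packages:

* :class:`AssociationStudy` — per-SNP case-control association scan of one
  cohort (allele and genotype chi-square tests, minor-allele OR with CI,
  HWE checks, Kruskal-Wallis on SPT scores), with q-values and the
  observed/expected P-value bin diagnostic hanging off the results.
* :class:`PowerStudy` — Monte-Carlo power of the allele test for every
  catalog entry in each replication cohort, plus the expected number of
  significant tests.
* :class:`ConcordanceAnalysis` — Spearman/sign concordance of ORs between
  two association-result tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import concordance as _concordance
from . import fdr as _fdr
from . import power as _power
from . import stats as _stats
from .catalog import CohortDataset, SnpCatalogEntry, format_value, write_results
from .errors import InsufficientDataError, ValidationError


class AssociationStudy:
    """Per-SNP association model for one case-control cohort."""

    def __init__(self, cohort: CohortDataset):
        self.cohort = cohort

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "AssociationStudy":
        return cls(CohortDataset(frame))

    def fit(
        self, continuity_correction: bool = False, ci_level: float = 0.95
    ) -> "AssociationResults":
        results = _stats.run_association(
            self.cohort,
            continuity_correction=continuity_correction,
            ci_level=ci_level,
        )
        return AssociationResults(self, results, ci_level=ci_level)


class AssociationResults:
    """Fitted association scan: one row per SNP, plus FDR diagnostics."""

    def __init__(self, model, results, ci_level: float):
        self.model = model
        self.results = list(results)
        self.ci_level = ci_level

    @property
    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {
                "snp_id": r.snp_id,
                "maf_case": r.maf_case,
                "maf_control": r.maf_control,
                "p_allele": r.p_allele,
                "p_genotype": r.p_genotype,
                "or_minor": r.or_minor,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "hwe_p_case": r.hwe_p_case,
                "hwe_p_control": r.hwe_p_control,
                "flags": ";".join(r.flags),
            }
            for allergen, p in r.p_spt.items():
                row[f"p_spt_{allergen}"] = p
            rows.append(row)
        return pd.DataFrame(rows)

    def tested(self) -> list:
        return [r for r in self.results if "monomorphic" not in r.flags]

    def pvalues(self, kind: str = "allele") -> np.ndarray:
        """P-values for one test family ('allele', 'genotype', or an allergen)."""
        if kind == "allele":
            vals = [r.p_allele for r in self.tested()]
        elif kind == "genotype":
            vals = [r.p_genotype for r in self.tested()]
        else:
            vals = [r.p_spt.get(kind) for r in self.tested()]
        return np.array([v for v in vals if v is not None], dtype=float)

    def qvalues(self, kind: str = "allele", method: str = "spline",
                lambda_grid=None) -> _fdr.QValueSet:
        return _fdr.storey_qvalues(
            self.pvalues(kind), lambda_grid=lambda_grid, method=method
        )

    def pvalue_bin_table(
        self, kind: str = "allele", bin_edges=_fdr.DEFAULT_BIN_EDGES,
        with_qvalues: bool = False, pi0_method: str = "spline",
    ) -> _fdr.PValueBinTable:
        p = self.pvalues(kind)
        q = (
            np.asarray(_fdr.storey_qvalues(p, method=pi0_method).q_values)
            if with_qvalues
            else None
        )
        return _fdr.pvalue_bin_table(p, bin_edges=bin_edges, q_values=q)

    def save(self, path) -> None:
        write_results(self.frame, path)

    def summary(self) -> str:
        n_mono = sum("monomorphic" in r.flags for r in self.results)
        lines = [
            "Association study results",
            f"  individuals: {len(self.model.cohort)} "
            f"({self.model.cohort.n_case} cases, {self.model.cohort.n_control} controls)",
            f"  SNPs: {len(self.results)} ({n_mono} monomorphic, skipped)",
            f"  CI level: {self.ci_level:g}",
            "",
            self.frame.map(format_value).to_string(index=False),
        ]
        return "\n".join(lines)


class PowerStudy:
    """Monte-Carlo power of the allele test across a published-OR catalog."""

    def __init__(
        self,
        catalog: Sequence[SnpCatalogEntry],
        populations: Mapping[str, tuple[int, int]],
        maf_source: Mapping | None = None,
        default_p0: float = _power.DEFAULT_P0,
    ):
        if not catalog:
            raise ValidationError("catalog must be nonempty")
        if not populations:
            raise ValidationError("at least one population configuration required")
        self.catalog = list(catalog)
        self.populations = dict(populations)
        self.maf_source = maf_source
        self.default_p0 = default_p0

    def fit(
        self,
        alphas: Sequence[float] = _power.DEFAULT_ALPHAS,
        n_reps: int = _power.DEFAULT_N_REPS,
        seed: int = 0,
    ) -> "PowerResults":
        table = _power.power_table(
            self.catalog,
            self.populations,
            maf_source=self.maf_source,
            alphas=alphas,
            n_reps=n_reps,
            seed=seed,
            default_p0=self.default_p0,
        )
        return PowerResults(self, table, alphas=tuple(alphas), n_reps=n_reps, seed=seed)


class PowerResults:
    """Fitted power table plus expected-significant-count summaries."""

    def __init__(self, model, frame: pd.DataFrame, alphas, n_reps, seed):
        self.model = model
        self.frame = frame
        self.alphas = alphas
        self.n_reps = n_reps
        self.seed = seed

    def powers(self, cohort_label: str, alpha: float) -> np.ndarray:
        col = f"power_{alpha:g}"
        sub = self.frame[self.frame["cohort"] == cohort_label]
        return sub[col].dropna().to_numpy(dtype=float)

    def expected_significant(
        self, cohort_label: str, alpha: float, observed_count: int | None = None
    ) -> _power.ExpectedSignificanceSummary:
        return _power.expected_significant(
            self.powers(cohort_label, alpha), observed_count, alpha=alpha
        )

    def save(self, path) -> None:
        write_results(self.frame, path)

    def summary(self) -> str:
        lines = [
            "Power study results",
            f"  catalog entries: {len(self.model.catalog)}",
            f"  replicates per configuration: {self.n_reps} (seed {self.seed})",
        ]
        for label in self.model.populations:
            for alpha in self.alphas:
                es = self.expected_significant(label, alpha)
                lines.append(
                    f"  {label} @ alpha={alpha:g}: expected significant "
                    f"{es.expected_count:.1f} (SD {es.sd:.1f}) "
                    f"of {self.powers(label, alpha).size} SNPs"
                )
        lines += ["", self.frame.map(format_value).to_string(index=False)]
        return "\n".join(lines)


class ConcordanceAnalysis:
    """Concordance of minor-allele ORs between two association-result tables."""

    def __init__(self, frame_a: pd.DataFrame, frame_b: pd.DataFrame,
                 key: str = "snp_id", value: str = "or_minor"):
        merged = frame_a[[key, value]].merge(
            frame_b[[key, value]], on=key, suffixes=("_a", "_b")
        )
        if merged.empty:
            raise InsufficientDataError("no SNPs shared between the two tables")
        self.pairs = merged

    def fit(self) -> "ConcordanceResults":
        report = _concordance.concordance_report(
            self.pairs.iloc[:, 1].to_numpy(dtype=float),
            self.pairs.iloc[:, 2].to_numpy(dtype=float),
        )
        return ConcordanceResults(self, report)


class ConcordanceResults:
    def __init__(self, model, report: _concordance.ConcordanceReport):
        self.model = model
        self.report = report

    @property
    def frame(self) -> pd.DataFrame:
        r = self.report
        return pd.DataFrame(
            [
                {
                    "n_pairs": r.n_pairs,
                    "n_concordant": r.n_concordant,
                    "n_discordant": r.n_discordant,
                    "n_excluded": r.n_excluded,
                    "spearman_rho": r.spearman_rho,
                    "spearman_p": r.spearman_p,
                    "binomial_p": r.binomial_p,
                }
            ]
        )

    def save(self, path) -> None:
        write_results(self.frame, path)

    def summary(self) -> str:
        r = self.report
        return "\n".join(
            [
                "Cross-study concordance",
                f"  shared SNPs: {r.n_pairs} "
                f"({r.n_concordant} concordant, {r.n_discordant} discordant, "
                f"{r.n_excluded} excluded)",
                f"  Spearman rho = {format_value(r.spearman_rho)} "
                f"(P = {format_value(r.spearman_p)})",
                f"  sign test P = {format_value(r.binomial_p)}",
            ]
        )
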