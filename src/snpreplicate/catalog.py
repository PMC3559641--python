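"""Data model and TSV I/O for SNP catalogs, cohorts and result tables.

The package ships a catalog of published allergic-rhinitis SNP associations
(rsID, gene, source population, source study sizes, minor-allele odds ratio)
as a packaged fixture; cohorts are per-individual tables of case/control
status, minor-allele dosage per SNP and optional skin-prick-test scores.

All tables are tab-separated UTF-8 with a header row.  Cohort schema::

    individual_id  status  <rsID> ...  spt:<allergen> ...

with dosages in {0, 1, 2, NA} counting copies of the minor allele (minor
allele defined in the combined case+control sample), and SPT columns holding
nonnegative reals or NA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

CATALOG_COLUMNS = (
    "gene",
    "snp_id",
    "polymorphism",
    "population",
    "n_cases",
    "n_controls",
    "or",
    "reference",
)

SPT_PREFIX = "spt:"
STATUS_VALUES = ("case", "control")


@dataclass(frozen=True)
class SnpCatalogEntry:
    """One published SNP-disease association.

    ``published_or`` is the minor-allele odds ratio as printed in the source
    report; ``source_n_cases``/``source_n_controls`` are the sizes of the
    original study, not of any replication cohort.
    """

    snp_id: str
    gene: str
    polymorphism: str
    source_population: str
    source_n_cases: int
    source_n_controls: int
    published_or: float
    reference_tag: str

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValidationError("snp_id must be non-empty")
        if not (self.published_or > 0) or not math.isfinite(self.published_or):
            raise ValidationError(
                f"published_or must be a positive real, got {self.published_or!r}"
            )
        if self.source_n_cases < 1 or self.source_n_controls < 1:
            raise ValidationError(
                f"source sample sizes must be >= 1 "
                f"({self.source_n_cases}; {self.source_n_controls})"
            )


@dataclass(frozen=True)
class GenotypeCountTable:
    """Genotype counts for one group, indexed by minor-allele dosage.

    ``n_major_hom`` is dosage 0, ``n_het`` dosage 1, ``n_minor_hom`` dosage 2.
    """

    group: str
    n_major_hom: int
    n_het: int
    n_minor_hom: int

    def __post_init__(self) -> None:
        if min(self.n_major_hom, self.n_het, self.n_minor_hom) < 0:
            raise ValidationError("genotype counts must be nonnegative")

    @property
    def n_total(self) -> int:
        return self.n_major_hom + self.n_het + self.n_minor_hom

    @property
    def minor_allele_count(self) -> int:
        return 2 * self.n_minor_hom + self.n_het

    @property
    def allele_total(self) -> int:
        return 2 * self.n_total

    @property
    def maf(self) -> float:
        if self.n_total == 0:
            raise ValidationError(f"empty genotype table for group {self.group!r}")
        return self.minor_allele_count / self.allele_total

    def as_array(self) -> np.ndarray:
        """Counts ordered by dosage (0, 1, 2)."""
        return np.array([self.n_major_hom, self.n_het, self.n_minor_hom])


class CohortDataset:
    """Per-individual case-control cohort with minor-allele dosages.

    Wraps a :class:`pandas.DataFrame` with columns ``individual_id``,
    ``status``, one float column per SNP (values 0/1/2 or NaN) and optional
    ``spt:<allergen>`` score columns (nonnegative reals or NaN).
    """

    def __init__(self, data: pd.DataFrame):
        self.data = data.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        df = self.data
        for col in ("individual_id", "status"):
            if col not in df.columns:
                raise SchemaError(f"cohort table is missing column {col!r}")
        bad_status = set(df["status"].unique()) - set(STATUS_VALUES)
        if bad_status:
            raise ValidationError(
                f"status values outside {{case, control}}: {sorted(bad_status)}"
            )
        for snp in self.snp_ids:
            vals = df[snp].dropna()
            if not vals.isin([0.0, 1.0, 2.0]).all():
                bad = sorted(set(vals) - {0.0, 1.0, 2.0})
                raise ValidationError(
                    f"dosages for {snp} outside {{0,1,2,NA}}: {bad}"
                )
        for col in self.spt_columns:
            vals = df[col].dropna()
            if (vals < 0).any():
                raise ValidationError(f"negative SPT scores in column {col!r}")

    # -- basic views -------------------------------------------------------

    @property
    def spt_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith(SPT_PREFIX)]

    @property
    def allergens(self) -> list[str]:
        return [c[len(SPT_PREFIX):] for c in self.spt_columns]

    @property
    def snp_ids(self) -> list[str]:
        return [
            c
            for c in self.data.columns
            if c not in ("individual_id", "status") and not c.startswith(SPT_PREFIX)
        ]

    @property
    def n_case(self) -> int:
        return int((self.data["status"] == "case").sum())

    @property
    def n_control(self) -> int:
        return int((self.data["status"] == "control").sum())

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CohortDataset):
            return NotImplemented
        if list(self.data.columns) != list(other.data.columns):
            return False
        try:
            pd.testing.assert_frame_equal(self.data, other.data, check_dtype=False)
        except AssertionError:
            return False
        return True

    # -- per-SNP extraction (complete-case per SNP) ------------------------

    def dosages(self, snp_id: str) -> pd.DataFrame:
        """Status + dosage for individuals genotyped at ``snp_id``."""
        if snp_id not in self.snp_ids:
            raise ValidationError(f"unknown SNP {snp_id!r}")
        sub = self.data[["status", snp_id]].dropna(subset=[snp_id])
        return sub.rename(columns={snp_id: "dosage"})

    def genotype_counts(self, snp_id: str) -> tuple[GenotypeCountTable, GenotypeCountTable]:
        """(case, control) genotype count tables, complete-case for this SNP."""
        sub = self.dosages(snp_id)
        out = []
        for group in ("case", "control"):
            d = sub.loc[sub["status"] == group, "dosage"]
            out.append(
                GenotypeCountTable(
                    group=group,
                    n_major_hom=int((d == 0).sum()),
                    n_het=int((d == 1).sum()),
                    n_minor_hom=int((d == 2).sum()),
                )
            )
        return out[0], out[1]

    def spt_scores(self, allergen: str) -> pd.DataFrame:
        """Status + score for individuals with a recorded score."""
        col = SPT_PREFIX + allergen
        if col not in self.data.columns:
            raise ValidationError(f"unknown allergen {allergen!r}")
        sub = self.data[["status", col]].dropna(subset=[col])
        return sub.rename(columns={col: "score"})


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_snp_catalog(path: str | Path) -> list[SnpCatalogEntry]:
    """Read a published-association catalog TSV.

    Raises :class:`SchemaError` if a required column is missing and
    :class:`ValidationError` (with the 1-based data row number) for
    non-numeric or non-positive odds ratios or sample sizes.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in CATALOG_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"catalog file missing column(s): {', '.join(missing)}")
    entries = []
    for i, row in enumerate(df.to_dict(orient="records"), start=1):
        try:
            entry = SnpCatalogEntry(
                snp_id=row["snp_id"],
                gene=row["gene"],
                polymorphism=row["polymorphism"],
                source_population=row["population"],
                source_n_cases=_parse_int(row["n_cases"], "n_cases"),
                source_n_controls=_parse_int(row["n_controls"], "n_controls"),
                published_or=_parse_float(row["or"], "or"),
                reference_tag=row["reference"],
            )
        except ValidationError as exc:
            raise ValidationError(f"catalog row {i}: {exc}") from exc
        entries.append(entry)
    return entries


def _parse_int(text: str, name: str) -> int:
    try:
        return int(str(text).strip())
    except (TypeError, ValueError):
        raise ValidationError(f"column {name!r}: non-integer value {text!r}")


def _parse_float(text: str, name: str) -> float:
    try:
        return float(str(text).strip())
    except (TypeError, ValueError):
        raise ValidationError(f"column {name!r}: non-numeric value {text!r}")


def split_size_field(text: str) -> tuple[int, int]:
    """Split a ``"cases; controls"`` size field into two integers."""
    parts = str(text).split(";")
    if len(parts) != 2:
        raise ValidationError(f"size field must be 'cases; controls', got {text!r}")
    return _parse_int(parts[0], "n_cases"), _parse_int(parts[1], "n_controls")


def packaged_catalog() -> list[SnpCatalogEntry]:
    """The packaged catalog of 33 published AR associations."""
    ref = resources.files("snpreplicate.data") / "published_associations.tsv"
    with resources.as_file(ref) as path:
        return read_snp_catalog(path)


def read_cohort(path: str | Path) -> CohortDataset:
    """Read a cohort TSV (schema in the module docstring)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("individual_id", "status"):
        if col not in df.columns:
            raise SchemaError(f"cohort file missing column {col!r}")
    out = pd.DataFrame({"individual_id": df["individual_id"], "status": df["status"]})
    for col in df.columns:
        if col in ("individual_id", "status"):
            continue
        vals = df[col].replace("NA", np.nan).replace("", np.nan)
        try:
            out[col] = vals.astype(float)
        except ValueError:
            raise ValidationError(f"column {col!r}: non-numeric entries")
    return CohortDataset(out)


def write_cohort(cohort: CohortDataset, path: str | Path) -> None:
    df = cohort.data.copy()
    for col in cohort.snp_ids:
        df[col] = df[col].map(lambda v: "NA" if pd.isna(v) else str(int(v)))
    for col in cohort.spt_columns:
        df[col] = df[col].map(format_value)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result-table rendering
# ---------------------------------------------------------------------------


def format_value(value: object) -> str:
    """Render one cell: 4 significant figures, scientific below 1e-4, NA for missing."""
    if value is None:
        return "NA"
    if isinstance(value, float) and math.isnan(value):
        return "NA"
    if isinstance(value, (bool, np.bool_)):
        return str(bool(value))
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        x = float(value)
        if x == 0:
            return "0"
        if abs(x) < 1e-4:
            return f"{x:.3e}"
        return f"{x:.4g}"
    return str(value)


def write_results(results: Sequence | pd.DataFrame, path: str | Path,
                  columns: Sequence[str] | None = None) -> None:
    """Write a result table as TSV with stable column order.

    ``results`` may be a DataFrame or a sequence of dataclass-like records
    (anything with ``__dataclass_fields__`` or a mapping).  An empty sequence
    still produces a header-only file when ``columns`` is given.
    """
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        records = []
        for r in results:
            if hasattr(r, "__dataclass_fields__"):
                records.append({k: getattr(r, k) for k in r.__dataclass_fields__})
            elif isinstance(r, Mapping):
                records.append(dict(r))
            else:
                raise ValidationError(f"cannot render result of type {type(r)!r}")
        df = pd.DataFrame(records, columns=columns)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    rendered = df.map(format_value) if len(df) else df
    try:
        rendered.to_csv(path, sep="\t", index=False)
    except OSError:
        raise


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a result TSV back, with 'NA' as missing and numerics restored."""
    return pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
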