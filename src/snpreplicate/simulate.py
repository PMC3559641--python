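"""Synthetic case-control cohorts with a known allelic architecture.

Controls carry Hardy-Weinberg genotypes at a stated minor-allele frequency
``p0``; cases carry HWE genotypes at the frequency implied by an allelic
odds ratio.  Under a multiplicative allelic model the case minor-allele
frequency is

    p1 = OR * p0 / (1 - p0 + OR * p0),

i.e. case odds = OR * control odds.  Skin-prick-test (SPT) scores are
log-normal with an optional additive per-dosage shift on the log scale,
drawn for cases only (controls are by construction SPT-negative).

All randomness flows from a single master seed; each SNP and each allergen
gets its own stream derived by stable hashing of (seed, label), so adding
or reordering SNPs never perturbs the draws of the others.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .catalog import SPT_PREFIX, CohortDataset
from .errors import ValidationError


def case_allele_freq(p0: float, odds_ratio: float) -> float:
    """Case minor-allele frequency implied by control frequency and allelic OR.

    Multiplies the control allele odds by ``odds_ratio``:
    ``p1 = OR*p0 / (1 - p0 + OR*p0)``.  Monotone increasing in OR for
    ``p0`` in (0,1); equals ``p0`` at OR = 1; maps 0 to 0 and 1 to 1.
    """
    if not odds_ratio > 0:
        raise ValidationError(f"odds ratio must be > 0, got {odds_ratio}")
    if not 0 <= p0 <= 1:
        raise ValidationError(f"allele frequency must lie in [0,1], got {p0}")
    return odds_ratio * p0 / (1 - p0 + odds_ratio * p0)


def _stable_hash(label: str) -> int:
    """Deterministic 32-bit hash of a text label (independent of PYTHONHASHSEED)."""
    return int.from_bytes(hashlib.sha256(label.encode()).digest()[:4], "little")


def substream(seed: int, *labels: str) -> np.random.Generator:
    """A generator whose stream depends only on (seed, labels)."""
    entropy = [int(seed) & 0x7FFFFFFF] + [_stable_hash(lab) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class SnpSpec:
    """One simulated SNP: control MAF and allelic odds ratio."""

    snp_id: str
    p0: float
    odds_ratio: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.p0 < 1:
            raise ValidationError(f"{self.snp_id}: p0 must lie in (0,1), got {self.p0}")
        if not self.odds_ratio > 0:
            raise ValidationError(
                f"{self.snp_id}: odds ratio must be > 0, got {self.odds_ratio}"
            )


@dataclass(frozen=True)
class SptEffect:
    """Log-normal SPT score model for one allergen.

    log score ~ Normal(baseline_log_mean + per_dosage_log_shift * dosage,
    log_sd), where dosage is the minor-allele dosage of ``snp_id`` (the
    first SNP in the simulation spec when unset).
    """

    allergen: str
    baseline_log_mean: float = 1.0
    per_dosage_log_shift: float = 0.0
    log_sd: float = 0.5
    snp_id: str | None = None

    def __post_init__(self) -> None:
        if not self.log_sd > 0:
            raise ValidationError(f"{self.allergen}: log_sd must be > 0")


@dataclass(frozen=True)
class SimulationSpec:
    """Full description of a synthetic cohort."""

    n_case: int
    n_control: int
    snps: tuple[SnpSpec, ...]
    spt_effects: tuple[SptEffect, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise ValidationError("n_case and n_control must be >= 1")
        if len(self.snps) == 0:
            raise ValidationError("simulation spec needs at least one SNP")
        object.__setattr__(self, "snps", tuple(self.snps))
        object.__setattr__(self, "spt_effects", tuple(self.spt_effects))
        snp_ids = {s.snp_id for s in self.snps}
        for eff in self.spt_effects:
            if eff.snp_id is not None and eff.snp_id not in snp_ids:
                raise ValidationError(
                    f"SPT effect {eff.allergen!r} references unknown SNP {eff.snp_id!r}"
                )

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationSpec":
        """Load a spec from a YAML config: flat keys plus a ``snps`` block."""
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        snps = tuple(
            SnpSpec(
                snp_id=str(s["snp_id"]),
                p0=float(s["p0"]),
                odds_ratio=float(s.get("odds_ratio", s.get("or", 1.0))),
            )
            for s in raw.get("snps", [])
        )
        effects = tuple(
            SptEffect(
                allergen=str(e["allergen"]),
                baseline_log_mean=float(e.get("baseline_log_mean", 1.0)),
                per_dosage_log_shift=float(e.get("per_dosage_log_shift", 0.0)),
                log_sd=float(e.get("log_sd", 0.5)),
                snp_id=e.get("snp_id"),
            )
            for e in raw.get("spt_effects", [])
        )
        return cls(
            n_case=int(raw["n_case"]),
            n_control=int(raw["n_control"]),
            snps=snps,
            spt_effects=effects,
            seed=int(raw.get("seed", 0)),
        )

    def to_dict(self) -> dict:
        return {
            "n_case": self.n_case,
            "n_control": self.n_control,
            "seed": self.seed,
            "snps": [
                {"snp_id": s.snp_id, "p0": s.p0, "odds_ratio": s.odds_ratio}
                for s in self.snps
            ],
            "spt_effects": [
                {
                    "allergen": e.allergen,
                    "baseline_log_mean": e.baseline_log_mean,
                    "per_dosage_log_shift": e.per_dosage_log_shift,
                    "log_sd": e.log_sd,
                    "snp_id": e.snp_id,
                }
                for e in self.spt_effects
            ],
        }


# ---------------------------------------------------------------------------
# allele-level simulation (the power engine's sampling core)
# ---------------------------------------------------------------------------


def draw_allele_counts(
    rng: np.random.Generator,
    n_case: int,
    n_control: int,
    p0: float,
    odds_ratio: float,
    n_reps: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised minor-allele counts: (case counts, control counts), each length n_reps.

    Case counts are Binomial(2*n_case, p1), control counts Binomial(2*n_control, p0).
    """
    p1 = case_allele_freq(p0, odds_ratio)
    case = rng.binomial(2 * n_case, p1, size=n_reps)
    control = rng.binomial(2 * n_control, p0, size=n_reps)
    return case, control


def simulate_allele_counts(
    n_case: int,
    n_control: int,
    p0: float,
    odds_ratio: float,
    seed: int,
) -> np.ndarray:
    """One simulated 2x2 allele table, rows (case, control), cols (minor, major)."""
    if n_case < 1 or n_control < 1:
        raise ValidationError("sample sizes must be >= 1")
    if not 0 < p0 < 1:
        raise ValidationError(f"p0 must lie strictly in (0,1), got {p0}")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    case, control = draw_allele_counts(rng, n_case, n_control, p0, odds_ratio, 1)
    a, b = int(case[0]), int(control[0])
    return np.array([[a, 2 * n_case - a], [b, 2 * n_control - b]])


# ---------------------------------------------------------------------------
# individual-level simulation
# ---------------------------------------------------------------------------


def simulate_cohort(spec: SimulationSpec) -> CohortDataset:
    """Generate a per-individual cohort from a :class:`SimulationSpec`.

    Genotypes: minor-allele dosage ~ Binomial(2, p) per individual, which is
    exactly the HWE distribution (p^2, 2pq, q^2) on dosages (2, 1, 0) —
    controls at ``p0``, cases at the OR-shifted frequency.  SPT scores are
    drawn for cases only; controls stay missing.
    """
    n = spec.n_case + spec.n_control
    status = np.array(["case"] * spec.n_case + ["control"] * spec.n_control)
    data = {
        "individual_id": [f"ind{i:05d}" for i in range(1, n + 1)],
        "status": status,
    }
    dosage_by_snp: dict[str, np.ndarray] = {}
    for snp in spec.snps:
        rng = substream(spec.seed, "snp", snp.snp_id)
        p1 = case_allele_freq(snp.p0, snp.odds_ratio)
        d_case = rng.binomial(2, p1, size=spec.n_case)
        d_control = rng.binomial(2, snp.p0, size=spec.n_control)
        dosage = np.concatenate([d_case, d_control]).astype(float)
        dosage_by_snp[snp.snp_id] = dosage
        data[snp.snp_id] = dosage
    for eff in spec.spt_effects:
        rng = substream(spec.seed, "spt", eff.allergen)
        anchor = eff.snp_id if eff.snp_id is not None else spec.snps[0].snp_id
        dos_case = dosage_by_snp[anchor][: spec.n_case]
        log_mean = eff.baseline_log_mean + eff.per_dosage_log_shift * dos_case
        scores_case = np.exp(rng.normal(log_mean, eff.log_sd))
        col = np.full(n, np.nan)
        col[: spec.n_case] = scores_case
        data[SPT_PREFIX + eff.allergen] = col
    return CohortDataset(pd.DataFrame(data))
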