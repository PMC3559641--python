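import numpy as np
import pandas as pd
import pytest

from snpreplicate import (
    CohortDataset,
    SimulationSpec,
    SnpSpec,
    SptEffect,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def catalog():
    from snpreplicate import packaged_catalog

    return packaged_catalog()


def make_cohort_frame(
    n_case=2, n_control=2, dosages=None, spt=None
) -> pd.DataFrame:
    """Tiny hand-built cohort frame: dosages maps snp_id -> list of values."""
    n = n_case + n_control
    frame = {
        "individual_id": [f"i{k}" for k in range(n)],
        "status": ["case"] * n_case + ["control"] * n_control,
    }
    if dosages:
        for snp, vals in dosages.items():
            frame[snp] = vals
    if spt:
        for allergen, vals in spt.items():
            frame[f"spt:{allergen}"] = vals
    return pd.DataFrame(frame)


@pytest.fixture
def toy_cohort():
    return CohortDataset(
        make_cohort_frame(
            n_case=2,
            n_control=2,
            dosages={"rs1": [1.0, 2.0, 0.0, 1.0]},
        )
    )


@pytest.fixture(scope="session")
def simulated_cohort():
    """A moderately sized cohort with one real effect and one null SNP."""
    spec = SimulationSpec(
        n_case=300,
        n_control=300,
        snps=(
            SnpSpec("rs_effect", p0=0.25, odds_ratio=2.0),
            SnpSpec("rs_null", p0=0.30, odds_ratio=1.0),
        ),
        spt_effects=(SptEffect("birch", per_dosage_log_shift=0.6, snp_id="rs_effect"),),
        seed=11,
    )
    return simulate_cohort(spec)
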