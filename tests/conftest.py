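import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from axrisk.cohort import CANONICAL_COLUMNS, REGIONS, SWE_COLUMNS, CohortTable
from axrisk.synthetic import default_config, generate_cohort

settings.register_profile(
    "deterministic",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


#: Valid SWE values satisfying e_min <= e_mean <= e_max in every region.
BASE_SWE = {}
for _r in REGIONS:
    BASE_SWE[f"{_r}_emin"] = 2.0
    BASE_SWE[f"{_r}_emean"] = 25.0
    BASE_SWE[f"{_r}_emax"] = 120.0
    BASE_SWE[f"{_r}_esd"] = 15.0


def make_frame(rows: list[dict]) -> pd.DataFrame:
    """Build a canonical cohort frame from sparse row dicts (SWE defaults filled)."""
    full = []
    for i, row in enumerate(rows):
        base = {
            "patient_id": f"P{i:04d}",
            "ln_status": "negative",
            "birads": "4A",
            "stiff_rim": "absent",
            "e_ratio": 5.0,
            **BASE_SWE,
        }
        base.update(row)
        full.append(base)
    return pd.DataFrame(full).reindex(columns=list(CANONICAL_COLUMNS))


def make_cohort(rows: list[dict]) -> CohortTable:
    return CohortTable(make_frame(rows))


@pytest.fixture(scope="session")
def large_default_cohort():
    """One big cohort under the default calibration, shared across tests."""
    return generate_cohort(default_config(100_000, seed=1))


@pytest.fixture(scope="session")
def small_default_cohort():
    return generate_cohort(default_config(4_000, seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
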