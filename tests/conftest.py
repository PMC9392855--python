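import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import modrer as m

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_cohort() -> m.CohortTable:
    """One synthetic cohort at the reference calibration (fixed seed)."""
    return m.generate_cohort(m.CohortSpec(seed=7))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260101)


@pytest.fixture()
def simple_panel() -> m.BloodGasPanel:
    return m.BloodGasPanel(
        ph=7.40,
        pao2=80.0,
        paco2=40.0,
        sao2=0.96,
        pcvo2=40.0,
        pcvco2=50.0,
        scvo2=0.672,
        lactate=1.2,
        hemoglobin=14.0,
    )
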