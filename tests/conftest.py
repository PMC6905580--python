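import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sdmfusion as sf

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def study():
    """One deterministic study-mimic dataset shared across tests."""
    return sf.simulate_study(seed=42)


@pytest.fixture(scope="session")
def study_result(study):
    """Full pipeline output on the shared study-mimic dataset."""
    return sf.run_study(
        study.observations, study.covariates, study.elicitations, study.grid
    )


@pytest.fixture(scope="session")
def small_landscape():
    return sf.generate_landscape(20, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
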