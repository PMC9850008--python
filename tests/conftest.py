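import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import finclock as fc

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated cohort used across unit tests (fast to fit)."""
    cfg = fc.SimulationConfig(
        n_samples=30, n_age_cpgs=30, n_sex_cpgs=10, n_null_cpgs=100, seed=11
    )
    beta, sheet, truth = fc.simulate_dataset(cfg)
    return beta, sheet, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
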