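import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from swaylab.study_pipeline import parameter_table
from swaylab.synthetic_sway import SimulationConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def small_config():
    """A miniature study: 6 per group, 12-second trials at 50 Hz."""
    return SimulationConfig(seed=11, n_per_group=6, duration_s=12.0, fs=50.0)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_params(small_cohort):
    return parameter_table(small_cohort)
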