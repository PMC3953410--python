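import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from grscore import load_default_panel, simulate_cohort, SimulationConfig

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def small_panel(panel):
    """First six panel SNPs — enough structure, cheap to simulate."""
    return panel[:6]


@pytest.fixture(scope="session")
def null_cohort(panel):
    """A cohort with no genetic effects, for null checks."""
    return simulate_cohort(SimulationConfig(
        n_individuals=800, panel=panel, seed=424242))


@pytest.fixture()
def rng():
    return np.random.default_rng(20140313)
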