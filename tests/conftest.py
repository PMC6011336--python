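import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from epimethyl.simulate import SimulationConfig, generate_cohort

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cohort():
    """A small labelled cohort with strong planted signal: 300 sites of
    which 20 differ by 20 points between groups, subject noise sd 3."""
    cfg = SimulationConfig(n_sites=300, n_differential=20, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """A cohort with no planted differential sites."""
    cfg = SimulationConfig(n_sites=500, n_differential=0, seed=7)
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
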