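import pytest

from primrose_sim.cohort import default_cohort_spec, generate_cohort
from primrose_sim.config import default_config


@pytest.fixture(scope="session")
def config():
    """Default synthetic configuration (1000-patient spec, seed 3)."""
    return default_config(n=1000, seed=3)


@pytest.fixture(scope="session")
def cohort(config):
    """1000 synthetic patients drawn from the default spec."""
    return generate_cohort(config.cohort_spec)


@pytest.fixture(scope="session")
def small_cohort():
    """200 patients for fast engine/economics tests."""
    return generate_cohort(default_cohort_spec(n=200, seed=7))
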