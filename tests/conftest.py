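import numpy as np
import pytest

from neglectwmh import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small default-grid cohort shared by feature/design tests."""
    return simulate_cohort(SimulationConfig(n_patients=25, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
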