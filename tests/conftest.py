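import numpy as np
import pytest

from graspdyn import TaskConfig
from graspdyn.synthetic import simulate_session


@pytest.fixture(scope="session")
def small_session():
    """A small but complete synthetic session shared across tests."""
    cfg = TaskConfig(n_trials=80, rng_seed=11)
    return simulate_session(cfg, n_units=10)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
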