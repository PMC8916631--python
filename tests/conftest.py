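import numpy as np
import pytest

from ptda import PtdaConfig
from ptda.sim_model import make_validation_set


@pytest.fixture()
def rng():
    return np.random.default_rng(20220311)


@pytest.fixture()
def cfg():
    return PtdaConfig(seed=7)


@pytest.fixture(scope="session")
def small_transition_windows():
    """A handful of complexity-filtered runs with the shift at position 50."""
    return make_validation_set(6, tp_position=50, seed=101)


@pytest.fixture(scope="session")
def small_null_windows():
    """Runs windowed entirely inside the pre-shift stationary regime."""
    return make_validation_set(6, tp_position=None, seed=102)
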