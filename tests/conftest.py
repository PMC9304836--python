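import numpy as np
import pytest

from vibrodev.cohort import chance_observer, make_observer, perfect_observer
from vibrodev.config import ObserverConfig
from vibrodev.staircase import default_task_specs


@pytest.fixture(scope="session")
def specs():
    return default_task_specs()


@pytest.fixture
def perfect():
    return perfect_observer(age=20.0)


@pytest.fixture
def chance():
    return chance_observer(age=20.0)


@pytest.fixture(scope="session")
def observer_config():
    return ObserverConfig()


@pytest.fixture
def mid_child(observer_config):
    """A deterministic 10-year-old with exactly curve-valued thresholds."""
    return make_observer(10.0, observer_config, seed=0, noise_multiplier=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
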