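import numpy as np
import pytest

from kinetime.core_io import Geometry
from kinetime.observer import ObserverParams


@pytest.fixture(scope="session")
def geometry():
    return Geometry()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_params():
    return ObserverParams(seed=7)


@pytest.fixture(scope="session")
def log_durations():
    return np.geomspace(1000.0, 4000.0, 7)
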