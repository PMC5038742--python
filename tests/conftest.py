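import numpy as np
import pytest

from stepfall.defaults import default_model_set
from stepfall.model import FallClassModel, FallModel
from stepfall.signal import AccelSeries


@pytest.fixture(scope="session")
def model_set():
    return default_model_set()


@pytest.fixture(scope="session")
def fall_model():
    return FallModel()


@pytest.fixture(scope="session")
def fall_class_model():
    return FallClassModel()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_series(rng):
    """10 s of random tri-axial data at 50 Hz around 1 g."""
    data = np.array([0.0, 0.0, 1.0]) + rng.normal(0, 0.1, size=(501, 3))
    return AccelSeries(data=data, fs=50.0)


def make_series(data, fs=50.0, t0=0.0):
    return AccelSeries(data=np.asarray(data, dtype=float), fs=fs, t0=t0)
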