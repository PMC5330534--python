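import numpy as np
import pytest
from hypothesis import settings

from astrosim import CompartmentGeometry, default_parameters

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def geom():
    """Soma-like compartment: SVR = 1/µm, large ER fraction."""
    return CompartmentGeometry(svr=1.0, ratio_er=0.15)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
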