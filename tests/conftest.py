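import numpy as np
import pytest

from ambientglu.kinetics import default_scheme, scale_rates_q10
from ambientglu.stimulus import constant_train


@pytest.fixture(scope="session")
def scheme():
    """The shipped calibrated rate table at its 23 C reference temperature."""
    return default_scheme()


@pytest.fixture(scope="session")
def scheme34(scheme):
    """The same scheme scaled to the 34 C recording temperature."""
    return scale_rates_q10(scheme, 34.0)


@pytest.fixture(scope="session")
def train50():
    """The 50 Hz x 10 stimulation train with a 100 ms baseline."""
    return constant_train(50.0, 10, start_ms=100.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
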