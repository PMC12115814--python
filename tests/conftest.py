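import numpy as np
import pytest

from surfnet import MemoryConstants, MemoryStrand, PinchPulse, SolitonTrain


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def consts():
    return MemoryConstants()


@pytest.fixture
def strand():
    return MemoryStrand()


@pytest.fixture
def two_pulse_train():
    return SolitonTrain([
        PinchPulse(a=3.0, b=3.0, c=6.0, V0=1.0),
        PinchPulse(a=5.0, b=5.0, c=35.0, V0=1.8),
    ])
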