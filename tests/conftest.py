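import numpy as np
import pytest

from fdneuron.model import NeuronParams, resolve_preset


@pytest.fixture
def b1():
    """Effective bursting/regular-spiking parameter set, I = 3."""
    return resolve_preset("B1", I=3.0)


@pytest.fixture
def b1_I4():
    return resolve_preset("B1", I=4.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
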