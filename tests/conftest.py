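import numpy as np
import pytest

from betalink.signals import EpochedSignals


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_noise_epochs(rng):
    """10 trials of white noise, 2 channels, standard epoch window."""
    n = int(2.75 * 1000) + 1
    data = rng.standard_normal((10, 2, n))
    return EpochedSignals(data=data, fs=1000.0, t0=-0.25)
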