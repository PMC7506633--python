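import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_rgb(rng):
    """A generic 16x16 RGB test image."""
    return rng.random((16, 16, 3))
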