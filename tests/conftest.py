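import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def quantized_image(rng):
    """Random image with dyadic-rational intensities (like integer sensor data).

    Values are multiples of 1/1024, so sums over power-of-two sized pooling
    blocks are exact in double precision.
    """
    return rng.integers(0, 1024, size=(64, 64)).astype(float) / 1024.0


@pytest.fixture
def blob_image():
    """Smooth 64x64 image with a single bright blob, deterministic."""
    yy, xx = np.mgrid[0:64, 0:64].astype(float)
    return np.exp(-0.5 * (((yy - 30) / 8.0) ** 2 + ((xx - 36) / 6.0) ** 2))
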