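import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_patch(rng):
    """One 8-bit 40x40 patch with full dynamic range."""
    return rng.integers(0, 256, size=(40, 40), dtype=np.uint8)


def random_patches(n, shape, seed=0, high=256):
    rng = np.random.default_rng(seed)
    return [rng.integers(0, high, size=shape, dtype=np.uint8) for _ in range(n)]
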