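import numpy as np
import pytest

from chp import NucleusImage


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_binary(rng, max_size=32, density=None):
    h = int(rng.integers(1, max_size + 1))
    w = int(rng.integers(1, max_size + 1))
    p = density if density is not None else rng.uniform(0.2, 0.8)
    return rng.random((h, w)) < p


def annulus(n=5):
    """n x n frame of foreground around a background interior."""
    img = np.zeros((n, n), dtype=bool)
    img[0, :] = img[-1, :] = img[:, 0] = img[:, -1] = True
    return img


@pytest.fixture
def ring_nucleus():
    """Square ring of intensity 50 on background 200, full mask.

    One hole exists for 50 <= t < 200; everything floods at t >= 200.
    """
    inten = np.full((9, 9), 200, dtype=np.uint8)
    inten[2, 2:7] = inten[6, 2:7] = inten[2:7, 2] = inten[2:7, 6] = 50
    return NucleusImage(inten, np.ones((9, 9), dtype=bool))


def random_nucleus(rng, size=24, lo=40, hi=220):
    """Random-intensity nucleus with an off-centre rectangular mask."""
    inten = rng.integers(lo, hi + 1, size=(size, size)).astype(np.uint8)
    mask = np.zeros((size, size), dtype=bool)
    r0, c0 = rng.integers(0, size // 2, size=2)
    mask[r0 : r0 + size // 2, c0 : c0 + size // 2] = True
    return NucleusImage(inten, mask)
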