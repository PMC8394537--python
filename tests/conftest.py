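import numpy as np
import pytest

from topoiqa import GrayImage, build_complex, toy_ring_image


@pytest.fixture
def toy_ring():
    return toy_ring_image()


@pytest.fixture
def toy_ring_complex(toy_ring):
    return build_complex(toy_ring)


@pytest.fixture
def random_images():
    """Factory for batches of small random images."""

    def make(n, max_side=8, max_depth=16, seed=0):
        rng = np.random.default_rng(seed)
        out = []
        for _ in range(n):
            h, w = rng.integers(1, max_side + 1, 2)
            depth = int(rng.integers(2, max_depth + 1))
            out.append(GrayImage(rng.integers(0, depth, (h, w)), depth=depth))
        return out

    return make
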