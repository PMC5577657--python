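import numpy as np
import pytest

from seedcontact.phantom import sphere_mask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def sphere25():
    """Digitized sphere of radius 25 voxels with a small margin."""
    n = 58
    return sphere_mask((n, n, n), (n // 2, n // 2, n // 2), 25)


def make_sphere(radius: int, margin: int = 4) -> np.ndarray:
    n = 2 * radius + 2 * margin
    return sphere_mask((n, n, n), (n // 2, n // 2, n // 2), radius)
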