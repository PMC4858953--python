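import numpy as np
import pytest

from msishrink import SpectraImage
from msishrink.synth import PhantomSpec, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_image():
    """3x3 single-sample image with 2 features and hand-set intensities."""
    coords = np.array([(i, j) for i in range(1, 4) for j in range(1, 4)])
    intensities = np.arange(18, dtype=float).reshape(9, 2) + 1.0
    return SpectraImage(
        intensities=intensities,
        coords=coords,
        sample_id=np.ones(9, dtype=int),
        mz=np.array([100.0, 200.0]),
    )


@pytest.fixture(scope="session")
def phantom():
    """Default three-segment phantom, shared across read-only tests."""
    return make_phantom(PhantomSpec(seed=0))


def random_image(rng, n_side=4, p=3, n_samples=1, irregular=False):
    """Small random image helper used by oracle tests."""
    coords = np.array(
        [(i, j) for i in range(1, n_side + 1) for j in range(1, n_side + 1)]
    )
    coords = np.tile(coords, (n_samples, 1))
    sample = np.repeat(np.arange(1, n_samples + 1), n_side * n_side)
    if irregular:
        keep = rng.random(coords.shape[0]) > 0.25
        keep[0] = True
        coords, sample = coords[keep], sample[keep]
    x = rng.gamma(2.0, 1.0, size=(coords.shape[0], p))
    return SpectraImage(
        intensities=x,
        coords=coords,
        sample_id=sample,
        mz=100.0 + np.arange(p, dtype=float),
    )
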