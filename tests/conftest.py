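import numpy as np
import pytest

from radtex.volume_io import DiscretizedVolume, ROIMask, VolumeImage


def make_dvol(levels: np.ndarray, ng: int | None = None) -> DiscretizedVolume:
    """Wrap an integer level array (0 = outside mask) as a DiscretizedVolume."""
    levels = np.asarray(levels, dtype=np.int64)
    if levels.ndim == 2:
        levels = levels[:, :, None]
    ng = int(levels.max()) if ng is None else ng
    ng = max(ng, 1)
    return DiscretizedVolume(levels=levels, ng=ng, bin_edges=np.arange(ng + 1) + 0.5)


def random_dvol(rng: np.random.Generator, max_side: int = 8, max_ng: int = 5,
                mask_prob: float = 0.85) -> DiscretizedVolume:
    """Random small discretized volume with holes in the mask."""
    shape = tuple(rng.integers(4, max_side + 1, size=3))
    ng = int(rng.integers(2, max_ng + 1))
    levels = rng.integers(1, ng + 1, size=shape)
    mask = rng.random(shape) < mask_prob
    if not mask.any():
        mask.flat[0] = True
    levels = np.where(mask, levels, 0)
    return make_dvol(levels, ng=ng)


@pytest.fixture
def rng():
    return np.random.default_rng(20241001)


@pytest.fixture
def ball_mask():
    """Digitized ball of radius 15 voxels in a 35^3 grid, unit spacing."""
    n = 35
    c = (n - 1) / 2
    g = np.mgrid[0:n, 0:n, 0:n].astype(float)
    r2 = (g[0] - c) ** 2 + (g[1] - c) ** 2 + (g[2] - c) ** 2
    return ROIMask(data=r2 <= 15.0**2)


@pytest.fixture
def small_volume(rng):
    data = rng.normal(size=(10, 10, 10))
    vol = VolumeImage(data=data, spacing=(1.0, 1.0, 1.5))
    mask = ROIMask(data=np.ones((10, 10, 10), dtype=bool))
    return vol, mask
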