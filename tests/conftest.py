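import numpy as np
import pytest
from scipy import ndimage

from hgtrack.config import RunConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_cfg():
    """Small config for fast learned-model tests."""
    cfg = RunConfig()
    cfg.model.hidden = 16
    cfg.model.widths = (8, 16, 32, 64)
    cfg.model.depths = (1, 1, 1, 1)
    cfg.model.stages_used = (0,)
    return cfg


def textured_image(rng, size=64, smooth=2.0):
    img = ndimage.gaussian_filter(rng.random((size, size)), smooth)
    return (img - img.min()) / (img.max() - img.min())


def subpixel_shift(img, u, v):
    """Shift image content by (+u, +v) pixels with reflective fill."""
    ys, xs = np.mgrid[0:img.shape[0], 0:img.shape[1]].astype(float)
    return ndimage.map_coordinates(img, [ys - v, xs - u], order=3, mode="reflect")


def numeric_grad(f, x, eps=1e-6):
    """Central-difference gradient of scalar f w.r.t. array x."""
    g = np.zeros_like(x, dtype=float)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g
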