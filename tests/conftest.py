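import numpy as np
import pytest

from gliometry.io import Config
from gliometry.segmentation import ArborMask
from gliometry.synth import SynthConfig, make_atlas


@pytest.fixture
def cfg():
    return Config()


@pytest.fixture
def atlas():
    return make_atlas((256, 256), pixel_size_um=(0.2, 0.2))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def mask_from_bool(grid, pixel_size=(0.2, 0.2), nucleus_yx_um=None, cell_id=0):
    """Wrap a boolean grid as an ArborMask with a sensible nucleus."""
    grid = np.asarray(grid, dtype=bool)
    if nucleus_yx_um is None:
        ys, xs = np.nonzero(grid)
        nucleus_yx_um = (float(ys.mean()) * pixel_size[0], float(xs.mean()) * pixel_size[1])
    return ArborMask(
        cell_id=cell_id, mask=grid, nucleus_yx_um=nucleus_yx_um, pixel_size_um=pixel_size
    )


def ellipse_mask(a_um, b_um, angle_deg=0.0, pixel_size=0.2, pad_um=4.0):
    """Rasterized filled ellipse with semi-axes a (along the rotated y axis)."""
    half = a_um + pad_um
    n = int(round(2 * half / pixel_size)) + 1
    yy, xx = np.mgrid[0:n, 0:n] * pixel_size - half
    t = np.radians(angle_deg)
    u = yy * np.cos(t) + xx * np.sin(t)
    v = -yy * np.sin(t) + xx * np.cos(t)
    grid = (u / a_um) ** 2 + (v / b_um) ** 2 <= 1.0
    return mask_from_bool(grid, (pixel_size, pixel_size))


@pytest.fixture
def ms_like_cfg():
    """Midline-concentrated, fixed-length arbors (noise-free rendering)."""
    return SynthConfig(seed=7, branch_length_sd_um=0.0, noise_sd=0.0, orientation_kappa=8.0)
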