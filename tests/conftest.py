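import numpy as np
import pytest

from xirep import RegionMask, VoxelImage
from xirep.synthetic import NO_NOISE, get_preset


@pytest.fixture
def disc_image():
    """Bright 20x20 square (value 1000) on background 10; separable bimodal."""
    img = np.full((1, 64, 64), 10.0)
    img[0, 20:40, 20:40] = 1000.0
    return VoxelImage(img[None], ("DAPI",), (1.0, 0.1, 0.1))


@pytest.fixture
def quiet_scramble():
    """Scramble preset with noise disabled (exact bookkeeping)."""
    return get_preset("scramble", NO_NOISE)


def make_mask(shape, slicer, voxel_size=(1.0, 0.1, 0.1), label="nucleus"):
    m = np.zeros(shape, dtype=bool)
    m[slicer] = True
    return RegionMask(m, label, voxel_size)


@pytest.fixture
def ball_mask():
    """Voxelised sphere of radius 5 μm at 0.25 μm isotropic voxels."""
    r_um, v = 5.0, 0.25
    n = int(2 * r_um / v) + 5
    zz, yy, xx = np.ogrid[:n, :n, :n]
    c = (n - 1) / 2
    ball = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2) <= (r_um / v) ** 2
    return RegionMask(ball, "nucleus", (v, v, v))
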