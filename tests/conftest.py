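import numpy as np
import pytest

from cdmip.cdm_encoding import build_depth_lut
from cdmip.core_model import AlignmentSpace, CDMImage, Volume3D


@pytest.fixture(scope="session")
def small_space():
    """64 x 32 x 16 voxels at 1 µm isotropic: fast, midline at x=32 µm."""
    return AlignmentSpace(
        name="test-64", shape_xyz=(64, 32, 16), voxel_size_um=(1.0, 1.0, 1.0)
    )


@pytest.fixture(scope="session")
def small_lut(small_space):
    return build_depth_lut(small_space.shape_xyz[2])


@pytest.fixture(scope="session")
def deep_space():
    """64 x 64 x 64 voxels at 1 µm: big enough z range for depth penalties."""
    return AlignmentSpace(
        name="test-deep", shape_xyz=(64, 64, 64), voxel_size_um=(1.0, 1.0, 1.0)
    )


@pytest.fixture(scope="session")
def deep_lut(deep_space):
    return build_depth_lut(deep_space.shape_xyz[2])


def make_cdm(space, lut, pixels_zyx, source_id="cdm", intensity=255):
    """CDM with foreground at given (x, y, z) triples, full saturation."""
    sx, sy, _ = space.shape_xyz
    px = np.zeros((sy, sx, 3), dtype=np.uint8)
    for x, y, z in pixels_zyx:
        px[y, x] = np.rint(lut.colors[z] * (intensity / 255.0)).astype(np.uint8)
    return CDMImage(space=space, pixels=px, source_id=source_id)


def random_cdm(space, lut, rng, density=0.05, source_id="rand"):
    """Random sparse CDM: each pixel independently foreground with random depth."""
    sx, sy, sz = space.shape_xyz
    fg = rng.random((sy, sx)) < density
    z = rng.integers(0, sz, size=(sy, sx))
    px = np.zeros((sy, sx, 3), dtype=np.uint8)
    px[fg] = lut.colors[z[fg]]
    return CDMImage(space=space, pixels=px, source_id=source_id)


def random_volume(space, rng, density=0.02, bit_depth=8):
    sz, sy, sx = space.shape_zyx
    data = np.zeros((sz, sy, sx), dtype=np.uint8)
    fg = rng.random((sz, sy, sx)) < density
    data[fg] = rng.integers(1, 256, size=int(fg.sum()))
    return Volume3D(space=space, data=data, bit_depth=bit_depth)
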