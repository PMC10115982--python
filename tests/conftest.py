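import numpy as np
import pytest

from oareval import BinaryMask, VoxelGrid


@pytest.fixture
def iso_grid():
    """24^3 grid, 1 mm isotropic, origin at 0."""
    return VoxelGrid((0.0, 0.0, 0.0), (1.0, 1.0, 1.0), (24, 24, 24))


@pytest.fixture
def aniso_grid():
    """Planning-CT-like anisotropic grid (1.27 x 1.27 x 2 mm)."""
    return VoxelGrid((0.0, 0.0, 0.0), (1.27, 1.27, 2.0), (24, 24, 16))


def sphere_mask(grid: VoxelGrid, center, radius) -> BinaryMask:
    xs = grid.axis_centers(0)[:, None, None]
    ys = grid.axis_centers(1)[None, :, None]
    zs = grid.axis_centers(2)[None, None, :]
    occ = (xs - center[0]) ** 2 + (ys - center[1]) ** 2 + (zs - center[2]) ** 2 \
        <= radius ** 2
    return BinaryMask(grid, occ)


def cube_mask(grid: VoxelGrid, lo_idx, size_vox) -> BinaryMask:
    occ = np.zeros(grid.shape, dtype=bool)
    sl = tuple(slice(l, l + s) for l, s in zip(lo_idx, size_vox))
    occ[sl] = True
    return BinaryMask(grid, occ)
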