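import numpy as np
import pytest

from contourqa.volumes import StructureMask, VoxelGrid


@pytest.fixture
def unit_grid():
    """10x10x10 grid at 1 mm isotropic spacing, origin at 0."""
    return VoxelGrid(origin=(0, 0, 0), spacing=(1, 1, 1), dims=(10, 10, 10))


def mask_from_indices(grid: VoxelGrid, indices, name="m") -> StructureMask:
    occ = np.zeros(grid.dims, dtype=bool)
    for idx in indices:
        occ[tuple(idx)] = True
    return StructureMask(name, grid, occ)


def cube_mask(grid: VoxelGrid, lo, hi, name="m") -> StructureMask:
    """Axis-aligned filled box of voxel indices lo (incl.) .. hi (excl.)."""
    occ = np.zeros(grid.dims, dtype=bool)
    occ[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
    return StructureMask(name, grid, occ)


def random_mask(grid: VoxelGrid, rng, p=0.3, name="m") -> StructureMask:
    occ = rng.random(grid.dims) < p
    return StructureMask(name, grid, occ)
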