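import numpy as np
import pytest

from kbplan.core_grid import DoseGrid, StructureMask, VoxelGrid


@pytest.fixture
def unit_grid():
    return VoxelGrid(shape=(10, 10, 10), spacing=(1.0, 1.0, 1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def uniform_case(unit_grid):
    """A 5^3 cube structure receiving a uniform 50 Gy."""
    occ = np.zeros(unit_grid.shape, dtype=bool)
    occ[2:7, 2:7, 2:7] = True
    mask = StructureMask(grid=unit_grid, occupancy=occ, name="cube")
    dose = DoseGrid(
        grid=unit_grid, dose=np.full(unit_grid.shape, 50.0), prescription=70.0
    )
    return mask, dose
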