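import numpy as np
import pytest

import lapthick as lt


@pytest.fixture(scope="session")
def ring10():
    """Circular ring phantom at 10 px/mm (inner 1.5 mm, wall 1.5 mm)."""
    return lt.generate_phantom(lt.PhantomSpec(shape="circular_ring", resolution=10))


@pytest.fixture(scope="session")
def ring20_solved():
    """Solved potential on the circular ring at 20 px/mm."""
    grid = lt.generate_phantom(lt.PhantomSpec(shape="circular_ring", resolution=20))
    fieldP = lt.solve_laplace(grid, lt.SolverConfig(tol=1e-7))
    return grid, fieldP


@pytest.fixture(scope="session")
def ring20_thickness(ring20_solved):
    grid, fieldP = ring20_solved
    fieldU = lt.unit_gradient_field(fieldP)
    return grid, fieldU, lt.compute_thickness(fieldU)


@pytest.fixture(scope="session")
def slab_grid():
    """Flat slab: lumen | 15-voxel wall | exterior at h=0.1 mm, Neumann sides.

    The wall is 1.5 mm wide; the potential is linear across it.
    """
    labels = np.full((40, 21), lt.WALL, dtype=np.uint8)
    labels[:, :3] = lt.LUMEN
    labels[:, -3:] = lt.EXTERIOR
    return lt.LabelGrid(
        labels=labels, spacing=(0.1, 0.1), cap_faces={(0, 0), (0, 1)}
    )


@pytest.fixture(scope="session")
def slab_solved(slab_grid):
    return lt.solve_laplace(slab_grid, lt.SolverConfig(tol=1e-9))


def radial_coordinates(grid):
    """Physical radius of each voxel center from the lattice origin point."""
    axes = [np.arange(n) * grid.h + o for n, o in zip(grid.shape, grid.origin)]
    mesh = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(sum(m * m for m in mesh))
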