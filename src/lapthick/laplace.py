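"""Convolutional Jacobi solver for Laplace's equation on the wall domain.

The potential field ``phi`` satisfies ``∇²phi = 0`` on WALL voxels with
Dirichlet clamps ``phi = 0`` on the lumen and ``phi = 1`` on the exterior,
and a zero normal-gradient (Neumann) condition on vessel end-cap faces.

Each Jacobi sweep is a convolution with a neighbour-averaging kernel followed
by re-clamping of the boundary regions. End caps are realized by replicate
padding across lattice faces (the ghost value equals the boundary value, so
the normal difference vanishes); non-cap lattice borders are padded the same
way but always carry clamped EXTERIOR voxels, making the choice inert there.

Convergence is monitored by the per-wall-voxel RMS change between successive
iterates (the "energy" of the update), which is non-increasing for this
symmetric iteration and independent of grid size.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grids import EXTERIOR, LUMEN, LabelGrid, validate_labels

logger = logging.getLogger(__name__)

BACKENDS = ("ndimage", "numpy")
STENCILS = ("standard", "extended")


@dataclass(frozen=True)
class SolverConfig:
    """Iteration controls for the Jacobi solve.

    ``tol`` is the threshold on the per-wall-voxel RMS change between
    consecutive iterates, making it resolution independent. ``stencil``
    selects the neighbour-averaging kernel: ``standard`` is the 5-point
    (2D) / 7-point (3D) cross; ``extended`` the 9-point / 27-point compact
    variant. ``check_every`` is how often (in iterations) convergence is
    evaluated.
    """

    tol: float = 1e-6
    max_iters: int = 20_000
    stencil: str = "standard"
    check_every: int = 10
    backend: str = "ndimage"

    def __post_init__(self):
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.stencil not in STENCILS:
            raise ValueError(f"stencil must be one of {STENCILS}")
        if self.backend not in BACKENDS:
            raise ValueError(f"backend must be one of {BACKENDS}")
        if self.check_every < 1:
            raise ValueError("check_every must be >= 1")


@dataclass
class PotentialField:
    """Scalar potential on the label lattice with solve diagnostics.

    Invariants: ``0 <= phi <= 1`` everywhere (discrete maximum principle);
    ``phi == 0`` on LUMEN and ``phi == 1`` on EXTERIOR at every recorded
    state.
    """

    phi: np.ndarray
    grid: LabelGrid
    converged: bool = False
    iterations: int = 0
    energy_trace: list[float] = field(default_factory=list)


def laplacian_kernel(rank: int, stencil: str = "standard") -> np.ndarray:
    """Neighbour-averaging convolution kernel (weights sum to 1, center 0).

    standard, rank 2
        cross of four 1/4 weights — the Jacobi update of the five-point
        stencil.
    standard, rank 3
        six face neighbours with weight 1/6 (seven-point stencil).
    extended, rank 2
        nine-point compact stencil: ``1/20 * [[1,4,1],[4,0,4],[1,4,1]]``.
    extended, rank 3
        27-point compact stencil: faces 14/128, edges 3/128, corners 1/128
        (off-center weights of the fourth-order compact Laplacian, whose
        center weight is -128/30 before normalization).
    """
    if rank not in (2, 3):
        raise ValueError(f"rank must be 2 or 3, got {rank}")
    if stencil not in STENCILS:
        raise ValueError(f"unknown stencil {stencil!r}")
    if stencil == "standard":
        k = np.zeros((3,) * rank)
        for ax in range(rank):
            idx = [1] * rank
            idx[ax] = 0
            k[tuple(idx)] = 1.0
            idx[ax] = 2
            k[tuple(idx)] = 1.0
        return k / (2 * rank)
    if rank == 2:
        k = np.array([[1.0, 4.0, 1.0], [4.0, 0.0, 4.0], [1.0, 4.0, 1.0]])
        return k / 20.0
    k = np.zeros((3, 3, 3))
    for i in range(3):
        for j in range(3):
            for l in range(3):
                n_off = (i != 1) + (j != 1) + (l != 1)
                k[i, j, l] = {0: 0.0, 1: 14.0, 2: 3.0, 3: 1.0}[n_off]
    return k / 128.0


def _convolve(phi: np.ndarray, kernel: np.ndarray, backend: str) -> np.ndarray:
    """Kernel correlation with replicate (edge) padding at lattice borders."""
    if backend == "ndimage":
        return ndimage.correlate(phi, kernel, mode="nearest")
    if backend == "numpy":
        padded = np.pad(phi, 1, mode="edge")
        out = np.zeros_like(phi)
        for offset in np.argwhere(kernel != 0):
            w = kernel[tuple(offset)]
            sl = tuple(slice(o, o + n) for o, n in zip(offset, phi.shape))
            out += w * padded[sl]
        return out
    raise ValueError(f"unknown backend {backend!r}")


def init_potential(grid: LabelGrid) -> PotentialField:
    """Initial field: 0 on LUMEN, 1 on EXTERIOR, and the boundary-value
    average (0.5) on WALL."""
    validate_labels(grid)
    phi = np.full(grid.shape, 0.5, dtype=np.float64)
    phi[grid.labels == LUMEN] = 0.0
    phi[grid.labels == EXTERIOR] = 1.0
    return PotentialField(phi=phi, grid=grid)


def jacobi_step(
    fieldP: PotentialField, kernel: np.ndarray, backend: str = "ndimage"
) -> PotentialField:
    """One Jacobi sweep: neighbour average on WALL, boundary regions re-clamped.

    Replicate padding across lattice faces gives the zero normal-gradient
    condition on cap faces; elsewhere the border is EXTERIOR-clamped anyway.
    """
    grid = fieldP.grid
    conv = _convolve(fieldP.phi, kernel, backend)
    phi = np.where(grid.wall_mask(), conv, fieldP.phi)
    phi[grid.labels == LUMEN] = 0.0
    phi[grid.labels == EXTERIOR] = 1.0
    return PotentialField(
        phi=phi,
        grid=grid,
        converged=fieldP.converged,
        iterations=fieldP.iterations + 1,
        energy_trace=list(fieldP.energy_trace),
    )


def energy(prev: PotentialField, nxt: PotentialField) -> float:
    """RMS change of the potential over WALL voxels between two states."""
    if prev.grid is not nxt.grid and not np.array_equal(
        prev.grid.labels, nxt.grid.labels
    ):
        raise ValueError("energy requires fields on the same grid")
    wall = prev.grid.wall_mask()
    diff = nxt.phi[wall] - prev.phi[wall]
    return float(np.sqrt(np.mean(diff * diff)))


def solve_laplace(grid: LabelGrid, cfg: SolverConfig | None = None) -> PotentialField:
    """Iterate Jacobi sweeps until the RMS update over wall voxels falls
    below ``cfg.tol`` or ``cfg.max_iters`` is reached.

    Deterministic; non-convergence is reported via ``converged=False`` and a
    warning, never an exception, so diagnostics are still produced on hard
    grids.
    """
    cfg = cfg or SolverConfig()
    fieldP = init_potential(grid)
    kernel = laplacian_kernel(grid.rank, cfg.stencil)
    wall = grid.wall_mask()
    base = np.where(grid.labels == EXTERIOR, 1.0, 0.0)

    phi = fieldP.phi
    trace: list[float] = []
    converged = False
    iters = 0
    while iters < cfg.max_iters:
        check = (iters + 1) % cfg.check_every == 0 or iters + 1 == cfg.max_iters
        prev_wall = phi[wall].copy() if check else None
        conv = _convolve(phi, kernel, cfg.backend)
        phi = np.where(wall, conv, base)
        iters += 1
        if check:
            diff = phi[wall] - prev_wall
            e = float(np.sqrt(np.mean(diff * diff)))
            trace.append(e)
            if e < cfg.tol:
                converged = True
                break
    if not converged:
        warnings.warn(
            f"Laplace solve did not converge in {iters} iterations "
            f"(last RMS update {trace[-1] if trace else float('nan'):.3g}, "
            f"tol {cfg.tol:g})",
            stacklevel=2,
        )
    logger.info(
        "laplace solve: %d iterations, converged=%s, final energy %.3g",
        iters, converged, trace[-1] if trace else float("nan"),
    )
    return PotentialField(
        phi=phi, grid=grid, converged=converged, iterations=iters, energy_trace=trace
    )
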