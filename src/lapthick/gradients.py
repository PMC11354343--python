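"""Sobel–Feldman gradients of the potential and the unit streamline field.

The streamline direction at a point is the normalized potential gradient
``n = ∇phi / ‖∇phi‖``. Gradients are estimated with the Sobel–Feldman
operator implemented as convolutions: in 2D the familiar 1/8-normalized
3×3 kernels; in 3D the separable smooth⊗smooth⊗derivative kernels with a
1/32 normalization. Both conventions make a unit-slope ramp yield a unit
gradient, and the positive component points toward increasing coordinate
and increasing potential.

Gradients are expressed per lattice step (the pipeline guarantees isotropic
spacing upstream; lengths are converted to mm only when accounting path
lengths). Off-lattice directions are obtained by multilinear interpolation
of the unit-field components followed by renormalization, so that direction
near the clamped boundary regions is not dominated by their large raw
gradient magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import LabelGrid
from .laplace import PotentialField

#: ramp normalization of the n-D Sobel operator: central difference (1/2)
#: times a [1,2,1]/4 smoothing on each orthogonal axis
_SOBEL_NORM = {2: 8.0, 3: 32.0}


@dataclass
class UnitGradientField:
    """Unit streamline directions on the lattice.

    ``n`` has shape ``(rank, *grid.shape)``; ``valid`` flags voxels whose raw
    gradient magnitude reached ``eps``. ``‖n‖ = 1`` at every valid voxel and
    ``n = 0`` at invalid ones. Directions are defined on the whole lattice
    (the clamped regions see the potential jump at their boundary), but only
    WALL voxels are measurement sites.
    """

    n: np.ndarray
    valid: np.ndarray
    grid: LabelGrid
    eps: float = 1e-8

    @property
    def rank(self) -> int:
        return self.grid.rank

    def invalid_wall_voxels(self) -> np.ndarray:
        """Indices of WALL voxels where no direction is defined."""
        return np.argwhere(self.grid.wall_mask() & ~self.valid)


def sobel_gradient(fieldP: PotentialField) -> np.ndarray:
    """Raw Sobel–Feldman gradient, shape ``(rank, *shape)``, per lattice step.

    Computed with replicate padding; values outside WALL are computed but
    unused downstream.
    """
    phi = fieldP.phi
    rank = phi.ndim
    norm = _SOBEL_NORM[rank]
    return np.stack(
        [ndimage.sobel(phi, axis=ax, mode="nearest") / norm for ax in range(rank)]
    )


def normalize(
    raw: np.ndarray, grid: LabelGrid, eps: float = 1e-8
) -> UnitGradientField:
    """Per-voxel division by the gradient magnitude.

    Voxels with magnitude below ``eps`` are flagged invalid (their direction
    is undefined, e.g. deep inside the clamped regions); invalidity is data,
    not an error.
    """
    mag = np.sqrt(np.sum(raw * raw, axis=0))
    valid = mag >= eps
    n = np.where(valid, raw / np.where(valid, mag, 1.0), 0.0)
    return UnitGradientField(n=n, valid=valid, grid=grid, eps=eps)


def unit_gradient_field(fieldP: PotentialField, eps: float = 1e-8) -> UnitGradientField:
    """Convenience: Sobel gradient of the potential, then normalization."""
    return normalize(sobel_gradient(fieldP), fieldP.grid, eps=eps)


def sample_direction(
    fieldU: UnitGradientField, p: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Streamline direction at continuous voxel coordinates.

    ``p`` is an ``(m, rank)`` batch (a single point may be given as a 1-D
    array). Components of the unit field are interpolated multilinearly and
    the result renormalized; points where the interpolated magnitude falls
    below ``eps`` are flagged invalid. Callers must keep ``p`` inside the
    lattice bounds (the tracer checks bounds before sampling).

    Returns
    -------
    (directions, valid): arrays of shape ``(m, rank)`` and ``(m,)``.
    """
    p = np.atleast_2d(np.asarray(p, dtype=np.float64))
    coords = p.T
    comps = np.stack(
        [
            ndimage.map_coordinates(fieldU.n[c], coords, order=1, mode="nearest")
            for c in range(fieldU.rank)
        ],
        axis=1,
    )
    mag = np.sqrt(np.sum(comps * comps, axis=1))
    valid = mag >= fieldU.eps
    safe = np.where(valid, mag, 1.0)
    return comps / safe[:, None], valid
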