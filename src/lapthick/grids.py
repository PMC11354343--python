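"""Label lattices and the preprocessing applied before thickness measurement.

A :class:`LabelGrid` is the domain of every other operation in the package:
an integer lattice of rank 2 or 3 whose voxels carry one of three codes
(:data:`EXTERIOR`, :data:`LUMEN`, :data:`WALL`), plus the physical spacing
``h`` per axis in mm, the physical coordinate of the first voxel center, and
the set of lattice faces that act as vessel end caps (zero normal-gradient
boundaries for the potential solve).

Preprocessing mirrors what is done on real segmentation masks before
measuring: resample anisotropic voxels to the finest spacing present, then
optionally upsample by an integer factor with Gaussian smoothing of the
per-label indicators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

EXTERIOR = 0
LUMEN = 1
WALL = 2

#: argmax precedence when relabelling smoothed/resampled indicators:
#: ties never erode the measurement domain.
_PRECEDENCE = (WALL, LUMEN, EXTERIOR)

# A cap face is (axis, side) with side 0 = low-index face, 1 = high-index face.
CapFace = tuple[int, int]


class LabelGridError(ValueError):
    """Raised when a label lattice violates the three-code contract."""


@dataclass(frozen=True)
class LabelGrid:
    """Segmentation lattice: lumen / wall / exterior labels with geometry.

    Parameters
    ----------
    labels:
        Integer array of rank 2 or 3 containing only the codes
        ``EXTERIOR=0``, ``LUMEN=1``, ``WALL=2``.
    spacing:
        Physical size of one lattice step per axis, in mm.
    origin:
        Physical coordinate (mm) of the center of voxel ``(0, ..., 0)``.
    cap_faces:
        Lattice boundary faces flagged as vessel end caps; the potential
        solver applies a zero normal-gradient (Neumann) condition there.
    """

    labels: np.ndarray
    spacing: tuple[float, ...]
    origin: tuple[float, ...] = ()
    cap_faces: frozenset[CapFace] = field(default_factory=frozenset)

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim not in (2, 3):
            raise LabelGridError(f"labels must have rank 2 or 3, got {labels.ndim}")
        object.__setattr__(self, "labels", labels)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != labels.ndim:
            raise LabelGridError("spacing length must match lattice rank")
        if any(s <= 0 for s in spacing):
            raise LabelGridError(f"spacing must be strictly positive, got {spacing}")
        object.__setattr__(self, "spacing", spacing)
        origin = tuple(float(o) for o in self.origin) or (0.0,) * labels.ndim
        if len(origin) != labels.ndim:
            raise LabelGridError("origin length must match lattice rank")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "cap_faces", frozenset(self.cap_faces))

    @property
    def rank(self) -> int:
        return self.labels.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    @property
    def is_isotropic(self) -> bool:
        return len(set(self.spacing)) == 1

    @property
    def h(self) -> float:
        """Isotropic grid spacing in mm; defined only after isotropy holds."""
        if not self.is_isotropic:
            raise LabelGridError(
                f"grid is anisotropic {self.spacing}; resample_isotropic first"
            )
        return self.spacing[0]

    def wall_mask(self) -> np.ndarray:
        return self.labels == WALL

    def lumen_mask(self) -> np.ndarray:
        return self.labels == LUMEN

    def exterior_mask(self) -> np.ndarray:
        return self.labels == EXTERIOR

    def label_counts(self) -> dict[int, int]:
        return {
            code: int(np.count_nonzero(self.labels == code))
            for code in (EXTERIOR, LUMEN, WALL)
        }


@dataclass(frozen=True)
class PreprocessConfig:
    """Upsampling/smoothing applied to masks before measurement.

    ``upsample_factor=3`` with a Gaussian filter is the preprocessing used on
    in vivo segmentation masks; ``gaussian_sigma`` is in upsampled voxels.
    """

    upsample_factor: int = 3
    gaussian_sigma: float = 0.5
    resample_order: int = 1

    def __post_init__(self):
        if self.upsample_factor < 1:
            raise ValueError("upsample_factor must be >= 1")
        if self.gaussian_sigma < 0:
            raise ValueError("gaussian_sigma must be >= 0")


def validate_labels(grid: LabelGrid) -> LabelGrid:
    """Check the three-code contract and a nonempty measurement domain.

    Returns the grid unchanged when it contains only the codes
    {EXTERIOR, LUMEN, WALL} and at least one WALL voxel.

    Raises
    ------
    LabelGridError
        Naming the offending codes, or "no wall to measure" when the WALL
        set is empty.
    """
    present = np.unique(grid.labels)
    unknown = sorted(set(present.tolist()) - {EXTERIOR, LUMEN, WALL})
    if unknown:
        raise LabelGridError(
            f"unknown label code(s) {unknown}; expected only "
            f"EXTERIOR={EXTERIOR}, LUMEN={LUMEN}, WALL={WALL}"
        )
    if WALL not in present:
        raise LabelGridError("no wall to measure (zero WALL voxels)")
    return grid


def _argmax_relabel(indicators: list[np.ndarray]) -> np.ndarray:
    """Relabel from per-label indicator images, ties won by WALL > LUMEN > EXTERIOR."""
    stack = np.stack([indicators[code] for code in _PRECEDENCE])
    # np.argmax returns the first maximum, and the stack is ordered by precedence
    winner = np.argmax(stack, axis=0)
    out = np.empty(winner.shape, dtype=np.uint8)
    for idx, code in enumerate(_PRECEDENCE):
        out[winner == idx] = code
    return out


def resample_isotropic(grid: LabelGrid, order: int = 1) -> LabelGrid:
    """Resample an anisotropic grid to the minimum spacing on all axes.

    Each label's indicator is interpolated independently (spline ``order``)
    and the output label is the argmax of the resampled indicators, ties
    broken WALL > LUMEN > EXTERIOR so thin walls are never eroded by ties.
    Always upsamples (target = finest input spacing), never downsamples.
    """
    validate_labels(grid)
    if grid.is_isotropic:
        return grid
    target = min(grid.spacing)
    zoom = tuple(s / target for s in grid.spacing)
    indicators = [
        ndimage.zoom(
            (grid.labels == code).astype(np.float32), zoom, order=order,
            mode="nearest", grid_mode=True,
        )
        for code in (EXTERIOR, LUMEN, WALL)
    ]
    labels = _argmax_relabel(indicators)
    return LabelGrid(
        labels=labels,
        spacing=(target,) * grid.rank,
        origin=grid.origin,
        cap_faces=grid.cap_faces,
    )


def _breach_location(lumen: np.ndarray, exterior: np.ndarray) -> tuple[int, ...]:
    contact = ndimage.binary_dilation(lumen) & exterior
    idx = np.argwhere(contact)
    return tuple(int(i) for i in idx[0])


def check_wall_integrity(grid: LabelGrid) -> None:
    """Ensure lumen and exterior stay separated by wall (no face adjacency)."""
    lumen = grid.lumen_mask()
    exterior = grid.exterior_mask()
    if not lumen.any() or not exterior.any():
        return
    contact = ndimage.binary_dilation(lumen) & exterior
    if contact.any():
        loc = _breach_location(lumen, exterior)
        raise LabelGridError(
            f"wall breached: lumen touches exterior at voxel {loc} "
            "(smoothing or resampling merged the two boundary regions)"
        )


def upsample_and_smooth(grid: LabelGrid, cfg: PreprocessConfig | None = None) -> LabelGrid:
    """Upsample each label indicator by an integer factor, Gaussian-smooth, relabel.

    Spacing is divided by the factor. With ``gaussian_sigma=0`` the result is a
    pure nearest (block) upsampling, so label counts scale exactly by
    ``factor**rank``. After relabelling, the lumen and exterior regions must
    remain separated by wall; a breach raises with the offending location.
    """
    cfg = cfg or PreprocessConfig()
    validate_labels(grid)
    if not grid.is_isotropic:
        raise LabelGridError("upsample_and_smooth requires an isotropic grid")
    f = cfg.upsample_factor
    if f == 1 and cfg.gaussian_sigma == 0:
        return grid

    def block_upsample(a: np.ndarray) -> np.ndarray:
        for ax in range(a.ndim):
            a = np.repeat(a, f, axis=ax)
        return a

    indicators = []
    for code in (EXTERIOR, LUMEN, WALL):
        ind = block_upsample((grid.labels == code).astype(np.float32))
        if cfg.gaussian_sigma > 0:
            ind = ndimage.gaussian_filter(ind, cfg.gaussian_sigma, mode="nearest")
        indicators.append(ind)
    labels = _argmax_relabel(indicators)

    h = grid.h / f
    # voxel centers shift: the first fine voxel center sits half a coarse
    # voxel minus half a fine voxel before the coarse center
    shift = (grid.h - h) / 2.0
    out = LabelGrid(
        labels=labels,
        spacing=(h,) * grid.rank,
        origin=tuple(o - shift for o in grid.origin),
        cap_faces=grid.cap_faces,
    )
    check_wall_integrity(out)
    return out


def wall_layer_adjacent_to_lumen(grid: LabelGrid) -> np.ndarray:
    """First wall-voxel layer on the lumen side (the 'inner surface' layer)."""
    return grid.wall_mask() & ndimage.binary_dilation(grid.lumen_mask())


def warn_if_thin_wall(grid: LabelGrid, min_voxels: int = 4) -> bool:
    """Warn when the wall spans fewer than ``min_voxels`` lattice steps.

    Thickness tracing needs a few voxels of wall to resolve the potential
    gradient; below ~4 voxels the measurement is unreliable. Returns True if
    a warning was emitted.
    """
    wall = grid.wall_mask()
    if not wall.any():
        return False
    edt = ndimage.distance_transform_edt(~grid.lumen_mask())
    span = float(edt[wall].max())
    if span < min_voxels:
        warnings.warn(
            f"wall spans only ~{span:.1f} voxels; thickness measurement is "
            "unreliable at this resolution",
            stacklevel=2,
        )
        return True
    return False


def with_labels(grid: LabelGrid, labels: np.ndarray) -> LabelGrid:
    """Copy of ``grid`` with a new label array (same geometry)."""
    return replace(grid, labels=labels)
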