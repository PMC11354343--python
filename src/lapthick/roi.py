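"""ROI morphometrics: areas, normalized indices, thickness statistics.

Given manually drawn regions of interest on a vessel section (lumen, outer
wall, and plaque components such as calcifications, hemorrhages, lipid pools
or loose extracellular matrix), this module computes the standard
morphological report: the ROI area (volume in 3D), the normalized index
(ROI area divided by the total vessel area, where total = lumen + wall), and
the mean ± standard deviation of the wall thickness and of the
distance-to-lumen over the ROI's wall voxels.

Standard deviations are population (divide-by-N) values; ROI voxel counts
are large enough that the distinction is below reporting precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import LabelGrid
from .thickness import ThicknessResult

ROI_TYPES = (
    "lumen",
    "outer_wall",
    "calcification",
    "hemorrhage",
    "lipid_pool",
    "loose_matrix",
    "other",
)


@dataclass(frozen=True)
class ROI:
    """A named region: boolean mask on the grid plus a type tag."""

    mask: np.ndarray
    roi_type: str = "other"

    def __post_init__(self):
        if self.roi_type not in ROI_TYPES:
            raise ValueError(f"roi_type must be one of {ROI_TYPES}")


@dataclass
class ROISet:
    """Mapping of ROI ids to regions on a common grid. ROIs may overlap
    (plaque components typically lie inside the outer-wall ROI)."""

    rois: dict[str, ROI]
    grid: LabelGrid

    def __post_init__(self):
        for key, roi in self.rois.items():
            if roi.mask.shape != self.grid.shape:
                raise ValueError(f"ROI {key!r} mask shape {roi.mask.shape} does "
                                 f"not match grid {self.grid.shape}")


def roi_area(mask: np.ndarray, grid: LabelGrid) -> float:
    """Area (mm², rank 2) or volume (mm³, rank 3): voxel count × h^rank."""
    return float(np.count_nonzero(mask)) * grid.h ** grid.rank


def normalized_index(roi_area_: float, lumen_area: float, wall_area: float) -> float:
    """ROI area divided by the total vessel area (lumen + wall)."""
    if roi_area_ < 0 or lumen_area < 0 or wall_area < 0:
        raise ValueError("areas must be non-negative")
    total = lumen_area + wall_area
    if total <= 0:
        raise ValueError("total vessel area (lumen + wall) is zero; "
                         "normalized index undefined")
    return roi_area_ / total


@dataclass(frozen=True)
class ROIThicknessStats:
    """Thickness and distance-to-lumen statistics over ROI ∩ WALL ∩ ok."""

    thickness_mean: float
    thickness_std: float
    dist_lumen_mean: float
    dist_lumen_std: float
    n_voxels: int


def roi_thickness_stats(mask: np.ndarray, result: ThicknessResult) -> ROIThicknessStats:
    """Mean/std of wall thickness and distance-to-lumen within an ROI.

    Statistics are voxel-weighted over the ROI's successfully traced wall
    voxels. Raises when the ROI does not intersect the traced wall.
    """
    sel = mask & result.ok_mask()
    n = int(np.count_nonzero(sel))
    if n == 0:
        raise ValueError("ROI has no successfully traced wall voxels (count 0)")
    t = result.T[sel]
    dl = result.T_minus[sel]
    return ROIThicknessStats(
        thickness_mean=float(np.mean(t)),
        thickness_std=float(np.std(t)),
        dist_lumen_mean=float(np.mean(dl)),
        dist_lumen_std=float(np.std(dl)),
        n_voxels=n,
    )


def roi_report(
    roiset: ROISet,
    result: ThicknessResult | None = None,
    lumen_area: float | None = None,
    wall_area: float | None = None,
) -> pd.DataFrame:
    """Morphometric table: one row per ROI.

    Columns: roi, type, area (mm² or mm³), normalized_index, thickness
    mean/std and distance-to-lumen mean/std (NaN for ROIs without traced wall
    voxels, e.g. the lumen). The total vessel area defaults to the grid's
    lumen + wall regions but can be overridden with explicit areas (e.g. when
    the lumen/outer-wall ROIs are drawn rather than encoded as labels).
    """
    grid = roiset.grid
    if lumen_area is None:
        lumen_area = roi_area(grid.lumen_mask(), grid)
    if wall_area is None:
        wall_area = roi_area(grid.wall_mask(), grid)
    rows = []
    for key, roi in roiset.rois.items():
        area = roi_area(roi.mask, grid)
        row: dict[str, object] = {
            "roi": key,
            "type": roi.roi_type,
            "area": area,
            "normalized_index": normalized_index(area, lumen_area, wall_area),
            "thickness_mean": np.nan,
            "thickness_std": np.nan,
            "dist_lumen_mean": np.nan,
            "dist_lumen_std": np.nan,
            "n_wall_voxels": 0,
        }
        if result is not None and roi.roi_type != "lumen":
            sel = roi.mask & result.ok_mask()
            if sel.any():
                stats = roi_thickness_stats(roi.mask, result)
                row.update(
                    thickness_mean=stats.thickness_mean,
                    thickness_std=stats.thickness_std,
                    dist_lumen_mean=stats.dist_lumen_mean,
                    dist_lumen_std=stats.dist_lumen_std,
                    n_wall_voxels=stats.n_voxels,
                )
        rows.append(row)
    return pd.DataFrame(rows)
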