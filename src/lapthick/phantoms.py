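"""Digital validation phantoms with analytically known, uniform wall thickness.

Each phantom is a label grid whose wall has thickness exactly ``d`` mm
everywhere by construction: the lumen is the region inside an inner surface,
and the wall is the set of points whose Euclidean distance to that inner
surface lies in ``(0, d]``. The outer boundary is therefore the Euclidean
*offset* of the inner surface — concentric for circle/sphere/pipe, and the
true offset curve/surface (not a scaled copy) for the ellipse/ellipsoid,
which is what makes the ground truth uniform.

Available shapes
----------------
``circular_ring``        2D annulus, inner radius ``r``.
``elliptical_ring``      2D, inner ellipse semi-axes ``r1 >= r2``.
``half_spherical_shell`` 3D hemisphere shell, equatorial cap plane (Neumann).
``half_ellipsoid_shell`` 3D, inner ellipsoid semi-axes ``r1, r2, r3``, cap plane.
``bent_pipe``            3D quarter-torus tube, axis radius ``R``, two cap planes.

Signed distances to the inner surface are exact: closed form for the circle,
sphere and bent pipe, and a machine-precision root solve of the foot-point
equation for the ellipse/ellipsoid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grids import EXTERIOR, LUMEN, WALL, LabelGrid

SHAPES_2D = ("circular_ring", "elliptical_ring")
SHAPES_3D = ("half_spherical_shell", "half_ellipsoid_shell", "bent_pipe")
SHAPES = SHAPES_2D + SHAPES_3D

#: resolutions (lattice steps per mm) used in the validation experiments
RESOLUTIONS_2D = (2, 5, 10, 20, 50, 100, 200)
RESOLUTIONS_3D = (2, 5, 10)


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a validation shape.

    Defaults reproduce the standard validation geometry: inner radius
    1.5 mm, uniform wall thickness ``d = 1.5`` mm; the elliptical ring uses
    semi-axes 1.5/1.0 mm and the half-ellipsoid 2.0/1.5/1.0 mm; the bent
    pipe's quarter-circle axis has radius ``R = 4.5`` mm.

    ``resolution`` is in lattice steps per mm, so the grid spacing is
    ``h = 1/resolution``. ``margin`` is exterior padding in voxels on
    non-cap faces.
    """

    shape: str
    r: float = 1.5
    r1: float = 1.5
    r2: float = 1.0
    r3: float = 1.0
    R: float = 4.5
    d: float = 1.5
    resolution: float = 10.0
    margin: int = 4

    def __post_init__(self):
        if self.shape not in SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}; expected one of {SHAPES}")
        if self.d <= 0:
            raise ValueError("wall thickness d must be > 0")
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0")
        for name in ("r", "r1", "r2", "r3", "R"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def h(self) -> float:
        return 1.0 / self.resolution

    @property
    def rank(self) -> int:
        return 2 if self.shape in SHAPES_2D else 3


def _full_axis(extent: float, h: float) -> np.ndarray:
    """Voxel-center coordinates symmetric about 0, covering |x| <= extent."""
    m = int(np.ceil(extent / h))
    return (np.arange(-m, m + 1)) * h


def _capped_axis(extent: float, h: float) -> np.ndarray:
    """Voxel-center coordinates starting half a step above the cap plane at 0."""
    n = int(np.ceil(extent / h - 0.5)) + 1
    return (np.arange(n) + 0.5) * h


def _ellipse_boundary_distance(
    pts: np.ndarray, semi_axes: tuple[float, ...], n_iter: int = 120
) -> np.ndarray:
    """Exact unsigned distance from points to an ellipse (2D) or ellipsoid
    (3D) boundary.

    The foot point of ``y`` on the boundary is ``x_i = e_i² y_i / (t + e_i²)``
    where ``t`` is the unique root of
    ``F(t) = Σ (e_i y_i / (t + e_i²))² − 1`` on ``(−min(e_i²), ∞)``;
    ``F`` is strictly decreasing there, so bisection converges to machine
    precision. Points are folded into the positive orthant (the boundary is
    axis-symmetric) and components are nudged off the axes by 1e-12 mm so the
    bracket endpoint stays a pole of ``F``.
    """
    semi = np.asarray(semi_axes, dtype=np.float64)
    e2 = semi**2
    y = np.abs(np.asarray(pts, dtype=np.float64)) + 1e-12
    ey2 = (semi * y) ** 2

    def F(t):
        return np.sum(ey2 / (t[:, None] + e2) ** 2, axis=1) - 1.0

    lo = np.full(y.shape[0], -e2.min() * (1.0 - 1e-12))
    hi = np.full(y.shape[0], semi.max() * (np.linalg.norm(y, axis=1) + semi.max()))
    for _ in range(100):
        too_low = F(hi) > 0
        if not too_low.any():
            break
        hi[too_low] *= 2.0
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        above = F(mid) > 0
        lo = np.where(above, mid, lo)
        hi = np.where(above, hi, mid)
    t = 0.5 * (lo + hi)
    foot = e2 * y / (t[:, None] + e2)
    return np.sqrt(np.sum((foot - y) ** 2, axis=1))


def _signed_distance_to_inner_surface(spec: PhantomSpec, coords: list[np.ndarray]) -> np.ndarray:
    """Signed Euclidean distance (negative inside) from voxel centers to the
    phantom's inner surface."""
    mesh = np.meshgrid(*coords, indexing="ij")
    if spec.shape == "circular_ring":
        return np.hypot(mesh[0], mesh[1]) - spec.r
    if spec.shape == "half_spherical_shell":
        return np.sqrt(mesh[0] ** 2 + mesh[1] ** 2 + mesh[2] ** 2) - spec.r
    if spec.shape == "bent_pipe":
        # quarter-circle axis of radius R in the xy-plane; all grid points have
        # x, y >= 0 so the foot point on the full circle lies on the quarter arc
        rho = np.hypot(mesh[0], mesh[1])
        return np.sqrt((rho - spec.R) ** 2 + mesh[2] ** 2) - spec.r
    if spec.shape == "elliptical_ring":
        semi = (spec.r1, spec.r2)
    else:  # half_ellipsoid_shell
        semi = (spec.r1, spec.r2, spec.r3)
    pts = np.column_stack([m.ravel() for m in mesh])
    dist = _ellipse_boundary_distance(pts, semi)
    inside = sum((m / s) ** 2 for m, s in zip(mesh, semi)).ravel() <= 1.0
    dist[inside] *= -1.0
    return dist.reshape(mesh[0].shape)


def generate_phantom(spec: PhantomSpec) -> LabelGrid:
    """Rasterize a phantom to a label grid at ``spec.resolution``.

    Voxel centers are classified by signed distance ``s`` to the inner
    surface: LUMEN where ``s <= 0``, WALL where ``0 < s <= d``, EXTERIOR
    otherwise. Cap planes of the half-shells and the bent pipe coincide with
    lattice faces and are recorded in ``cap_faces`` for Neumann treatment.

    A warning is emitted when the wall spans fewer than 4 voxels (thickness
    measurement is unreliable at such resolutions).
    """
    h = spec.h
    pad = spec.margin * h
    if spec.shape == "circular_ring":
        ext = spec.r + spec.d + pad
        coords = [_full_axis(ext, h)] * 2
        cap_faces: set[tuple[int, int]] = set()
    elif spec.shape == "elliptical_ring":
        coords = [
            _full_axis(spec.r1 + spec.d + pad, h),
            _full_axis(spec.r2 + spec.d + pad, h),
        ]
        cap_faces = set()
    elif spec.shape == "half_spherical_shell":
        ext = spec.r + spec.d + pad
        coords = [_full_axis(ext, h), _full_axis(ext, h), _capped_axis(ext, h)]
        cap_faces = {(2, 0)}
    elif spec.shape == "half_ellipsoid_shell":
        coords = [
            _full_axis(spec.r1 + spec.d + pad, h),
            _full_axis(spec.r2 + spec.d + pad, h),
            _capped_axis(spec.r3 + spec.d + pad, h),
        ]
        cap_faces = {(2, 0)}
    else:  # bent_pipe
        ext_xy = spec.R + spec.r + spec.d + pad
        ext_z = spec.r + spec.d + pad
        coords = [_capped_axis(ext_xy, h), _capped_axis(ext_xy, h), _full_axis(ext_z, h)]
        cap_faces = {(0, 0), (1, 0)}

    sdist = _signed_distance_to_inner_surface(spec, coords)
    labels = np.full(sdist.shape, EXTERIOR, dtype=np.uint8)
    labels[sdist <= 0.0] = LUMEN
    labels[(sdist > 0.0) & (sdist <= spec.d)] = WALL

    if spec.d * spec.resolution < 4:
        warnings.warn(
            f"wall is only ~{spec.d * spec.resolution:.1f} voxels thick at "
            f"{spec.resolution} steps/mm; thickness measurement is unreliable",
            stacklevel=2,
        )

    return LabelGrid(
        labels=labels,
        spacing=(h,) * spec.rank,
        origin=tuple(float(c[0]) for c in coords),
        cap_faces=frozenset(cap_faces),
    )
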