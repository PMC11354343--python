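# Methods

## Model

Thickness between two boundaries is defined through a harmonic potential:
φ solves ∇²φ = 0 on the wall with Dirichlet values 0 on the lumen side and
1 on the exterior side, and zero normal gradient (Neumann) on designated end
caps. The thickness at a point is the combined arc length of the two
streamlines of n̂ = ∇φ/‖∇φ‖ through that point, one ending on each boundary
(T = T⁺ + T⁻, where T⁻ is the distance to the lumen and T⁺ the distance to
the outer wall). The definition is self-consistent for non-parallel
boundaries because the equipotential surfaces of a harmonic field never
cross: they foliate the wall into locally parallel sublayers.

Assumptions: the wall is a single connected layer separating lumen from
exterior; boundaries are resolved by at least a few voxels (≈4 across the
wall is a practical floor — below that the gradient field is too coarse and
the package warns); voxels are isotropic by the time the solver runs
(anisotropic inputs are resampled first).

## Discretization and numerical choices

**Lattice and labels.** Label codes are fixed internally as EXTERIOR=0,
LUMEN=1, WALL=2 (I/O remaps arbitrary codes). Voxel indexing is 0-based with
the voxel-center convention: physical position = origin + index × h. All
tracing happens in voxel coordinates; lengths convert to mm only when path
lengths are accounted (steps × γ × h).

**Jacobi solve as convolution.** Each sweep convolves φ with a
neighbour-averaging kernel and re-clamps the lumen (0) and exterior (1)
regions. The standard kernel is the 5-point cross (2D, weights ¼) or
7-point face-neighbour average (3D, weights 1/6). An `extended` variant is
available for robustness studies: the 9-point compact stencil
1/20·[1 4 1; 4 0 4; 1 4 1] in 2D and its 27-point compact counterpart in 3D
(faces 14/128, edges 3/128, corners 1/128 — the off-center weights of the
fourth-order compact Laplacian). All kernels sum to one, so constants are
fixed points and the discrete maximum principle holds: φ stays in [0, 1]
with the extremes attained only on the clamped regions.

**Boundary realization.** The Dirichlet conditions clamp the *full* lumen
and exterior regions every iteration — the simplest stable discretization.
Its consequence: the effective Dirichlet surface of the discrete problem
lies at the clamped voxel layer, i.e. about half a voxel *outside* the wall
on each side, with an additional local staircase of amplitude ≤ h/2 from
rasterizing a curved boundary on the lattice. Both effects vanish with
resolution. Closed-form comparisons in the tests therefore use the
clamped-layer radii (e.g. r₀ − h/2, r₁ + h/2 for the annulus and shell
profiles); with nominal radii the same fields show the expected half-voxel
systematic offset. In 3D at 10 voxels/mm the staircase still dominates the
*tail* of the potential error (max deviation ≈0.04 at staircase-adjacent
voxels against ≈0.01 in the interior), which is why shell-profile checks
bound the median and upper percentiles rather than the maximum.

**Neumann caps.** Cap faces are lattice boundary faces; replicate (edge)
padding during the convolution makes the ghost value equal the boundary
value, so the normal difference is exactly zero — verified equivalent to an
explicit mirror ghost-cell construction to machine precision. Non-cap
lattice borders use the same padding but always carry clamped exterior
voxels, so the choice is inert there.

**Convergence.** The "energy" monitored is the RMS change of φ over wall
voxels between consecutive sweeps, making the tolerance (default 1e-6)
independent of grid size; it is checked every 10 sweeps. The Jacobi
iteration matrix is symmetric with spectral radius < 1 on the wall, so this
quantity is non-increasing — asserted numerically in the tests.
Non-convergence within `max_iters` (default 20 000) is a warning, not an
error, so diagnostics are still produced on hard grids. Initialization is
the boundary-value average (0.5) on the wall.

**Backends.** The convolution backend is pluggable: `ndimage`
(scipy.ndimage.correlate, default) and `numpy` (explicit shift-and-add with
edge padding). Both are CPU implementations and are required to agree to
≤1e-10 RMS; the same contract would apply to any accelerator backend added
behind the same interface.

**Gradients.** Sobel–Feldman kernels with ramp normalization: 1/8 in 2D,
1/32 in 3D (central difference × [1,2,1]/4 smoothing per orthogonal axis),
so a unit-slope ramp yields a unit gradient and the operator is exact on
quadratics along the derivative axis. Directions are normalized per voxel;
magnitudes below 1e-8 are flagged invalid (data, not an exception).
Off-lattice directions interpolate the *unit* field multilinearly and
renormalize — interpolating raw gradients instead would let the large
clamped-region magnitudes dominate near boundaries. On the annulus phantom
the resulting field is radial to a median of ~0.2°; misalignment above 2°
is confined to the two staircase-adjacent voxel layers per boundary.

**Tracing.** Fixed-step explicit Euler, p ← p ± γ·n̂(p), with γ = 0.25
lattice steps (h/4 physically) — small enough that the termination residual
per path end is below γ·h. A path ends when the voxel nearest the current
position is no longer wall; there is no sub-voxel boundary refinement, and
the ≤ γ·h overshoot per end is the main source of the small positive bias
visible at low resolutions. Failure modes (invalid gradient, out of bounds,
step cap 4 × lattice diagonal / γ) are recorded per voxel; failed voxels
carry no partial lengths and are either left NaN or filled from the nearest
successful voxel (default) with their failure flag preserved. Tracing is
per-voxel independent, so results do not depend on evaluation order; an
optional `stride` mode traces a subsample and fills the rest by nearest
neighbour, trading accuracy for speed (off by default). More than 10% failed
traces triggers a warning (typical causes: unresolved wall, touching
boundaries).

## Phantoms (what the generator emulates — and what it does not)

The phantoms are ideal, noise-free label images with uniform true thickness
d = 1.5 mm by construction: lumen inside an inner surface, wall = points at
Euclidean distance (0, d] from it. The outer boundary is the true Euclidean
*offset* of the inner surface — concentric circle/sphere/torus for the
symmetric shapes, the offset curve/surface (not a scaled copy) for the
ellipse (semi-axes 1.5/1.0 mm) and ellipsoid (2.0/1.5/1.0 mm); a scaled
ellipse would have non-uniform truth. The bent pipe bends a 1.5 mm-radius
tube along a quarter-circle axis of radius 4.5 mm, with both end planes as
Neumann caps; the half-shells cap at their equatorial plane. Cap planes
coincide with lattice faces; non-cap faces get 4 voxels of exterior padding.

Signed distances to the inner surface are exact: closed form where possible,
and for the ellipse/ellipsoid a vectorized bisection of the foot-point
equation F(t) = Σ(eᵢyᵢ/(t+eᵢ²))² − 1 (accuracy ~1e-10 mm away from the
medial axis, ~1e-4 mm at its degenerate center — far below the voxel size).
Validation resolutions follow the study conditions: 2–200 steps/mm in 2D,
2–10 in 3D (higher 3D resolutions are computationally disproportionate for
what they add).

What passing these phantoms does **not** show: robustness to segmentation
noise, partial-volume effects, touching vessels with unresolved outer
boundaries, or anisotropic acquisition artifacts. Real masks should be
inspected for boundary integrity (the preprocessing refuses masks whose
smoothing merges lumen with exterior, naming the breach location).

## Preprocessing

Anisotropic grids are resampled to the *minimum* input spacing (upsample,
never downsample, so thin walls are not destroyed): each label's indicator
is interpolated independently and the output label is the indicator argmax
with ties broken WALL > LUMEN > EXTERIOR, so the measurement domain is never
eroded by ties. The in vivo recipe — upsample by an integer factor (default
3) and Gaussian-smooth — operates on per-label indicators with the same
argmax relabelling, keeping a crisp boundary for the solver. The smoothing
width (σ = 0.5 upsampled voxels by default) is a package choice: small
enough to preserve one-voxel features after ×3 upsampling, large enough to
round the blockiness that upsampling introduces. With σ = 0 the operation is
exact block replication (label counts scale by factor^rank).

## ROI morphometrics

Area/volume is voxel count × h^rank. The normalized index is ROI area
divided by total vessel area, with total = lumen + wall (the convention the
printed morphometric tables are consistent with). Thickness and
distance-to-lumen statistics are voxel-weighted over ROI ∩ wall ∩
successfully-traced voxels, with population (divide-by-N) standard
deviations — at typical ROI sizes the sample/population distinction is below
reporting precision. Overlapping ROIs are allowed (plaque components
normally lie inside the outer-wall ROI).

## Known limitations

- Accuracy degrades sharply when the wall spans fewer than ~4 voxels;
  upsample first (the package warns).
- The ≤ γ·h termination overshoot per path end gives a small positive
  thickness bias at coarse resolutions; it decays with h.
- Boundary staircase rasterization dominates the potential error near
  clamped layers in 3D at ≤10 voxels/mm (see above); thickness means are
  much less sensitive because tracing integrates across the wall.
- Plain Jacobi iteration converges in O(w²) sweeps for a wall w voxels
  thick; very high 2D resolutions (≥100 px/mm) need tens of thousands of
  sweeps. Multigrid/SOR acceleration is deliberately out of scope.
- Segmentation itself, registration, centerline extraction and
  surface-mesh rendering are out of scope; masks and ROIs are inputs.
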