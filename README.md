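# lapthick

Voxel-wise 2D/3D wall-thickness measurement on segmentation masks using the
Laplacian (equipotential-streamline) method.

## The problem

Vessel-wall thickness is a key morphological marker in cardiovascular
imaging, but most measurement tools are 2D: they need centerlines and
cross-sectional slices, struggle with tortuous or bifurcating vessels, and
only report thickness at the lumen boundary. `lapthick` treats thickness
measurement as the inherently 3D problem it is. Given a label image that
partitions space into *lumen*, *wall* and *exterior*, it produces a thickness
value at **every** wall voxel, plus per-voxel distance-to-lumen and
distance-to-outer-wall maps — the inputs for localized plaque morphometrics.
It works identically on 2D sections (e.g. histology) and 3D volumes (e.g.
black-blood MRI segmentations).

## The method

A harmonic potential φ is assigned to the wall between the two boundaries
S₀ (lumen–wall interface) and S₁ (wall–exterior interface):

```
∇²φ = 0,   φ|S₀ = 0,   φ|S₁ = 1,   ∇φ·n̂|caps = 0
```

The zero-normal-gradient (Neumann) condition applies at vessel end caps, as
if the vessel continued uniformly past them. The equipotential surfaces of φ
foliate the wall into parallel sublayers, which yields a self-consistent
thickness definition even where the two boundaries are far from parallel.

The discrete solve is a Jacobi iteration written as a convolution. In 2D each
wall voxel is repeatedly replaced by the average of its four face neighbours,

```
φ ← K ⊛ φ,    K = ¼ [0 1 0; 1 0 1; 0 1 0]
```

(in 3D: six face neighbours, weight 1/6), with the lumen and exterior
re-clamped to 0 and 1 after every sweep and replicate padding across cap
faces realizing the Neumann condition. Convergence is declared when the RMS
change per wall voxel drops below a tolerance (default 1e-6).

The streamline direction field is the normalized Sobel–Feldman gradient
n̂ = ∇φ/‖∇φ‖. From each wall voxel, two paths are integrated with fixed-step
explicit Euler (step γ = h/4, with h the voxel size): the positive path
follows +n̂ to the outer boundary (length T⁺ = distance to outer wall) and
the negative path follows −n̂ to the lumen (length T⁻ = distance to lumen).
The wall thickness at that voxel is

```
T = T⁺ + T⁻.
```

Because every stage is a convolution or an independent per-voxel
integration, the method is deterministic, order-independent, and maps
naturally onto array hardware.

The package also ships digital validation phantoms with uniform true
thickness (circular/elliptical rings; half-spherical and half-ellipsoid
shells; a bent pipe) and ROI morphometrics (area, normalized index =
ROI area / (lumen + wall area), thickness and distance-to-lumen statistics
per region).

## Worked example

Measure a circular ring phantom (inner radius 1.5 mm, true wall thickness
1.5 mm) rasterized at 10 pixels/mm:

```python
import lapthick as lt

spec = lt.PhantomSpec(shape="circular_ring", r=1.5, d=1.5, resolution=10)
out = lt.measure_phantom(spec)
for k, v in out.summary.items():
    print(f"{k}: {v}")
em = lt.error_metrics(out.thickness, truth=spec.d)
print(f"bias: {em.bias:.4f} mm   rms error: {em.error:.4f} mm")
```

prints

```
n_wall: 2112
n_ok: 2112
fraction_ok: 1.0
thickness_mean_mm: 1.5251893939393943
thickness_std_mm: 0.03815665130782091
solver_iterations: 700
solver_converged: True
final_energy: 9.1416362428818e-07
h_mm: 0.1
bias: 0.0252 mm   rms error: 0.0457 mm
```

All 2112 wall pixels were traced successfully; the mean measured thickness
is 1.525 mm against a 1.5 mm truth — a +0.025 mm bias, a quarter of a pixel,
dominated by the one-step overshoot at each path end (bounded by γ·h) and
rasterization of the ring at this resolution. Both shrink as resolution
increases.

The same pipeline runs from the shell:

```sh
lapthick phantom --shape circular_ring --res 10 --out ring.png
lapthick run ring.png --out run/          # thickness + distance maps, summary CSV
lapthick sweep --shape circular_ring --resolutions 2,5,10,20,50 --out sweep.csv
```

`lapthick run` accepts NIfTI label volumes (3D) or PNG/TIFF label images
(2D, spacing via `--spacing`), with `--lumen/--wall/--exterior` to remap
label codes and `--upsample/--sigma` for the upsample-and-smooth
preprocessing used on in vivo masks.

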