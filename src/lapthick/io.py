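"""Reading and writing label grids and measurement maps.

3D grids travel as NIfTI (``.nii``/``.nii.gz``) with spacing and origin taken
from the affine; 2D grids as PNG/TIFF with spacing supplied by the caller.
A small JSON sidecar (``<image>.lapthick.json``) carries what the image
format cannot: cap faces always, and spacing/origin for 2D rasters. Write
followed by read reproduces labels, spacing, origin and cap faces exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .grids import EXTERIOR, LUMEN, WALL, LabelGrid, validate_labels
from .thickness import ThicknessResult

_NIFTI_SUFFIXES = (".nii", ".nii.gz")
_RASTER_SUFFIXES = (".png", ".tif", ".tiff")


def _is_nifti(path: Path) -> bool:
    return path.name.endswith(_NIFTI_SUFFIXES)


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".lapthick.json")


def _write_sidecar(path: Path, grid: LabelGrid) -> None:
    meta = {
        "spacing": list(grid.spacing),
        "origin": list(grid.origin),
        "cap_faces": sorted([list(f) for f in grid.cap_faces]),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def _read_sidecar(path: Path) -> dict | None:
    sc = _sidecar_path(path)
    if sc.exists():
        return json.loads(sc.read_text())
    return None


def read_label_image(
    path: str | Path,
    mapping: dict[int, int] | None = None,
    spacing: tuple[float, ...] | None = None,
) -> LabelGrid:
    """Load a label grid from NIfTI (3D) or PNG/TIFF (2D).

    ``mapping`` remaps raw pixel values to the canonical codes
    (EXTERIOR=0, LUMEN=1, WALL=2), e.g. ``{0: 0, 3: 1, 5: 2}``. For 2D
    rasters the physical ``spacing`` (mm/pixel) is required unless a sidecar
    provides it.
    """
    path = Path(path)
    meta = _read_sidecar(path)
    if _is_nifti(path):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        if not np.issubdtype(data.dtype, np.integer):
            rounded = np.rint(data)
            if not np.allclose(data, rounded, atol=1e-6):
                raise ValueError(f"{path} does not contain integer labels")
            data = rounded.astype(np.int32)
        zooms = tuple(float(z) for z in img.header.get_zooms()[: data.ndim])
        origin = tuple(float(o) for o in img.affine[: data.ndim, 3])
    elif path.suffix.lower() in _RASTER_SUFFIXES:
        data = np.asarray(iio.imread(path))
        if data.ndim != 2:
            raise ValueError(f"{path} is not a single-channel 2D label image")
        if spacing is None and meta is not None:
            spacing = tuple(meta["spacing"])
        if spacing is None:
            raise ValueError(
                f"2D image {path} carries no physical spacing; pass spacing= "
                "(mm per pixel) or provide a sidecar"
            )
        zooms = tuple(float(s) for s in np.broadcast_to(spacing, (2,)))
        origin = (0.0, 0.0)
    else:
        raise ValueError(f"unsupported label-image format: {path}")

    if spacing is not None:
        zooms = tuple(float(s) for s in np.broadcast_to(spacing, (data.ndim,)))
    if mapping:
        out = np.full(data.shape, -1, dtype=np.int32)
        for raw, code in mapping.items():
            out[data == raw] = code
        if (out < 0).any():
            extra = sorted(np.unique(data[out < 0]).tolist())
            raise ValueError(f"image contains values {extra} absent from the "
                             "label mapping")
        data = out

    cap_faces = frozenset()
    if meta is not None:
        origin = tuple(meta.get("origin", origin))
        cap_faces = frozenset(tuple(f) for f in meta.get("cap_faces", []))
        if spacing is None:
            # sidecar spacing is exact; NIfTI header zooms are float32
            zooms = tuple(meta["spacing"])
    grid = LabelGrid(labels=data.astype(np.uint8), spacing=zooms, origin=origin,
                     cap_faces=cap_faces)
    return validate_labels(grid)


def write_label_image(grid: LabelGrid, path: str | Path) -> Path:
    """Write a label grid to NIfTI (3D) or PNG/TIFF (2D) plus a sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        if grid.rank != 3:
            raise ValueError("NIfTI output expects a rank-3 grid")
        affine = np.diag(list(grid.spacing) + [1.0])
        affine[:3, 3] = grid.origin
        nib.save(nib.Nifti1Image(grid.labels.astype(np.uint8), affine), str(path))
    elif path.suffix.lower() in _RASTER_SUFFIXES:
        if grid.rank != 2:
            raise ValueError("PNG/TIFF output expects a rank-2 grid")
        iio.imwrite(path, grid.labels.astype(np.uint8))
    else:
        raise ValueError(f"unsupported label-image format: {path}")
    _write_sidecar(path, grid)
    return path


def write_float_map(
    data: np.ndarray, grid: LabelGrid, path: str | Path
) -> Path:
    """Write a float map aligned to the grid (NIfTI in 3D, TIFF in 2D)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if grid.rank == 3:
        if not _is_nifti(path):
            raise ValueError("3D float maps are written as NIfTI")
        affine = np.diag(list(grid.spacing) + [1.0])
        affine[:3, 3] = grid.origin
        nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))
    else:
        if path.suffix.lower() not in (".tif", ".tiff"):
            raise ValueError("2D float maps are written as TIFF")
        iio.imwrite(path, data.astype(np.float32))
    return path


def write_maps(result: ThicknessResult, out_dir: str | Path) -> dict[str, Path]:
    """Persist thickness (T), distance maps (T+, T−) and trace flags."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    grid = result.grid
    suffix = ".nii.gz" if grid.rank == 3 else ".tiff"
    paths = {}
    for name, data in (
        ("thickness", result.T),
        ("dist_to_outer_wall", result.T_plus),
        ("dist_to_lumen", result.T_minus),
    ):
        paths[name] = write_float_map(data, grid, out_dir / f"{name}{suffix}")
    # flags are a status volume, not a 3-code label image: write raw
    if grid.rank == 3:
        affine = np.diag(list(grid.spacing) + [1.0])
        affine[:3, 3] = grid.origin
        fpath = out_dir / "trace_flags.nii.gz"
        nib.save(nib.Nifti1Image(result.flags.astype(np.uint8), affine), str(fpath))
    else:
        fpath = out_dir / "trace_flags.png"
        iio.imwrite(fpath, result.flags.astype(np.uint8))
    paths["trace_flags"] = fpath
    return paths
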