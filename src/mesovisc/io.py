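"""File formats: NIfTI volumes + JSON sidecars, histology rasters, tables.

Phase series are stored as 5-D NIfTI in scanner-style axis order
(x, y, z, offset, frequency*component) with a JSON sidecar recording the
dimension order, frequencies, spacing and provenance; internally arrays are
(frequency, component, offset, z, y, x).  Viscoelastic maps are one 3-D
NIfTI per parameter plus a shared sidecar with units and provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .fields import ComplexWaveField, RawPhaseSeries
from .grid import AcquisitionGrid
from .histology import HistologyImage
from .inversion import ElastoMaps

__all__ = [
    "save_phase_series",
    "load_phase_series",
    "save_elasto_maps",
    "load_elasto_maps",
    "save_wave_field",
    "load_wave_field",
    "save_histology_image",
    "load_histology_image",
]

_DIM_ORDER = "x,y,z,offset,frequency*component"


def _affine(grid: AcquisitionGrid) -> np.ndarray:
    # internal axis 0 is z; NIfTI axis 0 is x
    return np.diag([grid.spacing_mm[2], grid.spacing_mm[1], grid.spacing_mm[0], 1.0])


def _grid_meta(grid: AcquisitionGrid) -> dict:
    return {
        "shape_zyx": list(grid.shape),
        "spacing_mm_zyx": list(grid.spacing_mm),
        "frequencies_hz": list(grid.frequencies_hz),
        "n_offsets": grid.n_offsets,
        "n_components": grid.n_components,
    }


def _grid_from_meta(meta: dict) -> AcquisitionGrid:
    return AcquisitionGrid(
        tuple(meta["shape_zyx"]),
        tuple(meta["spacing_mm_zyx"]),
        tuple(meta["frequencies_hz"]),
        meta["n_offsets"],
        meta["n_components"],
    )


def save_phase_series(series: RawPhaseSeries, path: str | Path) -> Path:
    """Write a phase series as 5-D NIfTI with a ``.json`` sidecar."""
    path = Path(path)
    grid = series.grid
    # (f, c, t, z, y, x) -> (x, y, z, t, f*c)
    fc = grid.n_frequencies * grid.n_components
    data = series.data.reshape(fc, grid.n_offsets, *grid.shape)
    data = np.transpose(data, (4, 3, 2, 1, 0))
    nib.save(nib.Nifti1Image(data.astype(np.float32), _affine(grid)), str(path))
    sidecar = {
        "dimension_order": _DIM_ORDER,
        "grid": _grid_meta(grid),
        "noise_sigma_rad": series.noise_sigma,
        "wrapped": series.wrapped,
        "provenance": list(series.provenance),
    }
    sidecar_path = path.with_suffix("").with_suffix(".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return path


def load_phase_series(path: str | Path) -> RawPhaseSeries:
    path = Path(path)
    meta = json.loads(path.with_suffix("").with_suffix(".json").read_text())
    grid = _grid_from_meta(meta["grid"])
    data = np.asanyarray(nib.load(str(path)).dataobj).astype(np.float64)
    data = np.transpose(data, (4, 3, 2, 1, 0)).reshape(
        grid.n_frequencies, grid.n_components, grid.n_offsets, *grid.shape
    )
    return RawPhaseSeries(
        data,
        grid,
        noise_sigma=meta.get("noise_sigma_rad", 0.0),
        wrapped=meta.get("wrapped", True),
        provenance=tuple(meta.get("provenance", ())),
    )


def save_wave_field(field: ComplexWaveField, stem: str | Path) -> tuple[Path, Path]:
    """Store a complex field as paired real/imaginary 5-D NIfTI volumes."""
    stem = Path(stem)
    grid = field.grid
    paths = []
    for part, arr in (("real", field.data.real), ("imag", field.data.imag)):
        data = np.transpose(arr, (4, 3, 2, 1, 0))  # (f,c,z,y,x)->(x,y,z,c,f)
        p = stem.parent / f"{stem.name}_{part}.nii"
        nib.save(nib.Nifti1Image(data.astype(np.float32), _affine(grid)), str(p))
        paths.append(p)
    sidecar = {"grid": _grid_meta(grid), "provenance": list(field.provenance)}
    (stem.parent / f"{stem.name}.json").write_text(json.dumps(sidecar, indent=2))
    return tuple(paths)


def load_wave_field(stem: str | Path) -> ComplexWaveField:
    stem = Path(stem)
    meta = json.loads((stem.parent / f"{stem.name}.json").read_text())
    grid = _grid_from_meta(meta["grid"])
    parts = []
    for part in ("real", "imag"):
        arr = np.asanyarray(nib.load(str(stem.parent / f"{stem.name}_{part}.nii")).dataobj)
        parts.append(np.transpose(arr.astype(np.float64), (4, 3, 2, 1, 0)))
    return ComplexWaveField(parts[0] + 1j * parts[1], grid, tuple(meta.get("provenance", ())))


_MAP_UNITS = {"sws": "m/s", "gstar_kpa": "kPa", "phi_rad": "rad"}


def save_elasto_maps(maps: ElastoMaps, outdir: str | Path, *, extra_meta: dict | None = None) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name in ("sws", "gstar_kpa", "phi_rad"):
        arr = getattr(maps, name)
        if arr is None:
            continue
        p = outdir / f"{name}.nii"
        data = np.transpose(arr, (2, 1, 0)).astype(np.float32)
        nib.save(nib.Nifti1Image(data, _affine(maps.grid)), str(p))
        written[name] = str(p)
    meta = {"grid": _grid_meta(maps.grid), "units": _MAP_UNITS, "maps": written}
    if extra_meta:
        meta.update(extra_meta)
    (outdir / "maps.json").write_text(json.dumps(meta, indent=2))
    return written


def load_elasto_maps(outdir: str | Path) -> ElastoMaps:
    outdir = Path(outdir)
    meta = json.loads((outdir / "maps.json").read_text())
    grid = _grid_from_meta(meta["grid"])
    arrays: dict[str, np.ndarray | None] = {}
    for name in ("sws", "gstar_kpa", "phi_rad"):
        p = outdir / f"{name}.nii"
        if p.exists():
            arrays[name] = np.transpose(
                np.asanyarray(nib.load(str(p)).dataobj).astype(np.float64), (2, 1, 0)
            )
        else:
            arrays[name] = None
    return ElastoMaps(arrays["sws"], arrays["gstar_kpa"], arrays["phi_rad"], grid)


def save_histology_image(image: HistologyImage, stem: str | Path) -> Path:
    """RGB TIFF + mask PNGs + JSON sidecar (pixel size, truth fraction, seed)."""
    import tifffile
    from imageio.v3 import imwrite

    stem = Path(stem)
    p = stem.parent / f"{stem.name}.tiff"
    tifffile.imwrite(str(p), image.raster)
    imwrite(stem.parent / f"{stem.name}_roi.png", image.roi_mask.astype(np.uint8) * 255)
    sidecar = {"pixel_size_um": image.pixel_size_um, "seed": image.seed}
    if image.truth_mask is not None:
        imwrite(stem.parent / f"{stem.name}_truth.png", image.truth_mask.astype(np.uint8) * 255)
        sidecar["truth_fraction"] = image.truth_fraction
    (stem.parent / f"{stem.name}.json").write_text(json.dumps(sidecar, indent=2))
    return p


def load_histology_image(stem: str | Path) -> HistologyImage:
    import tifffile
    from imageio.v3 import imread

    stem = Path(stem)
    meta = json.loads((stem.parent / f"{stem.name}.json").read_text())
    raster = tifffile.imread(str(stem.parent / f"{stem.name}.tiff"))
    roi = imread(stem.parent / f"{stem.name}_roi.png") > 127
    truth_path = stem.parent / f"{stem.name}_truth.png"
    truth = imread(truth_path) > 127 if truth_path.exists() else None
    return HistologyImage(raster, meta["pixel_size_um"], roi, truth, meta.get("seed"))
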