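"""ROI summaries of viscoelastic maps.

A region of interest is accepted only if its largest single-slice in-plane
area reaches the configured minimum (default 31.25 mm^2, i.e. five
2.5 x 2.5 mm voxels), and statistics are taken over defined (non-NaN)
voxels only — undefined inversion output never enters a mean as zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .inversion import ElastoMaps

__all__ = ["RoiMask", "RoiSummary", "RoiTooSmallError", "summarize_roi", "MIN_ROI_AREA_MM2"]

MIN_ROI_AREA_MM2 = 31.25

PARAMETERS = ("sws", "gstar_kpa", "phi_rad")


class RoiTooSmallError(ValueError):
    """ROI rejected: below the minimum in-plane area or fully undefined."""


@dataclass
class RoiMask:
    mask: np.ndarray
    label: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("ROI mask is empty")


@dataclass
class RoiSummary:
    subject_id: str
    label: str
    mean: dict[str, float]
    sd: dict[str, float]
    n_voxels: dict[str, int]
    max_slice_area_mm2: float


def summarize_roi(
    maps: ElastoMaps, roi: RoiMask, min_area_mm2: float = MIN_ROI_AREA_MM2
) -> RoiSummary:
    """Mean and sample SD of each parameter over the defined voxels of a ROI.

    Raises :class:`RoiTooSmallError` when the largest single-slice in-plane
    area of the ROI is below ``min_area_mm2``, or when a computed parameter
    has no defined voxel inside the ROI.
    """
    if roi.mask.shape != maps.grid.shape:
        raise ValueError("ROI mask shape does not match the map grid")
    voxel_area = maps.grid.in_plane_voxel_area_mm2
    per_slice = roi.mask.reshape(roi.mask.shape[0], -1).sum(axis=1) * voxel_area
    max_area = float(per_slice.max())
    if max_area < min_area_mm2:
        raise RoiTooSmallError(
            f"largest single-slice ROI area {max_area:g} mm^2 is below the "
            f"minimum {min_area_mm2:g} mm^2"
        )
    mean: dict[str, float] = {}
    sd: dict[str, float] = {}
    nvox: dict[str, int] = {}
    for name in PARAMETERS:
        arr = {"sws": maps.sws, "gstar_kpa": maps.gstar_kpa, "phi_rad": maps.phi_rad}[name]
        if arr is None:
            continue
        vals = arr[roi.mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise RoiTooSmallError(f"ROI has no defined voxels for parameter '{name}'")
        mean[name] = float(vals.mean())
        sd[name] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        nvox[name] = int(vals.size)
    return RoiSummary(roi.subject_id, roi.label, mean, sd, nvox, max_area)
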