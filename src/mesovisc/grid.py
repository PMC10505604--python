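"""Acquisition geometry for multifrequency MR elastography volumes.

The grid couples the voxel lattice (shape, spacing) to the vibration
protocol (mechanical frequencies, number of wave-phase offsets per cycle,
number of motion-encoding directions).  Angular frequencies ``omega = 2*pi*f``
are derived, never stored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionGrid", "study_grid"]


@dataclass(frozen=True)
class AcquisitionGrid:
    """Voxel lattice plus vibration protocol.

    Parameters
    ----------
    shape
        Voxels per axis, (nz, ny, nx).  Axis 0 is the slice axis.
    spacing_mm
        Voxel size in mm per axis, same order as ``shape``.
    frequencies_hz
        Mechanical vibration frequencies, strictly increasing, Hz.
    n_offsets
        Wave-phase offsets sampled per vibration cycle (>= 4).
    n_components
        Motion-encoding directions (1 or 3).
    """

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float]
    frequencies_hz: tuple[float, ...]
    n_offsets: int = 8
    n_components: int = 3

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing_mm)
        freqs = tuple(float(f) for f in self.frequencies_hz)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing_mm", spacing)
        object.__setattr__(self, "frequencies_hz", freqs)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be a positive integer triple, got {shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing_mm must be strictly positive, got {spacing}")
        if not freqs or any(f <= 0 for f in freqs):
            raise ValueError("frequencies_hz must be non-empty and strictly positive")
        if any(b <= a for a, b in zip(freqs, freqs[1:])):
            raise ValueError("frequencies_hz must be strictly increasing")
        if self.n_offsets < 4:
            raise ValueError("n_offsets must be >= 4 for harmonic extraction")
        if self.n_components not in (1, 3):
            raise ValueError("n_components must be 1 or 3")

    @property
    def n_frequencies(self) -> int:
        return len(self.frequencies_hz)

    @property
    def omegas(self) -> np.ndarray:
        """Angular frequencies, rad/s."""
        return 2.0 * np.pi * np.asarray(self.frequencies_hz)

    @property
    def spacing_m(self) -> tuple[float, float, float]:
        return tuple(s * 1e-3 for s in self.spacing_mm)

    @property
    def in_plane_voxel_area_mm2(self) -> float:
        return self.spacing_mm[1] * self.spacing_mm[2]

    def coords_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinate arrays (open meshgrid), mm."""
        axes = [np.arange(n) * d for n, d in zip(self.shape, self.spacing_mm)]
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))

    def voxels_per_wavelength(self, sws_m_per_s: float, frequency_hz: float) -> float:
        """Shear-wavelength sampling density in the finest in-plane direction."""
        wavelength_mm = sws_m_per_s / frequency_hz * 1e3
        return wavelength_mm / min(self.spacing_mm[1:])


def study_grid(
    shape: tuple[int, int, int] = (12, 64, 64),
    spacing_mm: tuple[float, float, float] = (5.0, 2.5, 2.5),
    frequencies_hz: tuple[float, ...] = (30.0, 40.0, 50.0, 60.0),
    n_offsets: int = 8,
    n_components: int = 3,
) -> AcquisitionGrid:
    """Grid mirroring the study acquisition: 2.5 x 2.5 x 5 mm voxels,
    30/40/50/60 Hz vibration, 8 wave-phase offsets, 3 encoding directions."""
    return AcquisitionGrid(shape, spacing_mm, frequencies_hz, n_offsets, n_components)
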