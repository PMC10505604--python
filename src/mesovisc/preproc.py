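"""Wrapped phase -> clean complex shear-wave fields.

Stages, in pipeline order:

1. ``gaussian_denoise`` — circular Gaussian smoothing of the wrapped phase
   (sin and cos smoothed separately, recombined by arctangent) so that wrap
   discontinuities are not blurred into spurious intermediate values.
2. ``unwrap_gradient`` / ``unwrap_laplacian`` — spatial unwrapping per offset
   volume; the gradient method integrates re-wrapped finite differences, the
   Laplacian method estimates the true-phase Laplacian from sin/cos
   identities and inverts it with a Neumann Poisson solve (DCT).  The two
   feed the algebraic (MDEV) and wavenumber (k-MDEV) inversions respectively.
3. ``extract_harmonic`` — temporal DFT across wave-phase offsets; the
   fundamental bin is the complex vibration field.
4. ``suppress_compressional`` — in-plane spatial-frequency filtering: an
   ideal high-pass removes the near-uniform compressional contribution
   (~1500 m/s, wavelengths of metres at these frequencies) together with any
   constant unwrapping offsets, and the MDEV path adds a Butterworth
   low-pass against noise amplification in the Laplacian.

All spatial filtering is slice-wise 2-D with mirror boundary handling; the
unwrapping constant per offset volume is irrelevant downstream because the
high-pass annihilates spatially uniform terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import fft as sfft
from scipy import ndimage

from .fields import ComplexWaveField, RawPhaseSeries, wrap_phase
from .grid import AcquisitionGrid

__all__ = [
    "BandConfig",
    "gaussian_denoise",
    "unwrap_gradient",
    "unwrap_laplacian",
    "extract_harmonic",
    "suppress_compressional",
    "preprocess",
]


@dataclass(frozen=True)
class BandConfig:
    """In-plane spatial pass-band for shear waves.

    The high-pass removes wavelengths above ``lambda_max_mm``.  The
    Butterworth low-pass (MDEV path only, where it tempers the noise
    amplification of the Laplacian) is by default scaled per vibration
    frequency to a constant minimum wave speed ``min_speed_m_per_s``: the
    shear wavelength shrinks with frequency, so a fixed spatial cutoff would
    clip the high-frequency components of slow (soft) tissue while barely
    filtering the low ones.  With ``lowpass_per_frequency=False`` the fixed
    ``lambda_min_mm`` cutoff is used for every frequency instead.
    """

    lambda_min_mm: float = 12.0
    lambda_max_mm: float = 200.0
    butter_order: int = 3
    lowpass_per_frequency: bool = True
    min_speed_m_per_s: float = 0.3

    def __post_init__(self) -> None:
        if self.lambda_min_mm <= 0 or self.lambda_max_mm <= self.lambda_min_mm:
            raise ValueError("need 0 < lambda_min_mm < lambda_max_mm")
        if self.min_speed_m_per_s <= 0:
            raise ValueError("min_speed_m_per_s must be positive")

    @property
    def kappa_low(self) -> float:
        """High-pass cutoff, cycles/mm."""
        return 1.0 / self.lambda_max_mm

    @property
    def kappa_high(self) -> float:
        """Fixed low-pass cutoff, cycles/mm."""
        return 1.0 / self.lambda_min_mm

    def kappa_high_at(self, frequency_hz: float) -> float:
        """Low-pass cutoff for one vibration frequency, cycles/mm."""
        if self.lowpass_per_frequency:
            return frequency_hz / self.min_speed_m_per_s * 1e-3
        return self.kappa_high

    def wavenumber_floor_per_m(self) -> float:
        return 2.0 * np.pi / (self.lambda_max_mm * 1e-3)


def gaussian_denoise(series: RawPhaseSeries, sigma_voxels: float) -> RawPhaseSeries:
    """Circularly smooth wrapped phase in-plane (sigma in voxels)."""
    if sigma_voxels < 0:
        raise ValueError("sigma_voxels must be non-negative")
    if sigma_voxels == 0:
        return series.with_data(series.data.copy(), "gaussian_denoise(0)")
    sigma = (0.0,) * (series.data.ndim - 2) + (sigma_voxels, sigma_voxels)
    s = ndimage.gaussian_filter(np.sin(series.data), sigma, mode="mirror")
    c = ndimage.gaussian_filter(np.cos(series.data), sigma, mode="mirror")
    return series.with_data(
        np.arctan2(s, c), f"gaussian_denoise({sigma_voxels:g})", wrapped=True
    )


def _unwrap_volume_gradient(w: np.ndarray) -> np.ndarray:
    """Row-major path-following unwrap of one 3-D volume.

    Integrates re-wrapped differences along z for the corner line, along y
    for the first column of each slice, then along x for every row — exact
    for smooth fields, deterministic always.
    """
    corner = np.unwrap(w[:, 0, 0], axis=0)
    col = np.unwrap(w[:, :, 0], axis=1)
    col = col + (corner - w[:, 0, 0])[:, None]
    out = np.unwrap(w, axis=2)
    out = out + (col - w[:, :, 0])[:, :, None]
    return out


def unwrap_gradient(series: RawPhaseSeries) -> RawPhaseSeries:
    """Gradient-method unwrapping of every offset volume.

    Output is re-referenced so the per-volume median branch matches the
    wrapped input; any residual 2*pi constant is removed downstream by the
    compressional high-pass.
    """
    data = series.data
    flat = data.reshape(-1, *data.shape[-3:])
    out = np.empty_like(flat)
    for i, vol in enumerate(flat):
        u = _unwrap_volume_gradient(vol)
        offset = 2 * np.pi * np.round(np.median(u - vol) / (2 * np.pi))
        out[i] = u - offset
    return series.with_data(
        out.reshape(data.shape), "unwrap_gradient", wrapped=False
    )


def _poisson_solve_2d(lap: np.ndarray, spacing: tuple[float, float]) -> np.ndarray:
    """Invert the 3-point Neumann Laplacian via DCT-II (solution up to constant)."""
    ny, nx = lap.shape[-2:]
    ky = (2.0 * np.cos(np.pi * np.arange(ny) / ny) - 2.0) / spacing[0] ** 2
    kx = (2.0 * np.cos(np.pi * np.arange(nx) / nx) - 2.0) / spacing[1] ** 2
    eig = ky[:, None] + kx[None, :]
    eig[0, 0] = 1.0
    coef = sfft.dctn(lap, type=2, axes=(-2, -1))
    coef = coef / eig
    coef[..., 0, 0] = 0.0
    return sfft.idctn(coef, type=2, axes=(-2, -1))


def _discrete_laplacian_reflect(a: np.ndarray, spacing: tuple[float, float]) -> np.ndarray:
    """3-point Laplacian with half-sample symmetric boundaries (matches DCT-II)."""
    out = np.zeros_like(a)
    for ax, h in ((-2, spacing[0]), (-1, spacing[1])):
        out += ndimage.correlate1d(a, [1.0, -2.0, 1.0], axis=ax, mode="reflect") / h**2
    return out


def unwrap_laplacian(series: RawPhaseSeries) -> RawPhaseSeries:
    """Laplacian-based unwrapping, slice-wise.

    Estimates the true-phase Laplacian through the wrap-free identity
    ``lap(theta) = cos(theta) lap(sin theta) - sin(theta) lap(cos theta)``
    and inverts it with a Neumann Poisson solve.  The result is exact up to
    a per-slice harmonic (affine) term, which is inconsequential for the
    wavenumber-based inversion downstream.
    """
    hy, hx = series.grid.spacing_mm[1:]  # common scale cancels; anisotropy does not
    s, c = np.sin(series.data), np.cos(series.data)
    lap_est = c * _discrete_laplacian_reflect(s, (hy, hx)) - s * _discrete_laplacian_reflect(
        c, (hy, hx)
    )
    out = _poisson_solve_2d(lap_est, (hy, hx))
    # re-reference per volume as in the gradient method
    offset = 2 * np.pi * np.round(
        np.median(out - series.data, axis=(-3, -2, -1), keepdims=True) / (2 * np.pi)
    )
    return series.with_data(out - offset, "unwrap_laplacian", wrapped=False)


def extract_harmonic(series: RawPhaseSeries) -> ComplexWaveField:
    """Fundamental temporal-DFT coefficient across wave-phase offsets.

    For offsets encoded as ``Re(u * exp(-2 pi i t / N))`` the estimator
    ``(2/N) sum_t phi_t exp(+2 pi i t / N)`` returns ``u`` exactly (N >= 3);
    constant (DC) terms per voxel are orthogonal to the fundamental bin.
    Units follow the input (radians of encoded phase).
    """
    n = series.grid.n_offsets
    if n < 4:
        raise ValueError("harmonic extraction needs at least 4 wave-phase offsets")
    t = np.arange(n)
    basis = np.exp(2j * np.pi * t / n)  # (offset,)
    data = np.tensordot(series.data, basis, axes=([2], [0])) * (2.0 / n)
    # tensordot moves the contracted axis; result already (freq, comp, z, y, x)
    return ComplexWaveField(data, series.grid, series.provenance + ("extract_harmonic",))


def _radial_kappa(ny: int, nx: int, spacing_mm: tuple[float, float]) -> np.ndarray:
    ky = np.fft.fftfreq(ny, d=spacing_mm[0])
    kx = np.fft.fftfreq(nx, d=spacing_mm[1])
    return np.hypot(ky[:, None], kx[None, :])


def suppress_compressional(
    field: ComplexWaveField,
    band: BandConfig = BandConfig(),
    *,
    lowpass: bool = True,
    pad: int | None = None,
) -> ComplexWaveField:
    """In-plane spatial filtering against compressional (longitudinal) waves.

    Ideal high-pass below ``band.kappa_low`` (uniform/compressional content
    removed entirely), plus — on the MDEV path — a Butterworth low-pass of
    order ``band.butter_order`` at ``band.kappa_high`` with the standard
    -3 dB gain at cutoff.  Volumes are mirror-padded before the FFT to
    suppress periodicity artefacts.
    """
    grid = field.grid
    ny, nx = grid.shape[1], grid.shape[2]
    sp = grid.spacing_mm[1:]
    # warn when the expected shear band (protocol speeds 0.3-3 m/s) is excluded
    for f in grid.frequencies_hz:
        kappa_shear = f / 1.5e3  # cycles/mm at 1.5 m/s, mid-band speed
        if not (band.kappa_low <= kappa_shear <= band.kappa_high):
            warnings.warn(
                f"pass-band excludes the expected shear wavenumber at {f:g} Hz",
                stacklevel=2,
            )
            break
    if pad is None:
        pad = max(8, ny // 4, nx // 4)
    padded = np.pad(
        field.data, [(0, 0)] * (field.data.ndim - 2) + [(pad, pad), (pad, pad)], mode="reflect"
    )
    kappa = _radial_kappa(ny + 2 * pad, nx + 2 * pad, sp)
    # Butterworth high-pass: zero gain at DC (uniform + compressional content),
    # smooth transition to avoid the spatial ringing of a brick-wall filter
    with np.errstate(divide="ignore"):
        ratio = np.where(kappa > 0, band.kappa_low / np.where(kappa > 0, kappa, 1.0), np.inf)
    hp_gain = 1.0 / np.sqrt(1.0 + ratio ** (2 * band.butter_order))
    spec = np.fft.fft2(padded, axes=(-2, -1))
    if lowpass:
        gain = np.empty((grid.n_frequencies, 1, 1, *kappa.shape))
        for fi, f in enumerate(grid.frequencies_hz):
            kc = band.kappa_high_at(f)
            gain[fi, 0, 0] = hp_gain / np.sqrt(1.0 + (kappa / kc) ** (2 * band.butter_order))
    else:
        gain = hp_gain
    filt = np.fft.ifft2(spec * gain, axes=(-2, -1))
    out = filt[..., pad : pad + ny, pad : pad + nx]
    tag = f"suppress_compressional(band={band.lambda_min_mm:g}-{band.lambda_max_mm:g}mm"
    tag += f",butter{band.butter_order})" if lowpass else ",hp-only)"
    return field.with_data(out, tag)


def preprocess(
    series: RawPhaseSeries,
    *,
    method: str = "mdev",
    denoise_sigma_voxels: float = 1.0,
    band: BandConfig = BandConfig(),
) -> ComplexWaveField:
    """Full preprocessing chain for one acquisition.

    ``method`` selects the unwrapping and filter combination of the matching
    inversion: ``"mdev"`` (gradient unwrap, high-pass + Butterworth low-pass)
    or ``"kmdev"`` (Laplacian unwrap, high-pass only).
    """
    if method not in ("mdev", "kmdev"):
        raise ValueError("method must be 'mdev' or 'kmdev'")
    clean = gaussian_denoise(series, denoise_sigma_voxels)
    unwrapped = unwrap_gradient(clean) if method == "mdev" else unwrap_laplacian(clean)
    field = extract_harmonic(unwrapped)
    return suppress_compressional(field, band, lowpass=(method == "mdev"))
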