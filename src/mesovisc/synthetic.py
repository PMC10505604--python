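"""Synthetic multifrequency MRE data with known ground truth.

The forward model is deliberately simple and exactly invertible: within each
homogeneous phantom region a shear source launches a damped plane (or
cylindrical) wave with complex wavenumber

    k = omega * sqrt(rho / G*),        G* = |G*| * exp(i * phi),

so the spatial field ``u(x) = A * exp(-i k nhat.x)`` satisfies the Helmholtz
relation ``lap u = -(rho omega^2 / G*) u`` to discretization error.  The
principal square root puts ``arg(k) = -phi/2``, i.e. ``Im(k) < 0``, which with
the ``exp(-i k x)`` spatial convention gives amplitude decay along the
propagation direction — the loss behaviour of a viscoelastic tissue.

Motion encoding then samples ``sens * Re(u * exp(-2 pi i t / N))`` at N
wave-phase offsets t and wraps into [-pi, pi), mimicking the phase images a
scanner would produce; Gaussian phase noise is added afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .fields import ComplexWaveField, RawPhaseSeries, wrap_phase
from .grid import AcquisitionGrid

__all__ = [
    "PlaneSource",
    "CylindricalSource",
    "PhantomSpec",
    "homogeneous_phantom",
    "two_region_phantom",
    "complex_wavenumber",
    "shear_wave_speed",
    "simulate_wavefield",
    "encode_phase_offsets",
    "add_noise",
    "make_repeatability_pair",
]

DENSITY_SOFT_TISSUE = 1000.0  # kg/m^3, standard soft-tissue assumption

_ENCODING_AXES = np.eye(3)  # rows: z, y, x unit vectors (grid axis order)


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("direction vector must have non-zero length")
    return v / n


@dataclass(frozen=True)
class PlaneSource:
    """Plane shear wave: propagation ``direction``, displacement ``polarization``.

    Amplitude is in micrometres, either a scalar (same at all frequencies) or
    one value per frequency.  ``phase_rad`` offsets the source oscillation;
    the relative amplitudes/phases of multiple drivers are free parameters.
    """

    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)  # +x, in plane
    polarization: tuple[float, float, float] = (1.0, 0.0, 0.0)  # z motion
    amplitude_um: float | tuple[float, ...] = 10.0
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    phase_rad: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "direction", tuple(_unit(self.direction)))
        object.__setattr__(self, "polarization", tuple(_unit(self.polarization)))

    def amplitudes(self, n_freq: int) -> np.ndarray:
        a = np.atleast_1d(np.asarray(self.amplitude_um, dtype=float))
        if a.size == 1:
            a = np.full(n_freq, a[0])
        if a.size != n_freq:
            raise ValueError("amplitude_um must be scalar or one value per frequency")
        if np.any(a < 0):
            raise ValueError("amplitude_um must be non-negative")
        return a


@dataclass(frozen=True)
class CylindricalSource:
    """Line source along the slice axis, radiating in-plane (four-driver mimic).

    Field ~ exp(-i k r) / sqrt(max(r, r0)) with r the in-plane distance from
    ``origin_mm``; the sqrt spreading approximates a 2-D cylindrical wave
    without the Hankel-function machinery, adequate for a phantom.
    """

    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    polarization: tuple[float, float, float] = (1.0, 0.0, 0.0)
    amplitude_um: float | tuple[float, ...] = 10.0
    phase_rad: float = 0.0
    r0_mm: float = 5.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "polarization", tuple(_unit(self.polarization)))

    amplitudes = PlaneSource.amplitudes


@dataclass
class PhantomSpec:
    """Piecewise-homogeneous viscoelastic phantom.

    ``region_map`` labels every voxel; per-label complex shear modulus is
    given as magnitude ``gstar_kpa`` (kPa) and loss angle ``phi_rad``
    (0 <= phi < pi/2, phi > pi/4 meaning fluid-dominant behaviour).
    """

    region_map: np.ndarray
    gstar_kpa: dict[int, float]
    phi_rad: dict[int, float]
    density: float = DENSITY_SOFT_TISSUE
    sources: tuple = (PlaneSource(),)

    def __post_init__(self) -> None:
        self.region_map = np.asarray(self.region_map, dtype=np.int32)
        labels = np.unique(self.region_map)
        for lab in labels:
            if int(lab) not in self.gstar_kpa or int(lab) not in self.phi_rad:
                raise ValueError(f"region label {lab} missing a modulus or phase angle")
        for lab, g in self.gstar_kpa.items():
            if g <= 0:
                raise ValueError(f"|G*| must be positive (label {lab})")
        for lab, p in self.phi_rad.items():
            if not (0.0 <= p < np.pi / 2):
                raise ValueError(f"phase angle must be in [0, pi/2) (label {lab})")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if not self.sources:
            raise ValueError("phantom needs at least one source")

    def label_maps(self) -> tuple[np.ndarray, np.ndarray]:
        """Voxelwise ground-truth (|G*| kPa, phi rad) maps."""
        g = np.zeros(self.region_map.shape)
        p = np.zeros(self.region_map.shape)
        for lab in np.unique(self.region_map):
            sel = self.region_map == lab
            g[sel] = self.gstar_kpa[int(lab)]
            p[sel] = self.phi_rad[int(lab)]
        return g, p

    def true_sws(self, label: int) -> float:
        """Phase velocity sqrt(|G*|/rho) / cos(phi/2) for the labelled region, m/s."""
        return shear_wave_speed(self.gstar_kpa[label] * 1e3, self.phi_rad[label], self.density)


def homogeneous_phantom(
    grid: AcquisitionGrid,
    gstar_kpa: float = 1.0,
    phi_rad: float = 0.0,
    density: float = DENSITY_SOFT_TISSUE,
    sources: tuple = (PlaneSource(),),
) -> PhantomSpec:
    region = np.zeros(grid.shape, dtype=np.int32)
    return PhantomSpec(region, {0: gstar_kpa}, {0: phi_rad}, density, sources)


def two_region_phantom(
    grid: AcquisitionGrid,
    background: tuple[float, float],
    inclusion: tuple[float, float],
    *,
    split_axis: int = 2,
    density: float = DENSITY_SOFT_TISSUE,
    sources: tuple = (PlaneSource(),),
) -> PhantomSpec:
    """Half/half phantom split across ``split_axis``; tuples are (|G*| kPa, phi rad)."""
    region = np.zeros(grid.shape, dtype=np.int32)
    n = grid.shape[split_axis]
    idx = [slice(None)] * 3
    idx[split_axis] = slice(n // 2, None)
    region[tuple(idx)] = 1
    return PhantomSpec(
        region,
        {0: background[0], 1: inclusion[0]},
        {0: background[1], 1: inclusion[1]},
        density,
        sources,
    )


def complex_wavenumber(gstar_pa: float, phi_rad: float, density: float, omega: float) -> complex:
    """k = omega * sqrt(rho / G*), principal branch (Re > 0, Im <= 0), 1/m."""
    gstar = gstar_pa * np.exp(1j * phi_rad)
    return omega * np.sqrt(density / gstar)


def shear_wave_speed(gstar_pa: float, phi_rad: float, density: float) -> float:
    """Phase velocity omega / Re(k) of the damped plane wave, m/s."""
    k = complex_wavenumber(gstar_pa, phi_rad, density, omega=1.0)
    return 1.0 / k.real


def _wavenumber_map(phantom: PhantomSpec, omega: float) -> np.ndarray:
    kmap = np.zeros(phantom.region_map.shape, dtype=np.complex128)
    for lab in np.unique(phantom.region_map):
        k = complex_wavenumber(
            phantom.gstar_kpa[int(lab)] * 1e3, phantom.phi_rad[int(lab)], phantom.density, omega
        )
        kmap[phantom.region_map == lab] = k
    return kmap


def simulate_wavefield(
    phantom: PhantomSpec, grid: AcquisitionGrid, *, min_voxels_per_wavelength: float = 8.0
) -> ComplexWaveField:
    """Superpose all sources into a complex displacement field, micrometres.

    Encoding components are the projections of the vector displacement on the
    grid axes (z, y, x) when ``grid.n_components == 3``; with a single
    component the scalar field along each source's own polarization is used.

    Warns when the shear wavelength at the highest frequency is sampled by
    fewer than ``min_voxels_per_wavelength`` in-plane voxels.
    """
    if phantom.region_map.shape != grid.shape:
        raise ValueError("phantom region map does not match grid shape")
    zz, yy, xx = grid.coords_mm()
    out = np.zeros((grid.n_frequencies, grid.n_components, *grid.shape), dtype=np.complex128)

    fmax = grid.frequencies_hz[-1]
    for lab in np.unique(phantom.region_map):
        vpw = grid.voxels_per_wavelength(phantom.true_sws(int(lab)), fmax)
        if vpw < min_voxels_per_wavelength:
            warnings.warn(
                f"region {lab}: {vpw:.1f} in-plane voxels per wavelength at "
                f"{fmax:g} Hz (target >= {min_voxels_per_wavelength:g})",
                stacklevel=2,
            )

    for fi, omega in enumerate(grid.omegas):
        kmap_per_m = _wavenumber_map(phantom, omega)
        kmap = kmap_per_m * 1e-3  # 1/mm, coordinates are mm
        for src in phantom.sources:
            amp = src.amplitudes(grid.n_frequencies)[fi] * np.exp(1j * src.phase_rad)
            if isinstance(src, PlaneSource):
                d = np.asarray(src.direction)
                o = np.asarray(src.origin_mm)
                path = d[0] * (zz - o[0]) + d[1] * (yy - o[1]) + d[2] * (xx - o[2])
                u = amp * np.exp(-1j * kmap * path)
            elif isinstance(src, CylindricalSource):
                o = np.asarray(src.origin_mm)
                r = np.sqrt((yy - o[1]) ** 2 + (xx - o[2]) ** 2) + 0.0 * zz
                u = amp * np.exp(-1j * kmap * r) / np.sqrt(np.maximum(r, src.r0_mm))
            else:  # pragma: no cover - guarded by PhantomSpec construction
                raise TypeError(f"unknown source type {type(src).__name__}")
            pol = np.asarray(src.polarization)
            if grid.n_components == 3:
                for ci in range(3):
                    out[fi, ci] += pol[ci] * u
            else:
                out[fi, 0] += u
    return ComplexWaveField(out, grid, ("simulate_wavefield",))


def encode_phase_offsets(
    wavefield: ComplexWaveField, grid: AcquisitionGrid, sensitivity_rad_per_um: float = 1.0
) -> RawPhaseSeries:
    """Sample N wave-phase offsets of the vibration and wrap into [-pi, pi).

    Offset t of N stores ``wrap(sens * Re(u * exp(-2 pi i t / N)))``; the
    fundamental DFT coefficient across offsets recovers ``sens * u`` exactly
    when no wrapping occurs.
    """
    if sensitivity_rad_per_um <= 0:
        raise ValueError("sensitivity must be positive")
    n = grid.n_offsets
    t = np.arange(n)
    carrier = np.exp(-2j * np.pi * t / n)  # (offset,)
    u = wavefield.data[:, :, None] * carrier[None, None, :, None, None, None]
    phase = wrap_phase(sensitivity_rad_per_um * u.real)
    return RawPhaseSeries(
        phase,
        grid,
        noise_sigma=0.0,
        wrapped=True,
        provenance=wavefield.provenance + ("encode_phase_offsets",),
    )


def add_noise(series: RawPhaseSeries, sigma_rad: float, seed: int) -> RawPhaseSeries:
    """Add zero-mean Gaussian phase noise, re-wrap; deterministic given seed."""
    if sigma_rad < 0:
        raise ValueError("noise sigma must be non-negative")
    if sigma_rad == 0:
        return series.with_data(series.data.copy(), "add_noise(sigma=0)")
    rng = np.random.default_rng(seed)
    noisy = wrap_phase(series.data + rng.normal(0.0, sigma_rad, series.data.shape))
    out = series.with_data(noisy, f"add_noise(sigma={sigma_rad:g},seed={seed})")
    out.noise_sigma = float(np.hypot(series.noise_sigma, sigma_rad))
    return out


def make_repeatability_pair(
    phantom: PhantomSpec,
    grid: AcquisitionGrid,
    sigma_rad: float,
    seeds: tuple[int, int],
    sensitivity_rad_per_um: float = 1.0,
) -> tuple[RawPhaseSeries, RawPhaseSeries]:
    """Two back-to-back acquisitions of the same subject without repositioning:
    identical noiseless field, independent noise realizations."""
    if seeds[0] == seeds[1]:
        warnings.warn("identical seeds give identical noise: repeatability is degenerate", stacklevel=2)
    field = simulate_wavefield(phantom, grid)
    clean = encode_phase_offsets(field, grid, sensitivity_rad_per_um)
    return add_noise(clean, sigma_rad, seeds[0]), add_noise(clean, sigma_rad, seeds[1])
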