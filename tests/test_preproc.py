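"""Denoising, unwrapping, harmonic extraction and spatial filtering."""

import warnings

import numpy as np
import pytest

from mesovisc.fields import ComplexWaveField, RawPhaseSeries, wrap_phase
from mesovisc.grid import AcquisitionGrid
from mesovisc.numerics import interior_mask
from mesovisc.preproc import (
    BandConfig,
    extract_harmonic,
    gaussian_denoise,
    preprocess,
    suppress_compressional,
    unwrap_gradient,
    unwrap_laplacian,
)
from mesovisc.synthetic import encode_phase_offsets, homogeneous_phantom, simulate_wavefield


def _series_from(grid, volume_fn):
    """Build a RawPhaseSeries whose every (f, c, t) volume is volume_fn(t)."""
    data = np.stack([volume_fn(t) for t in range(grid.n_offsets)])
    data = np.broadcast_to(
        data, (grid.n_frequencies, grid.n_components, *data.shape)
    ).copy()
    return RawPhaseSeries(wrap_phase(data), grid)


@pytest.fixture(scope="module")
def tiny_grid():
    return AcquisitionGrid((4, 32, 32), (2.5, 2.5, 2.5), (30.0,), 8, 1)


class TestGaussianDenoise:
    def test_zero_sigma_identity(self, tiny_grid):
        rng = np.random.default_rng(0)
        s = _series_from(tiny_grid, lambda t: rng.uniform(-3, 3, tiny_grid.shape))
        out = gaussian_denoise(s, 0.0)
        assert np.array_equal(out.data, s.data)

    def test_constant_plus_noise_approaches_constant(self, tiny_grid):
        rng = np.random.default_rng(1)
        c = 1.2
        s = _series_from(
            tiny_grid, lambda t: c + rng.normal(0, 0.2, tiny_grid.shape)
        )
        out = gaussian_denoise(s, 3.0)
        inner = interior_mask(tiny_grid.shape, 4, in_plane_only=True)
        assert np.abs(out.data[..., inner] - c).mean() < 0.05

    def test_circular_smoothing_respects_wraps(self, tiny_grid):
        # wrapped steep ramp: circular smoothing must match the angle-domain
        # oracle exp-smoothing, while naive linear smoothing corrupts wraps
        from scipy import ndimage

        x = np.arange(32) * 0.7  # wraps every ~9 voxels
        ramp = np.broadcast_to(x, tiny_grid.shape)
        s = _series_from(tiny_grid, lambda t: ramp)
        sigma = 1.5
        out = gaussian_denoise(s, sigma)
        vol = s.data[0, 0, 0, 0]  # one wrapped slice row-plane
        # oracle: smooth the unit phasor directly in the complex domain
        z = np.exp(1j * s.data[0, 0, 0])
        zs = ndimage.gaussian_filter(z.real, (0, sigma, sigma), mode="mirror") + 1j * (
            ndimage.gaussian_filter(z.imag, (0, sigma, sigma), mode="mirror")
        )
        oracle = np.angle(zs)
        assert np.allclose(out.data[0, 0, 0], oracle, atol=1e-9)
        naive = ndimage.gaussian_filter(s.data[0, 0, 0], (0, sigma, sigma), mode="mirror")
        # away from the mirror boundary, a linear ramp is a fixed point of
        # circular smoothing, while naive smoothing corrupts the wraps
        naive_err = np.abs(wrap_phase(naive - s.data[0, 0, 0]))[..., 8:-8]
        circ_err = np.abs(wrap_phase(out.data[0, 0, 0] - s.data[0, 0, 0]))[..., 8:-8]
        assert circ_err.max() < 1e-9
        assert naive_err.max() > 1.0

    def test_commutes_with_global_offset(self, tiny_grid):
        rng = np.random.default_rng(2)
        s = _series_from(tiny_grid, lambda t: rng.uniform(-np.pi, np.pi, tiny_grid.shape))
        c = 0.9
        shifted = s.with_data(wrap_phase(s.data + c), "shift")
        a = gaussian_denoise(shifted, 1.0).data
        b = wrap_phase(gaussian_denoise(s, 1.0).data + c)
        assert np.allclose(wrap_phase(a - b), 0.0, atol=1e-9)


class TestExtractHarmonic:
    def test_pure_tone_recovered_exactly(self, tiny_grid):
        amp, theta = 0.8, 0.6
        s = _series_from(
            tiny_grid,
            lambda t: np.full(tiny_grid.shape, amp * np.cos(2 * np.pi * t / 8 + theta)),
        )
        u = extract_harmonic(s).data
        # encoding convention Re(u e^{-2 pi i t/N}): a cos(2 pi t/N + theta)
        # corresponds to u = a e^{-i theta}
        assert np.allclose(np.abs(u), amp, atol=1e-12)
        assert np.allclose(np.angle(u), -theta, atol=1e-12)

    def test_dc_offset_ignored(self, tiny_grid):
        s = _series_from(
            tiny_grid,
            lambda t: np.full(tiny_grid.shape, 0.5 * np.cos(2 * np.pi * t / 8)),
        )
        s2 = s.with_data(s.data + 1.3, "dc", wrapped=False)
        assert np.allclose(extract_harmonic(s).data, extract_harmonic(s2).data, atol=1e-12)

    def test_third_harmonic_confined_to_its_bin(self, tiny_grid):
        # fundamental + third harmonic: fundamental coefficient is exact
        s = _series_from(
            tiny_grid,
            lambda t: np.full(
                tiny_grid.shape,
                0.7 * np.cos(2 * np.pi * t / 8) + 0.3 * np.cos(6 * np.pi * t / 8),
            ),
        )
        u = extract_harmonic(s).data
        assert np.allclose(np.abs(u), 0.7, atol=1e-12)
        # DFT oracle: bin 3 carries the contamination
        spec = np.fft.fft(s.data[0, 0, :, 0, 0, 0])
        assert abs(spec[3]) == pytest.approx(0.3 * 8 / 2, rel=1e-9)

    def test_too_few_offsets_rejected(self):
        grid = AcquisitionGrid((2, 8, 8), (2.5, 2.5, 2.5), (30.0,), 4, 1)
        s = _series_from(grid, lambda t: np.zeros(grid.shape))
        object.__setattr__(grid, "n_offsets", 3)  # force a degenerate count
        with pytest.raises(ValueError):
            extract_harmonic(RawPhaseSeries(s.data[:, :, :3], grid))


class TestUnwrapGradient:
    def test_identity_up_to_constant_without_wraps(self, tiny_grid):
        rng = np.random.default_rng(3)
        smooth = rng.uniform(-1.2, 1.2, (1, 1, 1, *tiny_grid.shape))
        from scipy import ndimage

        smooth = ndimage.gaussian_filter(smooth, 4.0)
        grid1 = AcquisitionGrid(tiny_grid.shape, tiny_grid.spacing_mm, (30.0,), 8, 1)
        data = np.broadcast_to(smooth, (1, 1, 8, *tiny_grid.shape)).copy()
        s = RawPhaseSeries(wrap_phase(data), grid1)
        out = unwrap_gradient(s)
        d = out.data - data
        assert np.ptp(d) < 1e-9  # constant offset only

    def test_ramp_beyond_two_pi_recovered(self, tiny_grid):
        # 1-D ramp 0 -> 4 pi along x, wrapped; recovered up to global constant
        ramp = np.linspace(0, 4 * np.pi, 32)
        vol = np.broadcast_to(ramp, tiny_grid.shape)
        s = _series_from(tiny_grid, lambda t: vol)
        out = unwrap_gradient(s)
        d = out.data[0, 0, 0] - vol
        assert np.ptp(d) < 1e-9

    def test_wrapped_plane_wave_max_error_below_1e6(self, tiny_grid):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            field = simulate_wavefield(homogeneous_phantom(tiny_grid, 1.0, 0.0), tiny_grid)
        sens = 0.3  # peak 3 rad: wraps present
        enc = encode_phase_offsets(field, tiny_grid, sens)
        truth = np.stack(
            [
                (sens * field.data[:, :, None] * np.exp(-2j * np.pi * t / 8)).real[:, :, 0]
                for t in range(8)
            ],
            axis=2,
        )
        out = unwrap_gradient(enc)
        d = out.data - truth
        d = d - np.median(d, axis=(-3, -2, -1), keepdims=True)
        assert np.abs(d).max() < 1e-6


class TestUnwrapLaplacian:
    def test_plane_wave_recovered_up_to_affine(self, tiny_grid):
        ky, kx = 0.35, 0.55  # rad/voxel
        yy, xx = np.mgrid[0:32, 0:32]
        phase = ky * yy + kx * xx + 1.5 * np.sin(2 * np.pi * yy / 32)
        vol = np.broadcast_to(phase, tiny_grid.shape)
        s = _series_from(tiny_grid, lambda t: vol)
        out = unwrap_laplacian(s)
        res = out.data[0, 0, 0, 0] - vol[0]
        # remove best-fit affine plane, then residual must be small
        A = np.column_stack([yy.ravel(), xx.ravel(), np.ones(yy.size)])
        coef, *_ = np.linalg.lstsq(A, res.ravel(), rcond=None)
        resid = res.ravel() - A @ coef
        assert np.ptp(resid) < 0.01 * np.ptp(phase)

    def test_agrees_with_gradient_method_up_to_affine(self, tiny_grid):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            field = simulate_wavefield(homogeneous_phantom(tiny_grid, 1.0, 0.0), tiny_grid)
        enc = encode_phase_offsets(field, tiny_grid, 0.1)
        a = unwrap_gradient(enc).data[0, 0, 0, 0]
        b = unwrap_laplacian(enc).data[0, 0, 0, 0]
        yy, xx = np.mgrid[0:32, 0:32]
        A = np.column_stack([yy.ravel(), xx.ravel(), np.ones(yy.size)])
        res = (a - b).ravel()
        coef, *_ = np.linalg.lstsq(A, res, rcond=None)
        # residual after removing the Laplacian method's affine ambiguity:
        # < 2.5% of the encoded phase range
        assert np.std(res - A @ coef) < 0.025 * np.ptp(a)


class TestSuppressCompressional:
    def _tone_field(self, grid, lam_mm, amplitude=1.0):
        k = 2 * np.pi / lam_mm
        xx = np.arange(grid.shape[2]) * grid.spacing_mm[2]
        u = amplitude * np.exp(1j * k * xx)
        data = np.broadcast_to(u, (grid.n_frequencies, grid.n_components, *grid.shape))
        return ComplexWaveField(data.copy(), grid)

    def test_uniform_component_suppressed(self, tiny_grid):
        f = self._tone_field(tiny_grid, 20.0)
        uniform = ComplexWaveField(
            np.full((1, 1, *tiny_grid.shape), 2.0 + 0.0j), tiny_grid
        )
        out = suppress_compressional(uniform, BandConfig(), lowpass=False)
        assert np.abs(out.data).max() < 0.01 * 2.0  # >= 99% suppression

    def test_in_band_tone_preserved(self, tiny_grid):
        f = self._tone_field(tiny_grid, 20.0)
        out = suppress_compressional(f, BandConfig(), lowpass=False)
        inner = interior_mask(tiny_grid.shape, 4, in_plane_only=True)
        assert np.abs(out.data[0, 0][inner]).mean() == pytest.approx(1.0, abs=0.05)

    def test_butterworth_minus_3db_at_cutoff(self):
        # fixed-cutoff low-pass: tone exactly at cutoff -> amplitude 1/sqrt(2)
        grid = AcquisitionGrid((2, 8, 128), (2.5, 2.5, 2.5), (30.0,), 8, 1)
        band = BandConfig(lambda_min_mm=10.0, lowpass_per_frequency=False)
        f = self._tone_field(grid, 10.0)
        out = suppress_compressional(f, band, lowpass=True, pad=64)
        inner = interior_mask(grid.shape, 0, in_plane_only=True)
        inner[..., :20] = inner[..., -20:] = False
        gain = np.abs(out.data[0, 0][inner]).mean()
        assert gain == pytest.approx(1 / np.sqrt(2), abs=0.05)

    def test_linearity_machine_precision(self, tiny_grid, rng):
        u = ComplexWaveField(
            rng.normal(size=(1, 1, *tiny_grid.shape))
            + 1j * rng.normal(size=(1, 1, *tiny_grid.shape)),
            tiny_grid,
        )
        v = ComplexWaveField(
            rng.normal(size=(1, 1, *tiny_grid.shape))
            + 1j * rng.normal(size=(1, 1, *tiny_grid.shape)),
            tiny_grid,
        )
        a, b = 2.3, -0.7 + 0.2j
        lhs = suppress_compressional(
            ComplexWaveField(a * u.data + b * v.data, tiny_grid), BandConfig()
        ).data
        rhs = a * suppress_compressional(u, BandConfig()).data + b * suppress_compressional(
            v, BandConfig()
        ).data
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_empty_passband_warns(self, tiny_grid):
        f = self._tone_field(tiny_grid, 20.0)
        with pytest.warns(UserWarning, match="pass-band"):
            suppress_compressional(f, BandConfig(lambda_min_mm=90.0, lambda_max_mm=100.0))


def test_end_to_end_noiseless_l2_below_5_percent(grid_small, elastic_field):
    """simulate -> encode (with wraps) -> unwrap -> harmonic -> suppress
    reproduces the simulated field with < 5% relative L2 error (interior)."""
    _, field = elastic_field
    sens = 0.3
    enc = encode_phase_offsets(field, grid_small, sens)
    out = preprocess(enc, method="mdev", denoise_sigma_voxels=0.0)
    inner = interior_mask(grid_small.shape, 3, in_plane_only=True)
    ref = sens * field.data
    err = np.sqrt(
        np.sum(np.abs(out.data[..., inner] - ref[..., inner]) ** 2)
        / np.sum(np.abs(ref[..., inner]) ** 2)
    )
    assert err < 0.05
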