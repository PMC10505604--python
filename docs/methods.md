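# Methods

## Forward model

Tissue is modelled as piecewise-homogeneous, isotropic and viscoelastic
with complex shear modulus `G* = |G*| e^{iφ}` (magnitude in kPa, loss
angle φ in rad, `0 ≤ φ < π/2`) and density ρ = 1000 kg/m³ (the standard
soft-tissue assumption).  A driver launches a damped plane wave

    u(x) = A · exp(−i k n̂·x),      k = ω √(ρ/G*)  (principal branch),

so `arg k = −φ/2`, the field decays by `exp(−2π tan(φ/2))` per
wavelength, and `Δu = −(ρω²/G*) u` holds exactly.  Multiple drivers
superpose linearly; the default rig is four plane drivers entering from
the four in-plane faces (the clinical four-transducer arrangement: two
anterior, two posterior) with opposing pairs driven in antiphase
(0, π, 0, π).  Driver phasing is a free rig parameter; the antiphase
choice is 180°-rotation symmetric — so symmetrically placed ROIs see
statistically identical fields — and keeps the spatial mean of the
interference pattern small, which conditions both inversions well.  An
optional cylindrical line source is provided for point-like drivers.

Phase velocity (the quantity the SWS map estimates) is
`c = ω/Re k = √(|G*|/ρ) / cos(φ/2)`.

## Acquisition emulation

The acquisition grid mirrors the protocol: 2.5 × 2.5 mm in-plane voxels,
5 mm slices, vibration at 30/40/50/60 Hz, eight wave-phase offsets per
cycle, and up to three motion-encoding directions.  Offset `t` of `N`
stores `wrap(s · Re(u e^{−2πi t/N}))` with sensitivity `s` (rad/µm,
default 0.08 so that peak encoded phase is a few radians — wraps occur,
as in vivo).  All derived maps are invariant to `s` because every
inversion ratio is linear in `u` in both numerator and denominator, so
the scanner's gradient-strength conversion is not modelled.  Gaussian
phase noise (default σ = 0.1 rad) is added per offset and re-wrapped;
at the defaults this produces OSS-SNR values in the 3–6 dB range reported
for mesenteric fat.  The simulator warns below 8 in-plane voxels per
shear wavelength at the highest frequency.

## Preprocessing

1. **Circular Gaussian denoising** of the wrapped phase (sin and cos
   smoothed separately, recombined by arctangent; default σ = 1 voxel,
   in-plane).  This is nonlinear: for large phase amplitudes (≳ 3 rad)
   combined with wide kernels it distorts the temporal harmonic, which
   bounds the useful encoding amplitude from above.
2. **Unwrapping**, per offset volume.  The gradient method integrates
   re-wrapped finite differences row-major (corner line along z, first
   column along y, then every row along x) with per-volume median
   re-referencing — deterministic and exact for smooth fields.  The
   Laplacian method estimates `Δθ = cos θ Δ(sin θ) − sin θ Δ(cos θ)`
   slice-wise and inverts it by a DCT Poisson solve (Neumann boundary);
   it is exact up to an affine term per slice, which the wavenumber
   inversion downstream does not use.  The MDEV path uses the gradient
   method, the k-MDEV path the Laplacian method.
3. **Temporal DFT** across offsets; the fundamental bin is the complex
   harmonic field.  Constant per-volume unwrapping offsets land in the
   DC bin and never contaminate it.
4. **Compressional suppression**: slice-wise spatial Butterworth
   high-pass (order 3) below 1/200 mm⁻¹.  Compressional waves travel
   ~1500 m/s and are spatially near-uniform at 30–60 Hz; the high-pass
   removes them (and any residual unwrapping constant) with zero DC gain
   while leaving shear wavelengths up to 200 mm intact.  The MDEV path
   adds a Butterworth low-pass (order 3) whose cutoff is scaled per
   vibration frequency to a constant minimum speed of 0.3 m/s
   (wavelength 10 mm at 30 Hz, 5 mm at 60 Hz).  A fixed spatial cutoff
   would clip the 60 Hz component of slow tissue while barely filtering
   30 Hz noise; the speed-scaled cutoff regularizes the Laplacian's noise
   amplification evenly across frequencies.  Volumes are mirror-padded
   before the FFT.

All in-plane filters are 2-D slice-wise: with 2.5 mm in-plane voxels and
5 mm slices a 3-D operator would be dominated by the coarse through-plane
term, and the wavenumber inversion is slice-wise by construction.

## Inversions

**MDEV.**  `|G*| = ρ Σ ω²|u| / Σ|Δu|` and
`φ = arccos(−Σ Re(Δu ū) / Σ |u||Δu|)` (arccos argument clamped to
[−1, 1]), pooled over frequencies and components.  The Laplacian uses a
fourth-order in-plane stencil (plane-wave dispersion error `(kh)⁴/90`,
under 1% at eight voxels per wavelength, versus ~7% for the three-point
stencil at the protocol resolution).  Voxels whose pooled wave amplitude
falls below 0.4× the volume median are returned as NaN (undefined, never
zero): near interference nulls both `|u|` and `|Δu|` vanish and the
ratios become noise-dominated.  This amplitude confidence mask is the
standard accompaniment of algebraic inversions and is configurable.

**k-MDEV.**  Per slice, frequency and component the spectrum is split by
eight raised-cosine angular windows (50% overlap, partition of unity), so
counter-propagating and oblique wave packets are separated.  The local
wavenumber of each directional field is estimated from wrapped
single-voxel phase increments (mean of forward and backward
`arg(u_{i+1} ū_i)/h`), which is exact for plane waves whenever `|k|h < π`
— differentiating through the complex field instead would attenuate by
`sin(kh)/kh`, a −14% bias at 60 Hz and 1 m/s.  Candidates outside the
physical wavenumber band (below the high-pass floor or above the
two-voxel Nyquist limit) or with negligible amplitude are discarded;
surviving candidates `ω/k` are averaged with amplitude² weights.  Fields
are Tukey-apodized (taper 0.25) and zero-padded before the FFT: mirror
padding would create a counter-propagating image of every damped wave
whose fold contaminates the local phase gradient.

**OSS-SNR.**  The octahedral shear strain of the real harmonic
displacement,
`OSS = (2/3)√((ε_xx−ε_yy)² + (ε_yy−ε_zz)² + (ε_xx−ε_zz)² + 6(ε_xy²+ε_yz²+ε_xz²))`,
is compared with the OSS of a pure-noise field of the estimated sigma:
`OSS-SNR = 20 log₁₀(RMS_signal / RMS_noise)` dB.  The noise reference is
a fixed-seed Monte-Carlo quadrature (deterministic); in synthetic mode
the generator's true phase sigma is propagated to the harmonic as
`σ√(2/N)`.  With fewer than three encoding components the missing
components are treated as zero and the fallback is recorded.  The study
evaluates OSS-SNR on the unfiltered harmonic so it reflects acquisition
quality, not pipeline smoothing.

## Statistics

- ROI summaries: mean ± sample SD (n−1) over defined voxels only; an ROI
  is rejected if its largest single-slice in-plane area is below
  31.25 mm² (five in-plane voxels) or if a parameter has no defined
  voxel inside it.  A 2-voxel in-plane erosion margin is excluded from
  all map statistics.
- Two-group comparisons: Shapiro–Wilk at α = 0.05 per group; both groups
  normal → Student's t (unpaired) or paired t; otherwise exact
  Mann–Whitney U / Wilcoxon signed-rank.  Exact null distributions are
  built by dynamic programming over tie-adjusted average ranks —
  equivalent to full enumeration of all group assignments or sign
  patterns, including ties, at polynomial cost (exact up to n = 12 per
  group for the U test; a continuity- and tie-corrected normal
  approximation beyond).
- Two-sided p-values of the exact rank tests use the Lancaster **mid-p**
  convention (half the observed statistic's probability plus the more
  extreme tail, doubled, capped at 1).  With these heavily discrete
  nulls the conventional inclusive p makes the attainable size at
  α = 0.05 only 0.038 for 7 vs 7 groups, while mid-p sizes at 0.053 —
  much closer to nominal.  The inclusive convention remains available
  (`p_convention="inclusive"`).
- Spearman correlations: average-ranked ρ with exact two-sided
  permutation p for n ≤ 8 (all n! permutations of the observed values,
  inclusive tails: `p = min(1, 2·min(P(ρ* ≥ ρ), P(ρ* ≤ ρ)))`);
  t-approximation beyond.  At n = 6 the smallest attainable p is
  2/720 ≈ 0.0028, which is why perfect concordance is reported as
  p < 0.01 in degrees-of-freedom notation r(4).
- No multiple-testing correction is applied anywhere.

## Repeatability

For paired scans without repositioning: Bland–Altman bias = mean(d),
95% limits of agreement = bias ± 1.96·SD(d) (sample SD, no small-sample
t correction), and the duplicate-measurement within-subject CoV
`100·√(Σ dᵢ²/(2n)) / grand mean`.  The CoV formula follows the
root-mean-square within-subject convention for two replicates; published
within-subject CoV values are not always computed identically, so the
formula is fixed here and verified against its own Monte-Carlo oracle
(multiplicative 5% noise at n = 200 recovered within ±0.5%).

## Histology

**Generator.**  A synthetic stained section: pale Voronoi adipocyte
tessellation with slightly darker membranes, dark-red curvilinear
collagen strands (random smooth walks, width ~5 px), and an elliptical
delineated region.  Strand pixels are added one at a time until the count
inside the region equals `round(fraction × area)` exactly, so the ground
truth is reproducible to one pixel.  Default fraction 3.9%, the
study-population mean fibrotic score.

**Scorer.**  Inverted luminance (collagen stains dark) → Gaussian
smoothing (σ = 0.5 px) → three-class Otsu keeping the darkest class
(two-class Otsu latches onto adipocyte membranes when fibrosis occupies a
few percent) → marker-controlled watershed on the distance transform to
split merged strands → minimum-object-size filter (25 px) → percentage of
the delineated area.  If the selected pixels are not actually dark (mean
inverted luminance < 0.5) the section is scored 0% and flagged for manual
review; a manual threshold or a manual mask override preserves the
semi-automatic character.  Recovery on synthetic sections is within
±1% absolute at the 3.9% default and ±2% up to 50%.

MCFI (mesenteric creeping fat index) counts involved segments among
eight clockwise sectors; involvement is an input judgement, the score and
coverage percentage are derived.

## The simulated study

Defaults encode the clinical design: 7 cases vs 7 controls, 15
repeatability subjects scanned twice, 6 histology specimens.  Controls
and the repeatability arm draw |G*| ~ N(0.63, 0.10²) kPa and
φ ~ N(0.46, 0.05²) rad — centred on the values reported for healthy
mesentery; cases draw N(1.00, 0.10²) kPa and N(0.62, 0.05²) rad, shifted
by ≥ 3 between-subject SDs so the small-sample tests are expected to
reject.  Case subjects are homogeneous phantoms: the "affected" and
"presumably unaffected" ROIs sample the same tissue, encoding the
clinical finding that the two did not differ.  ROIs sit near the volume
faces where the drivers couple in (the clinical ROIs lie close to the
abdominal wall at the ileocecal junction); in a strongly damped medium
the volume centre is wave-starved.  Histology fractions (1–6%) increase
monotonically with the specimen's true wave speed, the relation the
histology arm probes; MCFI scores (~4 ± 1) are drawn independently of
stiffness, so their correlation with MRE parameters is null by
construction.

Study volumes are 40 × 40 in-plane voxels × 8 slices with a single
(through-plane) encoding component — the shear polarization of in-plane
propagating waves — which keeps a full study run around ten seconds
while exercising every stage; the pipeline itself supports three
components and arbitrary grids.

## What the generator does and does not emulate

It emulates: the acquisition geometry and vibration protocol, wrapped
multi-offset phase with Gaussian noise, multi-driver interference,
viscoelastic damping, back-to-back repeatability scans, and two-phase
stained sections with exact fibrosis truth.  It does not emulate: MR
physics (no Bloch/k-space simulation, no EPI or fat-suppression
artifacts), respiration or motion, heterogeneous tissue texture,
physiological between-scan variation (synthetic repeatability is
noise-only, so CoV/LoA are much tighter than in vivo), mode conversion
or true compressional wave content, or real stain variability.  Passing
tests therefore certify the numerical correctness and statistical
calibration of the analysis, not its in vivo accuracy.

## Known limitations

- k-MDEV SWS is biased upward for strongly damped media (the damping
  Lorentzian crosses DC, so any directional decomposition truncates it):
  about +7% at φ = 0.46 and +13% at φ = 0.6 on noiseless phantoms.
  Group contrasts and correlations are unaffected (the bias is smoothly
  monotone in the underlying parameters); absolute SWS values carry it.
- MDEV φ is noise-biased toward π/2 in low-amplitude regions; the
  amplitude confidence mask and the speed-scaled low-pass control this,
  but φ remains the most fragile of the three maps at low OSS-SNR.
- The circular denoiser distorts harmonics when encoded phase amplitude
  and kernel width are both large; encoding sensitivity should keep peak
  phase below ~3 rad.
- Exact rank tests are enumerated only up to 12 per group (U test) /
  25 pairs (signed rank); beyond that the corrected normal approximation
  is used.
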