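# Methods

## Coordinate and unit conventions

`x` lateral, `y` elevation, `z` depth; all distances in mm, times in µs,
frequencies in MHz, sound speed `c = 1.54 mm/µs` (standard soft tissue —
the value enters every delay and the wavelength `λ = c/f0 ≈ 0.1974 mm`).
Voxel positions are voxel centres, 0-based indices.

## Forward model

The simulator emulates a 32 x 32 matrix array (9.6 x 10.2 mm aperture →
0.3 / 0.31875 mm pitches) transmitting a single zero-degree plane wave.
The pulse is two cycles of a sine at `f0 = 7.8 MHz` under a Gaussian
window whose ±3σ spans the two cycles; transmit and receive share this
response, so every echo carries the pulse's self-convolution.  Echo
arrival at element `n` from a scatterer at depth `z` is `(z + r_n)/c`
with `r_n` the element-to-scatterer distance; the deposited waveform is
centred so that its *envelope peak* falls on that analytic time, which
keeps beamformed envelope maxima on the true scatterer positions.

Per-element echo amplitude is `R · a_n / r_n`: reflection coefficient,
receive element directivity `a_n = sinc(Lu/λ) sinc(Lv/λ) cosθ`, spherical
spreading.  The transmit field of a full-aperture plane wave is modelled
as uniform over the imaging cone — it is the coherent sum of 1024
element contributions, so no per-element transmit directivity factor is
applied; modelling transmit directivity per element would double-count
the aperture taper and depress side lobes well below realistic levels.
The element width defaults to 0.275 mm (the smaller pitch minus a 25 µm
kerf — matrix-array elements are square and narrower than either pitch).

Channel noise is white Gaussian at a prescribed channel SNR.  The signal
power reference is the mean squared RF amplitude over the echo-bearing
support (samples whose noiseless envelope exceeds 1 % of the frame
maximum); noise of power `P_signal · 10^(−SNR/10)` is added to every
sample, reproducibly per seed.  With several scatterers of different
strength this reference is dominated by the brighter echoes, so the
weakest scatterer sits well below the per-channel noise at the 0 dB
setting — see “Limitations”.

What the simulator does **not** model: element spatial impulse responses
(diffraction), transmit edge waves from the aperture boundary, nonlinear
bubble oscillation, phase aberration, attenuation, multiple scattering.
The first two shape the real PSF's defocus wings and the detailed channel
amplitude structure; consequently absolute side-lobe levels and the
noise response of the variance-based weights differ from full diffraction
simulations, while *relative* main-lobe and weight behaviour is
preserved.  Passing tests therefore demonstrate the beamformer algebra
and the pipeline, not full acoustic fidelity.

## Beamformers

All methods act on the per-channel analytic signal (Hilbert transform
along time, taken once per frame) sampled at the two-way delay by linear
interpolation of the complex trace.  Channels with element sensitivity
below 0.5 are excluded per voxel; `N` is the surviving count.

- DAS: `y = Σ a_n s_n`, image = |y|.
- p-DAS (p = 4): per-channel root compression `(s/|s|)|s|^{1/p}` (the
  analytic-signal generalisation of `sign(s)|s|^{1/p}`), coherent sum,
  p-th power with phase preserved.  Because the nonlinearity generates
  harmonics of the axial carrier `2 f0/c ≈ 10.1 cycles/mm`, the volume is
  reconstructed on an axial pitch of 0.01 mm (≤ voxel pitch / p and below
  the 1/(2·p·f_ax) anti-alias bound), band-pass filtered along depth with
  a zero-phase 4th-order Butterworth over [0.5, 1.5] × f_ax, enveloped,
  and down-sampled to the target grid.
- CF: `W = |Σ s_n|² / (N Σ |s_n|²)` — the 1/N normalisation makes fully
  coherent channels give exactly 1.
- CV_N / CV: `W = |Σ s_n|² / Σ |x_n − mean(x)|²` with `x_n = s_n` (plain)
  or `x_n = s_n / a_n` (inverse-apodized; removes the deterministic
  sensitivity amplitude profile so the denominator reflects true channel
  dispersion).  The numerator keeps the un-apodized coherent sum.  The
  denominator vanishes at the centre of a noiseless PSF; the weight is
  clamped at `W_max = 1e6` whenever the denominator falls below
  `1e−12 ×` the numerator.  At least two channels are required.

The volume driver accumulates the per-voxel channel sums for DAS, CF,
CV_N and CV in a single sweep (numba kernel, voxel-major loops); p-DAS
runs its own sweep on the depth-oversampled grid.  The kernels evaluate
the directivity sinc from a 4096-entry lookup table with 4-point cubic
interpolation (max error ~1.4e−14 versus direct evaluation), so the
driver agrees with the scalar per-voxel operations to float64 rounding.

## PSF metrics

- **FWHM**: width of the 1D profile through the peak at half maximum,
  crossings by linear interpolation between voxels.
- **Main lobe / side lobe**: the main-lobe region of each scatterer is an
  ellipsoid whose per-axis semi-axes are the distances from the peak to
  the first beam null (the profile's first turning point below half
  maximum; fallback 1.2 × FWHM).  A fixed 2 × FWHM radius was rejected:
  for a sinc-like beam the first side lobe sits at ≈ 1.19 × FWHM from the
  peak and would be swallowed.  The side-lobe peak of scatterer *i* is
  the maximum outside *all* main lobes within a ±1 mm depth slab around
  its peak.  `CPSMR(i, j) = 20 log10(side_i / main_j)`; the diagonal is
  the conventional (self-)PSMR, the matrix maximum the max-PSMR.
- **Image SNR**: `20 log10(mean of PSF-centre intensities / RMS of a
  noise-only region)`, the noise region being all voxels farther than
  1.5 mm from every truth position.
- **TPR/FPR**: for each retained-peak count, the k brightest
  localizations are matched one-to-one (nearest pair first) to truths
  within λ/2; TPR = matches/truths, FPR = unmatched/localizations,
  averaged over frames.  The AUC is the trapezoid of TPR over FPR across
  the achieved operating points, clipped at FPR = 0.05 by default (no
  extrapolation to FPR = 0); the full-curve area is also reported.
- **FSC**: spherical-shell normalised cross-spectrum of two volumes
  (zero-padded to a cube), crossed with the ½-bit threshold
  `T(r) = (0.2071 + 1.9102/√n_r)/(1.2071 + 0.9102/√n_r)`; the resolution
  is the inverse of the first crossing frequency.

## Localization pipeline

SVD clutter filter → beamform → 3D NCC against a simulated PSF template →
threshold + regional maxima → sub-voxel spline localization → density
map.

- The SVD filter builds the Casorati matrix (space-time samples ×
  frames).  Two parameterisations: `rank_cut` zeroes that many largest
  singular components (the usual clutter-filter control; re-applying it
  removes the *next* components, so it is not idempotent by
  construction), and `sv_threshold` zeroes all components at or above an
  absolute singular value, which is a genuine projection (idempotent).
  Default rank cut: 10 % of the frame count.
- PSF templates are simulated per beamformer: a unit point scatterer at
  the scene's centre depth reconstructed on an 11³ patch of the same
  pitch.
- NCC is Pearson-type sliding-window correlation (scikit-image
  `match_template`), values in [−1, 1]; detection keeps regional maxima
  (26-connectivity) at or above the 0.3 coefficient threshold, after
  zeroing voxels below the per-beamformer background threshold (dB
  relative to the sequence maximum).  The threshold is applied before
  peak detection.  Peaks within 2 voxels of the border are discarded.
- Each peak's 5×5×5 coefficient patch is up-sampled 10× per axis with a
  separable not-a-knot cubic spline (precomputed interpolation matrices);
  the up-sampled argmax gives the position at 1/10-voxel precision.
- The density map counts localizations per SR voxel (default pitch =
  beamforming pitch / 5); mass is conserved exactly, out-of-grid points
  are counted as dropped.
- Motion correction is an interface hook (callable per frame) and a
  no-op by default — simulated scenes have no tissue motion.

Background thresholds differ per beamformer because the weights change
the image dynamic range; `background_threshold_for_count` bisects the
threshold to match localization counts across methods (±2 % by default).

## Study problem sizes

Chosen once for single-CPU runtimes of minutes, and fixed:

- *Five-axial study*: scatterers at 15/17.5/20/22.5/25 mm, coefficients
  1 → 0.1; grid 0.05 mm restricted to ±2 mm transversally and 13–27 mm in
  depth; p-DAS on per-scatterer ±1 mm depth blocks at 0.01 mm axial
  pitch.  FWHM-reduction figures are quoted both as the ratio of mean
  widths and as the mean of per-scatterer/per-axis reductions; the two
  agree for CF and p-DAS and differ by ~2 pp for CV, whose width is
  noise-limited at the deep weak scatterers.
- *Localization ROC study*: 10 volumes of 23 scatterers uniform in a
  6 × 6 × 4 mm³ box (the 0.156 /mm³ density of a 100-scatterer
  10 × 8 × 8 mm³ scene), coefficients uniform on [0.1, 1], 0 dB channel
  SNR, 0.1 mm grid padded 0.3 mm beyond the box (p-DAS at 0.0125 mm axial
  pitch, its anti-alias bound on this grid), retained-peak sweep 5…35
  (the 20…150 sweep scaled by the same 0.23 volume factor).

## Numerical choices

- Default sampling 4·f0 = 31.2 MHz; linear interpolation of analytic
  traces for fractional delays.
- `sosfiltfilt` for the p-DAS depth band-pass (zero phase, both real and
  imaginary parts).
- CV regularisation ε = 1e−12, W_max = 1e6; CF defined 0 on an all-zero
  gather; voxels with no active channel are flagged invalid and set to 0.
- All randomness flows through `numpy.random.default_rng(seed)`; every
  scene, noise realisation and experiment is reproducible from its seed.

## Limitations

- Absolute side-lobe levels and absolute image SNRs inherit the forward
  model's simplifications (no diffraction wings, no transmit edge waves);
  relative comparisons between beamformers are the supported use.
- Under the support-based noise calibration, the weakest scatterer of the
  five-target scene sits ~20 dB below the per-channel noise at the 0 dB
  setting; all adaptive weights then compress its main lobe
  super-linearly, and the cross-PSMR of strong-scatterer side lobes over
  that weak main can turn positive.  This is a property of the scene
  conditions, not of the weights' definitions.
- The rank-cut SVD filter removes the temporal-mean component of the
  moving signal along with the clutter (retention bounded by
  (1 − 1/n_frames)²), as any subspace clutter filter does.
- Bubbles are linear point scatterers; no tracking or velocity mapping is
  provided.
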