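# Methods

## Scope and model overview

The package models a galvo-scanned, non-contact photoacoustic remote
sensing (PARS) retinal microscope paired with a swept-source OCT, and the
analysis chain that turns its raw acquisitions into en-face images,
oxygen-saturation estimates and safety budgets. The physical detection
mechanism is abstracted to a proportionality: the peak of the per-shot
transient is proportional to the local absorption coefficient times an
in-focus weight. Everything downstream of that proportionality — MAP
reconstruction, gridding, unmixing, OCT processing, safety rules — is
implemented in full.

## Hemoglobin optics

Blood absorption is μ_a(λ) = ln10·(ε_HbO₂(λ)·C_HbO₂ + ε_Hb(λ)·C_Hb) with
relative (unitless) concentrations; SO₂ is scale-invariant, so absolute
molarity and any wavelength-common gain (fluence, detector response)
cancel. Fluence is treated as wavelength-flat over the shallow imaging
depth (< 5 mm), so no fluence correction is applied; a per-wavelength gain
hook exists in the unmixing input but defaults to unity.

The shipped extinction table (`_data/hb_extinction_synthetic.csv`,
`source_id = synthetic-hb-compilation-v1`) is a **synthetic compilation**:
it reproduces the qualitative features of published whole-blood spectra
(Soret tail below 480 nm, oxy double peak near 540/576 nm, deoxy peak near
555 nm, crossings near 500/545/570/584 nm, NIR isosbestic near 800 nm)
with approximate magnitudes. The key structural facts the method rests on
hold exactly: ε_Hb(558) > ε_HbO₂(558) and a well-conditioned 532/558
basis (condition number ≈ 4). Because the simulator and the unmixer share
one table, all round-trip and accuracy results are self-consistent; for
quantitative work on real data, supply a measured tabulation via
`ChromophoreTable.from_csv` — the interpolation is piecewise-linear
(monotone, never extrapolating) by design.

## Synthetic data generator

The generator replaces the instrument and defines the conditions every
test runs under:

- **Geometry.** Capillary preset: one straight 100 µm-diameter tube in a
  300 × 300 µm field with an optional Gaussian focal waist — the in-vitro
  saturation target. Retina preset: 2.6 × 2.6 mm field, eight vessels
  radiating from an optic-nerve-head disc, radii spanning 10–60 µm
  (diameters 20–120 µm), arterial branches at SO₂ 0.95 and venous at 0.70.
  Fiber presets: 7 µm carbon-fiber strings behind human-eye (17 mm) and
  rat-eye (6 mm) chambers, wavelength-flat absorbers. Vessels with
  different SO₂ may not overlap (ground truth would be ambiguous; the
  constructor rejects it).
- **Scanning.** Row-major unidirectional raster, one shot per commanded
  position per wavelength, shot clock at the 60 kHz pulse repetition rate.
  The default rasters (≈ 80–120 points per axis) keep a full acquisition
  well under 6 s of instrument time. The actual galvo trajectory of a real
  system (bidirectional, fly-back) is not modelled.
- **Transient.** A damped 40 MHz oscillation whose first sample is the
  peak; since MAP consumes only max|trace|, the shape is a nuisance
  parameter and carries no physics.
- **Motion.** Smooth sinusoidal displacement (x/y dephased), emulating
  breathing-induced drift of an anesthetised animal; saccades are absent
  under anesthesia and are not modelled. Default amplitude is zero.
- **Noise.** Additive white Gaussian noise on the traces, calibrated in
  one pass to a target *image-domain* SNR (default 26 dB), defined as
  20·log₁₀(mean signal amplitude / background standard deviation) on the
  reconstructed image. The calibration predicts the background sd of the
  gridded MAP image as sd(max|noise trace|) × √½ — the √½ is the mean
  squared barycentric weight over a generic triangle, i.e. the variance
  reduction of linear interpolation between independent noisy samples.
  On grids whose nodes coincide with sample positions the factor is 1 and
  the measured SNR reads ≈ 3 dB below target; on generic grids it lands on
  target within the instrument-like ±3 dB spread.
- **OCT frames.** Each A-line is reference(k) + Σ r_i·cos(2 k z_i + φ(k))
  on a linear-in-k grid (vertical-cavity swept source ⇒ no resampling by
  default; a linear-resampling hook exists). The dispersion phase
  φ(k) = Σ_{j=2..5} a_j u^j uses the normalised coordinate
  u = (k − k₀)/halfspan with coefficients in radians, keeping magnitudes
  O(1–10) across orders. The nominal instrument figures (2448 samples,
  ~12 mm stated depth range, 7.3 µm axial resolution) are recorded as
  frame metadata only; they do not follow from the sampling closed forms
  alone and are never asserted.

Determinism: every stochastic stage consumes a `numpy` generator spawned
from the configuration seed; identical configurations give bit-identical
streams, frames and serialized files.

What the generator deliberately omits — rigorous photoacoustic wave
propagation, eye-optics aberrations, absorption saturation at high μ_a,
RPE melanin (off by default), vessel depth structure — bounds what passing
tests show: they validate the *analysis chain* under the stated forward
model, not instrument hardware.

## Reconstruction

MAP is max|trace| (no envelope/Hilbert step): the minimal reading of
"maximum amplitude", symmetric under sign flip. Gridding Delaunay-
triangulates the scattered (x, y, amplitude) samples and evaluates the
barycentric-linear interpolant at grid nodes (`scipy` `Delaunay` +
`LinearNDInterpolator`); nodes outside the convex hull are masked, never
filled. Samples are canonically sorted before triangulation so the result
is permutation-invariant even on co-circular (regular-raster) point sets,
where triangulation tie-breaking is otherwise input-order dependent.
Exactly repeated positions are averaged (dwell shots are physical
averaging), with a warning when the duplicates disagree. Reconstruction
uses actual (motion-displaced) positions by default, so motion appears as
geometric distortion exactly as in the instrument; `use_commanded=True`
grids on the ideal raster. Masked pixels export as 0 in TIFF with the mask
as a companion channel. The default reconstruction grid (512 px across the
field, tests use smaller) is this package's choice, not an instrument
property.

## Oximetry

The estimator is the mean-value method: a representative mean amplitude
per wavelength over an in-focus sub-region, then a least-squares solve
against the extinction basis (closed-form 2 × 2 for two wavelengths).
Averaging before unmixing suppresses per-pixel noise ∝ 1/√n. The focus
policy — pixels above the 80th amplitude percentile, largest connected
component — is declared plumbing for the unspecified "adequately in focus"
criterion and is swappable. Solutions outside the physical cone c ≥ 0 are
projected onto it (non-negative least squares) and flagged; a tolerance of
1e-9 relative distinguishes genuine clamping from round-off. The basis
condition-number ceiling is 1e6 (532/558 sits near 4). SO₂ maps paint one
value per segmented vessel, not per pixel; the default segmentation
(threshold + connected components on the 532 nm image) is likewise
declared plumbing. No normalisation by vessel size or depth is applied.

Known limitation: under additive trace noise, MAP is positively biased
(max of signal+noise exceeds the signal peak), which adds a common offset
to both wavelengths' means and pulls SO₂ toward the fixed point where the
two μ_a curves cross (≈ 0.61 for this table) — a few points of systematic
bias at 26 dB, strongest for dim edge pixels. The accuracy statistic
reported throughout is the *standard deviation* of estimate-minus-truth
(the oximetry convention), which this bias does not inflate; the bias
itself is reported alongside and left uncorrected, as the mean-value
method defines no bias correction.

## OCT reconstruction

Reference subtraction removes the DC term per A-line (a second call on the
same frame warns — the operation is not idempotent). Dispersion
compensation multiplies the analytic signal (one-sided spectral filtering
via the Hilbert transform) by exp(−iφ(k)) and keeps the real part; zero
coefficients reproduce the input exactly. Coefficient estimation minimises
the Shannon entropy of the B-scan intensity by coordinate descent over the
requested orders plus a Nelder–Mead polish. The metric transform is
Hann-apodised and 4× zero-padded: without this, sinc leakage from off-bin
reflectors biases the entropy optimum away from the physical coefficients
(odd orders can partially "apodise" leakage tails); with it, injected
(a₂, a₃) are recovered to well under 5% and compensation restores the
transform-limited peak width. Frames without structure (peak/median
contrast below 3) raise a non-convergence error rather than returning
noise-fitted coefficients. Depth axes are reported in air; tissue scaling
divides by a group index of 1.38.

## Laser safety

Only the rule branches a visible-wavelength, nanosecond-pulse, scanned
retinal system exercises are implemented — point sources (α < 1.5 mrad),
400–700 nm single pulses of 1 ns–18 µs, dual average limits for
0.7 s < t ≤ 100 s at 400–600 nm, the n^−0.25 repetitive-pulse correction,
and the 380–1400 nm flat corneal limit. Everything else raises an
unsupported-branch error instead of guessing standard tables. The
photochemical correction is C_B = 10^{0.02(λ−450)}. For the scanned beam,
the average-exposure (Rule 2) limit converts to a per-pulse equivalent by
dividing by the number of pulses a single retinal spot receives during the
exposure — the n overlapping pulses (default 2; a helper computes
⌈spot/step⌉ from the raster) — because the beam moves on after those; the
`stationary_beam` option divides by the total pulse count t × PRR instead,
which is the correct conversion for an unscanned beam and makes Rule 2
bind by orders of magnitude. With the scanned conversion Rule 3
(n^−0.25 × MPE_SP) governs. Reported values truncate limits toward zero at
2–3 significant figures (truncation is the conservative direction for a
limit; geometric quantities round); internal values keep full precision.
The corneal-limit branch point at t = 10 s (25·10^−0.75 ≈ 4.45 vs 4.0
beyond) is a documented discontinuity of the flat-limit formulation and is
implemented exactly as stated.

## Problem sizes and numerical choices

Test and analysis runs use rasters of 40–120 points per axis,
reconstruction grids of 48–128 px, OCT frames of 8–64 A-lines × 256–1024
samples, and 8–20 seeded repetitions per statistic — sizes chosen so the
full chain (not a shortcut) runs in seconds per experiment while every
statistic it reports is stable across seeds. Tolerances: noiseless
forward/inverse SO₂ recovery is asserted at 1e-6 absolute; affine-field
gridding at machine precision; dispersion coefficients at 5% relative;
peak-width restoration within one depth bin; SNR calibration within the
±3 dB instrument spread; saturation accuracy at ≤ 6 percentage points
(sd). Degenerate inputs fail loudly: collinear point sets, empty traces,
empty wavelength lists, out-of-span wavelengths, overlapping conflicting
vessels, structureless OCT frames, zero-signal regions.
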