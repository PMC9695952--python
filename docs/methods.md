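# Methods

## The measurement problem

A miniature spectral sensor chip under LED illumination measures skin
reflectance *R(λ)* on 400–1000 nm, but with systematic error relative to a
bench spectrometer: limited optical bandwidth, wavelength-dependent gain
that calibration does not fully remove, offset, and noise. The package
models the visible part of this error as learnable and removes it with a
residual CNN; all downstream skin quantities are closed-form functions of
the (enhanced) spectrum.

## Spectral grids and interpolation

The enhancer operates on the canonical **visible67** grid: 67 points,
400–730 nm inclusive, hence a 5 nm step ((730−400)/66). The near-infrared
tail (to 1000 nm) is never enhanced; the melanin-index band (880 nm) and
body-fat bands (937/947 nm) always read the raw spectrum. Resampling and
single-wavelength lookups are linear interpolation — the simplest
monotonicity-preserving scheme — and extrapolation is always an error:
invented reflectance would silently corrupt the log-ratio indices.
Reflectance is stored as a fraction (not percent); values above 1 are
allowed with a warning (calibration overshoot), negatives are rejected.

## Synthetic paired data

The generator replaces a hardware data collection (16 subjects × 9 body
sites, paired low-cost/reference measurements; on the order of 900 training
and 400 evaluation spectra). Defaults: `n_subjects=16, n_sites=9,
repeats=7` → 1008 pairs; `repeats` is exposed because the per-site repeat
count of such a collection is not fixed by the protocol.

**Skin model** (reference channel): `R(λ) = B · exp(−m·a_m(λ)) ·
exp(−h·a_h(λ))`, with `a_m(λ) = (400/λ)³` (melanin absorbs more at short
wavelengths; normalized to 1 at 400 nm) and `a_h(λ)` a pair of Gaussians at
545 nm (σ = 13) and 575 nm (σ = 11, ×0.9) mimicking the oxyhemoglobin
bands. Subject parameters are drawn per subject (melanin 0.25–2.0,
hemoglobin 0.1–0.6, baseline 0.40–0.68, uniform), sites modulate them
deterministically (sun-exposed sites darker, cheeks more perfused), and a
small seeded scale/tilt perturbation (2 %) individualizes repeats. This is
deliberately phenomenological, not radiative transfer: the enhancer only
needs the statistical shape of skin spectra (smooth, pigment-darkened,
green dip). Green tests therefore establish that the *method* works on
spectra with these statistics — not that any absolute accuracy transfers to
a physical device.

**Sensor model** (degraded channel), applied in order blur → ripple →
offset → noise (optical bandwidth first, electronics after): Gaussian blur
FWHM 14 nm, multiplicative ripple amplitude 0.035 with 80 nm period (fixed
phase — a property of the sensor, hence learnable), offset +0.008, Gaussian
noise σ = 0.012, clip at 0. These defaults were calibrated **once** by
simulation so the mean degraded-vs-reference MSE (~3×10⁻⁴ over 100 seeds)
sits in the few-10⁻⁴ band typical of an uncorrected low-cost sensor, and
are not revisited; the test suite asserts the band [2×10⁻⁴, 3×10⁻³].

## Enhancer

1×67 → 41×67 stacking replicates the spectrum row (original + 40 copies);
this is the only reading consistent with a 41-row image and with the
41-pixel receptive field of the default 20-layer chain (side 2N+1). The
output image's **middle 50 % of rows** is taken as the 21 centered rows
(0-based 10..30; round(0.5·41) = 21, symmetric) and averaged column-wise;
the average is computed relative to a pivot row so the no-network path
(stack → unstack) is bitwise exact.

Architecture: N zero-padded 3×3 conv layers; 1→64 channels, 64→64 hidden
with ReLU, final 64→1 reconstruction layer without activation; global
residual skip (output = input + residual), the standard behavior for this
family of super-resolution networks, toggleable. No input normalization:
reflectance fractions are already ≈[0, 1], and avoiding hidden scaling
state keeps model files self-contained.

Because no deep-learning framework is available in the target environment,
convolutions are implemented with im2col + BLAS matmul in float32 and
backpropagation is written out explicitly; backward passes recompute the
patch matrix from stored activations rather than caching it (9× memory
saving). Training: Adam (β₁ 0.9, β₂ 0.999), learning rate 1e-3, batch 16,
100 epochs, global-norm gradient clipping at 1.0, MSE on the 2D stacked
representation (network-native; a 1D-loss variant on the averaged rows is a
config switch). These hyperparameters are package choices, declared rather
than inherited. All randomness (init, split, shuffling) flows from explicit
seeds through `numpy.random.default_rng`, so identical seed + data + config
reproduces identical weights bitwise.

A reduced **test profile** (N = 8 layers, 16 filters, 200 pairs, 30 epochs)
exists so the end-to-end stochastic check runs in minutes on one CPU; the
16-filter width is part of that profile (the default 64 filters would be
~16× slower in numpy for no change in what the check establishes). On this
profile the held-out MSE reduction is ~79 % with ΔE\* and Δxy also reduced
— the off→on ordering that constitutes the acceptance surface. Absolute
error values of any physical device are out of reach by construction (no
deposited measurements exist); only the ordering and magnitude regime are
claimed.

## Colorimetry

Tristimulus: `X = k·Σ R S x̄ Δλ` (likewise Y, Z), `k = 100/Σ S ȳ Δλ`,
summed on visible67. Defaults D65 / CIE 1931 2° — the dominant convention
for reflectance colorimetry; the source convention is unknown, so absolute
Lab values are convention-dependent, but every comparative metric (ΔE\*,
Δxy) uses the same settings on both spectra and cancels the choice. The
color-matching functions are the Wyman–Sloan–Shirley multi-lobe Gaussian
analytic fit of the 1931 observer (accurate to ~1 % of peak), and D65 is
the standard 10 nm abridged SPD linearly interpolated to 5 nm; both are
tabulated once into a package-data CSV with provenance comments.
Integration is truncated to 400–730 nm (the only range an enhanced
spectrum covers) and k is computed over the same range, so the perfect
reflector is exactly Y = 100 / L\* = 100; this is a documented systematic
difference from full-range colorimetry. ΔE\* is CIE76 (plain Euclidean) —
matching the plain "ΔE\*" convention — not CIEDE2000.

## Skin analyses — conventions and edge cases

* **EI/MI** use base-10 logarithms (the dermatological absorbance
  convention). The default EI wavelength pair is (880, 570) nm, as used by
  the source application, although 880 nm is infrared and the classical
  erythema convention uses red ≈ 660 nm; the pair is therefore a parameter
  (`red_nm=660` restores the classical form). Non-positive reflectance at
  an operand wavelength is a domain error.
* **ITA/Fitzpatrick**: boundary angles (55, 41, 28, 10, −30 — which strict
  published inequalities leave unassigned) go to the darker class, making
  the bands lower-open/upper-closed and the labeling total. b\* = 0
  degenerates to ±90° (sign of L\*−50) or 0; negative b\* is evaluated with
  the same formula but flagged — it is outside the validity domain for
  skin and must not crash a report.
* **Palette matching** breaks ΔE\* ties to the lexicographically smallest
  id. Commercial skin-tone guide colors are proprietary, so palettes are
  user-supplied CSV; the shipped 30-entry palette is synthetic (generated,
  labeled as such) for tests and demos.
* **Sun exposure** maps the ITA label to phototype I–VI in order
  (Very light→I … Dark→VI) unless overridden — a documented assumption, as
  no published mapping accompanies the timing formula.
* **Body fat** uses the published example regression constants
  K = (84.2, −16.3, −6.2, 8.1, −13.7, −124.2, −81.4); they are example
  values from a patent-style multiple regression, not calibrated to any
  population, and outputs should be read accordingly.
* **analyze()** splices the enhanced 400–730 nm portion with the raw
  spectrum above 730 nm; EI/MI visible operands default to the spliced
  spectrum (raw-only switch available). Missing NIR coverage yields an
  explicit partial report naming the missing outputs and reasons.

## Evaluation

Per-spectrum metrics (MSE over the shared grid; ΔE\* and Δxy from each
spectrum's colorimetry) are computed pair-by-pair and aggregated as the
unweighted mean — per-spectrum-then-average, which is stated here as this
package's definition since the alternative (metrics of averaged spectra)
is not distinguishable from published summaries.

## Known limitations

* The skin and sensor models are statistical stand-ins; chromophore
  extinction coefficients are not physical, and no claim transfers to real
  hardware without retraining on measured pairs.
* The CMF analytic fit differs from the tabulated 1931 observer by up to
  ~1 % of peak; comparative metrics are unaffected, absolute XYZ
  negligibly so relative to the truncation-to-730 nm choice.
* Training is single-threaded numpy; the default 20-layer/64-filter
  profile trains in hours, not minutes — use the test profile for CI-scale
  experiments.
* The enhancer assumes the degradation statistics of training; a sensor
  with different ripple phase/period requires retraining.
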