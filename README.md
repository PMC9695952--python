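# skinspec

Toolkit for **low-cost skin reflectance spectroscopy**: it takes the noisy,
distorted reflectance spectra produced by miniature spectral sensor chips,
cleans them with a very-deep residual convolutional network, and derives the
standard dermatological and colorimetric quantities from the result.

Intended users: researchers prototyping low-cost optical skin measurement
(biomedical optics, cosmetology, personal-health devices) who need a tested,
reproducible software stack — without the hardware — for the whole chain
from raw spectrum to skin-tone report.

## What it does

A cheap spectral sensor (LED illumination, simple optics, miniature filter
array) measures skin reflectance *R(λ)* with systematic gain ripple, limited
optical bandwidth, offset and noise relative to a bench spectrometer. The
package addresses this in five parts:

1. **`synthetic`** — a generator of paired (degraded, reference) skin
   spectra. Skin is modeled phenomenologically as a baseline attenuated
   Beer–Lambert-style by melanin (power-law in λ) and hemoglobin (two
   absorption bands near 545/575 nm); the sensor model applies Gaussian
   blur → sinusoidal gain ripple → offset → noise. It stands in for a
   16-subject × 9-site paired data collection.
2. **`enhancement`** — the spectral enhancer. A 1×67 visible-range spectrum
   (400–730 nm, 5 nm step) is stacked into a 41×67 image, passed through an
   N-layer residual CNN of 3×3 convolutions (default N = 20, 64 filters,
   ReLU, zero padding; receptive field (2N+1)² = 41×41), and the middle 50 %
   of output rows (the 21 centered rows) are averaged back to 1×67.
   Implemented in pure numpy (im2col convolutions, manual backprop, Adam);
   training minimizes the MSE against the reference channel.
3. **`colorimetry`** — CIE XYZ / xy / CIELAB under D65 and the 1931 2°
   observer (tables shipped as package data), CIE76 ΔE\* and Δxy.
4. **`skin_apps`** — the five closed-form analyses:
   * erythema / melanin index: `(500/log₁₀5)·(log₁₀(R_a/R_b) + log₁₀5)`
     (500 at unit ratio),
   * individual typology angle `ITA° = arctan((L*−50)/b*)·180/π` with the
     six-band Fitzpatrick classification (thresholds 55/41/28/10/−30),
   * nearest-palette matching by ΔE\*,
   * vitamin-D sun-exposure timing `TRSVD = SDD/irradiance`,
     `RMSET = 4·TRSVD` (SDD by phototype: 37.2 … 185.1 J/m²),
   * NIR body-fat regression on R(937 nm), R(947 nm) and anthropometrics.
5. **`evaluation`** — the off/on comparison table: mean MSE, ΔE\* and Δxy of
   degraded-vs-reference and enhanced-vs-reference spectra.

A `skinspec` CLI (`simulate`, `train`, `enhance`, `analyze`, `evaluate`)
ties these into a reproducible workflow driven by a YAML config and a seed.

## Worked example

```python
import skinspec as ss
from skinspec.synthetic import SkinParams, simulate_skin_reflectance
from importlib import resources

spectrum = simulate_skin_reflectance(
    SkinParams(melanin_level=0.9, hemoglobin_level=0.4, baseline=0.55),
    grid=ss.full_grid(), seed=11)
palette = ss.read_palette(str(resources.files("skinspec.data")
                              .joinpath("synthetic_skintone_palette.csv")))
report = ss.analyze(spectrum,
                    metadata=ss.SubjectMetadata(150, 70, "female"),
                    palette=palette, uv_irradiance_w_per_m2=0.25)
```

prints (via the report fields):

```
L*a*b*        = (63.5, 8.7, 4.1)
EI / MI       = 695 / 539
ITA           = 73.1 deg -> Very light
palette match = ST09 (dE* = 11.79)
sun exposure  = TRSVD 149 s, max 595 s (type I)
body fat      = 81.6 %
```

EI > 500 says the 880 nm band reflects more than the 570 nm band (the
hemoglobin dip); the ITA angle classifies the tone; TRSVD is how long this
phototype needs at 0.25 W/m² UV to synthesize a standard vitamin-D dose.
The numbers describe the *synthetic* spectrum — its flat spectral slope
gives a low b\*, hence the high ITA, and the body-fat value reflects the
published example regression constants, not a calibrated instrument.

Training end to end (reduced CI profile: 8 layers × 16 filters, 200 pairs,
30 epochs, seed 7) takes ~2.5 min on one CPU and yields, on 25 held-out
pairs:

```
off: mse 3.006e-04  dE 1.155  dxy 0.00240
on : mse 6.220e-05  dE 0.833  dxy 0.00213   (MSE reduced 79.3 %)
```

i.e. the enhancer removes ~80 % of the squared spectral error and improves
the color accuracy — the qualitative off→on ordering the method is built to
deliver.

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, by running the package operations on freshly built inputs, the
desk-scale headline quantities (receptive-field side of the 20-layer
network, stacked-image row count, vitamin-D synthesis times for phototypes
I and VI at 1 W/m², and the erythema/melanin index at unit reflectance
ratio) and writes them as JSON.
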