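# nanodose

Carbon-ion dosimetry and range verification with phase-change ultrasound
contrast agents, simulated and analysed end to end.

Superheated perfluorobutane (PFB, C₄F₁₀, boiling point −2 °C) nanodroplets
dispersed in a tissue-mimicking phantom stay liquid at body temperature
until a particle with high enough linear energy transfer (LET) crosses
their core. A carbon-ion beam reaches such LETs only near the end of its
range — at the Bragg peak — so the droplets vaporize into echogenic
microbubbles in a narrow band there, visible as bright contrast in
ordinary B-mode ultrasound. Quantifying that contrast gives a
sub-millimetre, dose-sensitive readout of the beam range.

`nanodose` is for medical-physics researchers who want a tested, fully
synthetic testbed for this measurement chain: it simulates the physics
(nucleation thresholds, depth-dose and depth-LET curves, stochastic
droplet vaporization, speckle-realistic B-mode frames) and implements the
grayscale-profile analysis (thresholding, background subtraction,
calibration, Gaussian peak fitting, distal-fall range metrics,
dose-response fitting).

## The models in brief

* **Thermal-spike nucleation.** A droplet's degree of superheat is
  `s = (T − T_b)/(T_c − T_b)`; vaporization requires a critical vapor
  embryo of radius `R_c = 2σ/(p_v − p₀)` and energy
  `W_tot = 4πR_c²σ + (4/3)πR_c³ρ_v h_fg`, giving an LET threshold
  `LET_th = W_tot/(2R_c)`. For PFB at 37 °C this evaluates to s = 0.34 and
  `LET_th ≈ 140 keV/µm`.
* **Beam.** Analytic pristine Bragg curves (CSDA rise ⊗ Gaussian range
  straggling) whose distal W₈₀ is pinned to requested values; SOBP
  stacking by non-negative least squares; dose ↔ fluence at
  1.25×10⁷ C-ions/cm² per Gy; a calibrated depth-LET surrogate that
  crosses `LET_th` where the dose first reaches 60% of its peak.
* **Vaporization.** One-hit superheated-detector model:
  `p(z) = 1 − exp(−ε σ_geom F(z) g(z))` with the surviving-ion fluence
  `F(z)` and an above-threshold LET ramp `g(z)`; spontaneous vaporization
  is size-dependent and rare. Dose-rate independent by construction.
* **Imaging.** Rayleigh speckle, PSF-blurred bubble echoes, echo
  saturation, acoustic shadowing, fixed-gain log compression, 8-bit
  frames, 3-frame scan protocol.
* **Analysis.** Isodata threshold → depth-aggregated lateral grey
  profiles → pre-scan subtraction → mm calibration → n = 6 averaging →
  `GaussianPeakModel(...).fit()` (a statsmodels-style results object) →
  FWHM/W₈₀/area/distal-50%-fall → `DoseResponseModel` (4-parameter
  logistic) for the dose sweep.

See `docs/methods.md` for assumptions, parameter defaults and limits.

## Worked example

Simulate the reference irradiation (1 Gy at the Bragg peak, 180 mm range,
4×10⁶ ND/ml, two phantoms × three frames) and fit the vaporization peak
against the reference depth-dose curve:

```python
import numpy as np

from nanodose.beam import curve_metrics
from nanodose.experiments import phantom_profiles, reference_beam, simulate_phantom
from nanodose.imaging import USImagingConfig
from nanodose.phantom import PhantomSpec
from nanodose.profiles import GaussianPeakModel, average_profiles

curve, letc, beam = reference_beam(180.0, dose=1.0)
spec = PhantomSpec(entrance_position=144.0)
imaging = USImagingConfig()

profiles = []
for sub in np.random.SeedSequence(7).spawn(2):
    sim = simulate_phantom(spec, imaging, sub, layers=[(curve, letc, beam)])
    profiles.extend(phantom_profiles(sim, spec, imaging))

result = GaussianPeakModel(average_profiles(profiles), reference=curve).fit()
print(result.summary())
m = curve_metrics(curve)
print(f"dose curve: peak {m.peak_position:.2f} mm, R50 {m.R50_distal:.2f} mm, "
      f"W80 {m.W80:.2f} mm")
```

prints

```
Gaussian peak fit
========================================
 amplitude:    29.1238 +/- 0.2650
    center:   178.9387 +/- 0.0175
     sigma:     1.7012 +/- 0.0187
  baseline:     0.8670 +/- 0.0802
      FWHM:     4.0060
       W80:     2.2730
      area:   124.1925
     x_end:   182.5895  (baseline + 10% amplitude)
    fall50:   181.0887
       R^2:   0.980860
   shift50:     0.0914
dose curve: peak 178.81 mm, R50 181.00 mm, W80 3.04 mm
```

Reading this: the vaporization peak sits on the Bragg peak (center
178.9 mm vs dose peak 178.8 mm), is *narrower* than the dose peak
(W₈₀ 2.27 mm vs 3.04 mm — only near-peak LETs vaporize droplets), and its
distal 50% fall recovers the beam's distal R50 to 0.09 mm (`shift50`).
`area` is the integrated contrast used for dose-response curves; it grows
linearly with dose below ~1 Gy and saturates above ~2 Gy.

The same experiments are scriptable from the shell:

```bash
nanodose reproduce dose_effect --seed 0 --out runs/dose_effect
nanodose report runs/dose_effect
nanodose fixtures --seed 0 --out fixtures/
nanodose analyze fixtures/reference_1gy_180mm/*pre_f1.tif \
                 fixtures/reference_1gy_180mm/*post_f1.tif
```

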