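# Methods

`nanodose` simulates and analyses ultrasound-based dosimetry of carbon-ion
beams with superheated perfluorocarbon nanodroplets. This note records the
models, their assumptions, the tunable parameters that matter, and the
limits of what the synthetic data can show.

## Nucleation physics (`nanodose.nucleation`)

A perfluorocarbon (PFC) droplet held above its boiling point is metastable;
its degree of superheat is `s = (T - T_b)/(T_c - T_b)`. A charged particle
crossing the core deposits energy in a thermal spike; vaporization requires
nucleating a critical vapor embryo of radius `R_c = 2 sigma(T)/(p_v(T) -
p_0)` at an energy cost

```
W_tot = 4 pi R_c^2 sigma(T)  +  (4/3) pi R_c^3 rho_v(T) h_fg(T)
```

(surface formation plus vaporization enthalpy; an optional reversible
expansion-work term `(4/3) pi R_c^3 (p_v - p_0)` is off by default). The
particle must supply `W_tot` over a track segment of one critical diameter,
so the stopping-power threshold is `LET_th = W_tot/(2 R_c)`, reported in
keV/µm.

Thermophysical closures for the shipped PFC table
(`nanodose/data/pfc_properties.csv`) are standard engineering correlations:

* surface tension `sigma = sigma_ref ((1 - T/T_c)/(1 - T_ref/T_c))^1.26`
  (Guggenheim–Katayama), anchored at 9.5 mN/m at 25 °C for
  perfluorobutane (PFB, C4F10);
* vapor pressure: two-point log-linear Antoine form through the boiling
  point (1 atm) and the critical point (23.23 bar for PFB);
* latent heat: Watson correlation (exponent 0.38) anchored at the boiling
  point (96.3 kJ/kg for PFB);
* vapor density: ideal gas at `p_v(T)` — the simplest defensible closure;
  a few percent low near the critical region, irrelevant at 37 °C.

For PFB (T_b = −2 °C, T_c = 113.2 °C) at 37 °C and 1 atm this yields
`s = 0.34` and `LET_th ≈ 141 keV/µm`, decreasing monotonically with
temperature. The threshold is sensitive mainly to the vapor-pressure and
latent-heat closures; alternative literature correlations move it by about
±10%. Lower-boiling PFCs (perfluoropropane) are included for comparison;
their thresholds are far lower, which is why they are less specific to
heavy ions.

## Beam model (`nanodose.beam`)

The depth-dose curve is an analytic stand-in for a measured one: a
CSDA-style `1/sqrt(R - z)` stopping-power rise (capped one grid step from
the end of range) convolved with a Gaussian range-straggling kernel. The
kernel width is solved by bisection so the distal W80 (full width at 80% of
the peak) matches a requested value — the curves used throughout are pinned
to measured W80 values of 2.72 mm (50 mm range) and 3.04 mm (180 mm range).
A constant fragmentation tail (default 5% of peak) extends beyond the peak.
Grid step 0.05 mm, ten times finer than the sub-millimetre claims being
tested. Spread-out Bragg peaks are weighted sums of pristine peaks; the
flat-plateau weights come from non-negative least squares on the modulation
span.

Depth-LET is a calibrated monotone surrogate, not a transport calculation.
Proximal of the peak, LET rises as a power of the relative dose with the
exponent chosen so LET crosses the droplet threshold exactly where the dose
first reaches 60% of its peak — the onset depth the study design anchors.
The peak value (default 290 keV/µm, a plausible track-averaged LET at the
Bragg peak of a ~300 MeV/u carbon beam) is a free parameter; the crossing
depth is invariant to it by construction. Distal of the peak the
track-average decays slowly (`(dose/peak)^0.3`), staying above threshold
down to roughly the distal 10%-of-peak depth: ions still travelling there
are at end-of-track LET, so near the end of range the spatial confinement
of vaporization is governed by the stopping-ion fluence, not by an abrupt
LET cut.

Dose at the Bragg peak maps to fluence linearly at 1.25×10⁷ ions/cm² per
Gy. The fraction of primary ions surviving to depth z is
`Phi(z) = 0.5 erfc((z - R̄)/(sqrt(2) sigma_s))` with `sigma_s` the
straggling width.

## Vaporization model (`nanodose.phantom`)

Droplets are uniform in the phantom (homogeneous dispersion), with
truncated log-normal diameters (median 700 nm, geometric SD 1.25, bounds
200–1000 nm; sample mean ≈ 700 ± 100 nm). Only droplets inside the imaged
slabs are instantiated; Poisson sampling of the count preserves
concentration semantics exactly.

Spontaneous vaporization is an independent Bernoulli per droplet with
probability growing exponentially in diameter (Laplace-pressure
stabilization is weakest for the largest droplets); the default rate gives
a few tens of spots per frame before irradiation.

Radiation-induced vaporization is a one-hit superheated-detector model:

```
p(z) = 1 - exp( - efficiency * sigma_geom(d) * F(z) * g(z) )
```

with `sigma_geom` the droplet's geometric cross-section, `F(z)` the
surviving primary fluence, and `g(z)` an above-threshold ramp:
`(LET(z) - LET_th)/(LET_max - LET_th)` clipped to [0, 1] proximal of the
LET maximum, and 1 distal of it (the falling track-average distally
reflects the already-stopped fraction, which `F(z)` accounts for). The
ramp encodes the heterogeneity of track LETs near onset — vaporization
rises gradually from the 60%-dose onset to the peak — and is what makes
the vaporization peak *narrower* than the dose peak, as observed. A hard
threshold gate (`let_ramp=False`) is retained for comparison. The model
depends only on total fluence, never on delivery rate, so dose-rate
independence holds by construction.

The `efficiency` scalar (default 0.015) folds shell stabilization into the
geometric cross-section: far fewer droplets vaporize per unit fluence than
bare superheated-drop theory would give, which is what keeps 1 Gy in the
sparse, linear contrast regime (discrete bright spots) with saturation
appearing only at ≥ 2 Gy.

Vaporized droplets become bubbles with radius = liquid radius × the
ideal-gas expansion factor `(rho_liq R T/(p M))^(1/3)` ≈ 5.5 for PFB at
body conditions (an override is available; a factor of 10 is sometimes
quoted for acoustically triggered vaporization, but the ideal-gas value is
the self-consistent default here).

### Survival-midpoint calibration

The study's central empirical finding is that the vaporization profile's
distal 50% fall coincides with the distal 50% dose depth (R50) to within a
few tenths of a millimetre. In the simulator this coincidence is imposed
as a calibration: the survival-curve midpoint is offset (solved by
bisection, deterministically) so that the *expected measured profile* —
the bubble density times the saturating Boolean-coverage map
`1 - exp(-lambda(z))`, blurred by the imaging PSF — has its
midpoint-of-extremes distal crossing exactly at the dose R50. The peak
coverage `lambda` is predicted from concentration, slab thickness, hit
probability and the effective blob footprint (itself measured once per
imaging configuration from a deterministic rendering of isolated bubbles).
Without the coverage term the crossing of the *measured* profile sits
0.1–0.2 mm distal of the density crossing, because echo area saturates
where bubbles are dense and inflates the sparse fall-off region relatively.

## B-mode synthesis (`nanodose.imaging`)

Frames are 8-bit, 30 × 23 mm at 10 px/mm; rows are probe depth (probe on
top), columns lateral along the beam (beam enters at the left edge); the
probe is centered on the container's inner mid-length; three parallel
frames sample evenly spaced 1 mm elevational slabs across the 26 mm width.
Imaging at MI ≥ 0.4 is refused (acoustic droplet vaporization risk).

* Speckle: complex white Gaussian scatterer field smoothed by the PSF;
  the magnitude is exactly Rayleigh (unit backscatter power) with the
  PSF's spatial correlation. Gain is fixed so pure speckle averages grey
  30.
* PSF: anisotropic Gaussian, lateral sigma 0.12 mm, axial sigma 0.06 mm
  (the pulse is shorter than the lateral focus is wide at 7.5 MHz).
* Bubbles: point scatterers, amplitude proportional to radius (30 envelope
  units at 2 µm), deposited as impulses and convolved with the PSF.
* Saturation: the local bubble echo amplitude passes through
  `A_max tanh(A/A_max)` (ceiling 60) — dense clouds stop getting brighter.
* Shadowing: pixels are attenuated exponentially in the saturated bubble
  amplitude accumulated above them (coefficient 0.002 per amplitude·mm).
* Log compression: `grey = gain * log1p(envelope)`, clipped to 8 bits,
  with the gain derived from the target speckle mean; identical for pre
  and post frames by construction.

No frequency-dependent depth attenuation and no beamforming artefacts: the
phantom is small and gel-uniform, and the analysis aggregates over depth.

## Profile pipeline (`nanodose.profiles`)

The measurement chain mirrors a standard ImageJ workflow: isodata
(intermeans) threshold, zero sub-threshold pixels, per-column mean over the
full imaged depth, post-minus-pre subtraction clipped at zero, calibration
of columns to beam-axis millimetres (probe center ↔ container mid-length,
front wall thickness added), and averaging over frames and phantom
replicates (n = 6 in the reference protocol). Both frames of a pre/post
pair are thresholded at the *pre* frame's isodata level: the pre frame is
dose-independent, so its threshold is a stable estimate of the speckle
floor, whereas per-frame isodata is unstable on weakly bimodal low-dose
post frames. A config switch disables thresholding entirely.

Peaks are fitted with a Gaussian plus constant baseline
(`GaussianPeakModel`; nonlinear least squares; center initialized at the
argmax, width from the second central moment, baseline from the
proximal-quartile median). Derived descriptors: FWHM = 2.3548 sigma, W80 =
1.3358 sigma, analytic area `amplitude * sigma * sqrt(2 pi)`, `x_end` =
distal point where the fit decays to baseline + 10% amplitude (a package
definition — the quantity has no unique standard one), the proximal onset
(first sample above baseline + 3 background SD), and plateau-to-peak
ratios. The distal 50% fall is the most distal crossing of the
midpoint-of-extreme-grey-values level, linearly interpolated. Peak
*detection* uses a stricter gate than the onset rule (amplitude > 5 × a
robust noise level, the median of segment-wise scaled MADs): the maximum
of a few hundred noise columns exceeds 3 SD by chance alone, and the MAD
segments keep the estimate honest under both localized peaks and broad
SOBP plateaus.

## Dose response (`nanodose.dose_response`)

The integrated peak (analytic Gaussian area) versus dose is fitted with a
four-parameter logistic `floor + (ceiling - floor)/(1 + (ed50/D)^slope)`
(floor constrained ≥ 0) — the canonical saturating form — plus ordinary
least squares on the low-dose points (default ≤ 1 Gy). r² is plain
`1 - SS_res/SS_tot`. FWHM versus dose is summarized with a Spearman rank
trend and a saturating fit.

## Experiment runner (`nanodose.experiments`, `nanodose.cli`)

`run_experiment` reproduces the study matrix end to end (dose sweep,
concentration sweep, dose-rate halving, 10 mm phantom shift, SOBP, 50 mm
range change, and the two negative controls), with per-phantom and
per-frame random streams spawned from one master seed, geometry validation
(the Bragg peak must lie inside the phantom), and a summary that records
the seed, config hash and derived calibrations. The reference protocol is
2 phantoms × 3 frames (n = 6 profiles) per condition. A `click` CLI
(`nanodose simulate/reproduce/analyze/fixtures/report`) wraps the library
thinly.

Problem sizes used by the shipped analyses: 1 mm slabs give ≈ 5×10⁶
droplets per frame at the reference 4×10⁶ ND/ml; a full phantom pair
simulates in a few seconds, the 20-replicate range-verification study in
about two minutes.

## What the synthetic data do and do not show

The generator emulates: homogeneous dispersion, size-dependent spontaneous
vaporization, LET-gated one-hit radiation vaporization confined to the
Bragg peak, fully developed speckle, echo saturation and shadowing at high
bubble density, and the 3-frame scan protocol with fixed gain. It does not
emulate: RF-level wave propagation, shell viscoelasticity, droplet
diffusion or buoyancy, frequency-dependent attenuation, registration
errors between scans, or manual-positioning uncertainty (the in-vitro
study attributes ~0.4 mm of its shift error to the latter). Passing tests
therefore demonstrate that the *analysis chain* recovers the ranges, dose
trends and controls that the generator's physics encode under realistic
speckle and Poisson noise — not that the physical constants of any real
droplet batch are reproduced.

## Numerical choices and degenerate inputs

* Straggling-kernel and SOBP-weight solves: `brentq` / `nnls`, tolerances
  1e-4 mm and machine default.
* Peak fits: bounded Levenberg–Marquardt (trust-region) with xtol 1e-8 and
  a 500-iteration budget; non-convergence raises with diagnostics.
* Ties at the curve maximum break to the most distal sample with a
  warning; a monotone ramp (no interior peak) raises.
* Constant images make the threshold undefined: returned unchanged with a
  warning.
* Multiple distal mid-level crossings (noise) resolve to the most distal
  one, matching the fall-off semantics.
* All stochastic stages accept NumPy `SeedSequence`s; identical seeds give
  bit-identical frames, bubble fields and fixtures.

## Known limitations

* The LET surrogate has no physical meaning away from its two calibration
  anchors (the 60%-onset crossing and the peak value).
* The survival-midpoint calibration imposes the fall-off/R50 coincidence;
  the pipeline's residual error (noise plus uncorrected compression
  effects) is what the range-verification statistics measure.
* The 145 keV/µm threshold match is tolerance-based: it inherits the
  uncertainty of the thermophysical closures.
* At 4 Gy and at 8×10⁶ ND/ml the contrast is deliberately saturated;
  quantitative statements there are limited to orderings and plateaus.
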