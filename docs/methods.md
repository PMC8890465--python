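# Methods

## Radiometry

All corrections operate on total radiance through the Stefan–Boltzmann
approximation `W = σT⁴` rather than band-integrated spectral radiance.
This keeps every estimator an exact algebraic rearrangement of the
radiance chain and matches the convention under which thermal cameras
export *apparent temperature* with emissivity set to 1.0: that number is
defined so that `σ(T_app + 273.15)⁴` is the total detected radiance, so
temperature-domain files and radiance-domain algebra convert losslessly.
Temperatures are Kelvin internally; every interface takes and returns
degrees Celsius.

Atmospheric transmittance uses the two-term exponential mixture
`τ(d, ω) = K_atm·e^{−√d(α₁+β₁√ω)} + (1−K_atm)·e^{−√d(α₂+β₂√ω)}` with
`ω(RH, T) = RH·exp(h₁ + h₂T + h₃T² + h₄T³)`.  `K_atm = 1.9` and h₁…h₄ are
fixed model constants; α₁ = 0.006569, α₂ = 0.01262, β₁ = −0.002276,
β₂ = −0.00667 default to the published FLIR research values but are
config-overridable, since vendor tools carry them in firmware and
reported transmittance ranges cannot be pinned to one path length without
them.  Relative humidity is a fraction in [0, 1] everywhere; percent-style
values are rejected with a hint, never rescaled silently.  τ is computed
once per condition from that condition's environment state (air
temperature, humidity, path length), not per frame — the incubator holds
a steady state over a 20-minute capture.

## Correction equations

Four estimators are exposed (ids used throughout the package):

- **eq3** (conventional): `(W_det1 − W_amb)/(ε_obj τ) + W_amb`, with
  `W_amb` taken from the known incubator set temperature.  Corrects only
  external factors.
- **eq7** (full reference form): subtracts the reference-source estimate
  `(W_det2 − W_amb)/(ε_rs τ)` and re-anchors on the thermistor radiance
  `W_TMT-rs`.  Kept as `full_reference_correction` for the non-steady
  state; reduces exactly to eq8 when `W_amb = W_det2` (a property test
  asserts the reduction at machine precision).
- **eq8** (steady-state reference): `(W_det1 − W_det2)/(ε_obj τ) + W_TMT-rs`.
  Additive detector-chain terms (FPA drift, offset) are common to both
  trace areas and cancel in the difference.
- **eq9/eq10** (calibrated): `a·(W_det1 − W_det2)/(ε_obj τ) + W_TMT-rs + b`.
  One formula; the ids distinguish how (a, b) were fitted (all
  conditions vs the two-condition subset).

Default emissivities: object 0.97 (a blackbody calibration furnace
standing in for the neonate), reference 0.95 (a passive blackbody wrapped
in high-emissivity tape).

Calibration is unweighted OLS with intercept, fitted **in the radiance
domain on per-condition averages**: the response is `y = W_true − W_TMT-rs`
so the fitted line is exactly eq9 rearranged, and `W_true` comes from the
object's *set* temperature (the furnace's ±0.007 °C accuracy justifies
treating the set point as truth).  Fitting on per-condition averages
rather than pooled per-second points follows the protocol of averaging
within each condition before analysis; with noiseless inputs the two are
identical, with noise the averages weight conditions equally.  The
two-condition variant selects the conditions with the largest
object-minus-incubator temperature difference of either sign (incubator
30 °C / object 38 °C and incubator 39 °C / object 35 °C in the default
grid), ties broken by grid order.

A corrected radiance can be non-positive for deliberately inconsistent
inputs; the paired temperature is then NaN rather than an exception, so
vectorised sweeps and property tests over random inputs stay total.

## Aggregation protocol

Within each frame, each ROI is summarised by a two-sided trimmed mean
discarding `floor(n·f)` pixels per tail, `f = 0.10` by default — floor
keeps the rule deterministic and conservative for ROI sizes not divisible
by 10 (at n = 9 nothing is trimmed).  The per-frame series then feeds
per-second error computations; per-condition summaries are plain means.
MAE is the mean of per-second absolute deviations from the set
temperature.  Accuracy gate: per-condition MAE ≤ 0.3 °C (the skin-
thermometer bound); stability gate: SD of per-second absolute errors
< 0.1 °C (the fever-screening bound).  Because "within ±0.3 °C" can also
be read on the per-condition point estimate, both flags are computed;
the MAE-based flag is primary and drives the accuracy percentages.
Equations are compared by Pearson χ² on the 2×2 within/outside table
without Yates continuity correction — the worked study-scale tables
(e.g. 39/72 vs 3/72 → χ² = 43.6) reproduce only without it; with it the
same table gives ≈ 41.2.

## Simulator

`simulate_condition` is a forward model of an uncooled microbolometer
viewing the furnace and the passive reference inside the incubator:

1. Scene radiance per ROI from the radiance chain with
   `W_ref = W_atm = W_amb = σ(T_incu + 273.15)⁴`.  The reference's surface
   temperature equals the incubator air temperature (instant passive
   equilibration; the hardware protocol waits for stability before
   recording, so transient thermal mass is out of scope), which makes its
   scene radiance collapse to `W_amb` exactly.
2. Detector chain: `W_det = gain·W_tot + offset + drift(t) + noise`.
   Drift is an additive radiance sinusoid whose accumulated level is
   attenuated to a residual fraction at each NUC shutter event and then
   re-grows — the simplest shape reproducing the characteristic sawtooth
   fluctuation of intermittently-recalibrated microbolometers.  Gain is
   multiplicative on the *total* detected radiance; this is what makes a
   fitted recalibration slope differ from 1 and renders slope recovery
   analytic (`a = 1/gain`, because gain survives the ROI difference while
   offset and drift cancel).  Noise is Gaussian per pixel with SD equal to
   the NETD (in kelvin) times `dW/dT = 4σT³` at the ROI's scene
   temperature.  Background pixels view the far wall at air temperature
   through the same chain, without per-pixel noise (they feed no
   estimator).
3. Frames are stored as apparent temperature `(W_det/σ)^¼ − 273.15`
   (float64 in memory, float32 TIFF / 6-decimal CSV on disk).  The
   thermistor log reports `T_incu` plus Gaussian sensor noise.

### Study conditions (generator defaults)

- Grid: object set temperatures {35, 36, 37, 38} °C — the neonatal
  normothermic range — crossed with six incubator settings.  The study
  design states the ranges (30–39 °C, 50–90% RH) and the two extreme
  calibration conditions but not the individual settings; the default
  grid uses a low- and a high-humidity setting at each of three air
  temperatures, (30, 50%), (30, 90%), (34, 50%), (34, 80%), (39, 50%),
  (39, 80%), which contains both calibration extremes and spans the
  clinical envelope.  4 × 6 = 24 conditions.
- Acquisition: 1200 frames at 1 Hz (20 min), path length 0.4 m (a
  mid-incubator mounting; the true distance is unpublished).
- Sensor: 80 × 64 pixels with two 16 × 16 trace areas.  Real detectors are
  320 × 256 (A35) or 160 × 120 (Lepton); since all estimators consume only
  ROI-level trimmed means, sensor size affects nothing but runtime, and a
  256-pixel ROI already gives the spatial trim a realistic population.
- Camera errors: gain 1.08 (the per-unit magnitude implied by
  recalibration slopes of ~0.925 fitted to real A35-class cameras),
  offset 0.3 W m⁻², drift amplitude 2 W m⁻² / period 600 s / NUC every
  180 s with 30% residual — producing a conventional-equation fluctuation
  of roughly 0.6 °C peak-to-peak, the magnitude scale reported for real
  hardware — and NETD 0.05 °C from the detector datasheet.  The three
  preset cameras (`CAMERA_PRESETS`) use gains equal to the reciprocals of
  the three published per-camera slopes, so the acceptance run's fitted
  slopes land on those values by construction of the error model, not by
  table lookup.
- Thermistor noise 0.01 °C, the resolution class of a logging thermistor.

Randomness flows from one seed through `SeedSequence.spawn` per
condition (and per camera in the acceptance script), so any sub-grid is
bit-reproducible in isolation.

### What the simulator does not emulate

Optics (vignetting, point-spread), per-pixel fixed-pattern noise,
scene motion, reference-source thermal lag, and neonate-shaped targets
with unknown emissivity.  Passing tests therefore demonstrate the
*algebraic and statistical* correctness of the correction chain under
the stated error model — drift cancellation, gain recovery, accuracy
ordering — not clinical performance on real skin.

## Numerical choices

- Trim tail count `floor(n·f + 1e-12)`; the epsilon guards binary
  representation of `n·f` at exact multiples.
- τ is special-cased to exactly 1 at d = 0; values above 1 by ≤ 1e-4 are
  clamped, larger values are rejected as inconsistent constants.
- χ² degenerate tables (a zero column marginal, e.g. two equations both
  at 100%) are reported as `None` in summaries rather than 0/0.
- OLS via `scipy.stats.linregress`; R² is its squared correlation,
  clipped to 1 against rounding.
- Test problem sizes: property and acceptance tests run the same 24-
  condition grid on a 24 × 48 sensor with 8 × 8 ROIs and 20–120 frames —
  sizes chosen so the full suite stays interactive while every estimator
  still sees trimming, drift cycles spanning several NUC events, and
  pixel noise.  The acceptance script runs the full-scale study
  (3 cameras × 24 conditions × 1200 frames, 80 × 64 sensor).

## Known limitations

- The fitted intercept b is structurally ≈ 0 in simulation: a constant
  detector offset is common-mode across the two trace areas and cancels
  in the difference channel.  The small non-zero intercepts of real
  cameras presumably reflect scene- or temperature-dependent internal
  emission that this error model does not include.
- With every equation at 100% accuracy (clean limit), χ² comparisons are
  degenerate by construction; summaries carry `None` there.
- The reported per-condition SD is over per-second absolute errors; the
  SD over per-image means is also emitted (`sd_estimates`) since either
  reading of the stability gate is defensible.
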