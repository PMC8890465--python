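# nirtcal

Radiometric correction and in-scene blackbody calibration for infrared
thermography (IRT) operated **inside a convective neonatal incubator**.

Premature infants need continuous, contact-free temperature monitoring:
their under-keratinised skin makes thermistor probes unreliable, but an
uncooled thermal camera mounted inside the incubator is not accurate
enough out of the box.  Beyond the usual *external* error factors
(emissivity, reflected ambient radiation, atmospheric transmittance),
uncooled microbolometers suffer *internal* errors — thermal drift of the
focal plane array, only intermittently reset by the mechanical-shutter
non-uniformity correction (NUC), and per-unit gain differences.  This
package implements, end to end, a correction chain that defeats both
error classes using a **passive blackbody reference source** placed in the
camera's field of view and read by a thermistor, plus a **per-camera
linear recalibration**, and evaluates the result against clinical
accuracy gates.  A forward simulator of the camera/incubator scene makes
the whole protocol reproducible without hardware.

## The model

All algebra is carried out in radiance via the Stefan–Boltzmann law,
`W = σT⁴`, `T = (W/σ)^¼` (σ = 5.670367·10⁻⁸ W m⁻² K⁻⁴).  A camera viewing
an opaque object receives

```
W_tot = ε_obj · τ_atm · W_obj + (1 − ε_obj) · τ_atm · W_ref + (1 − τ_atm) · W_atm
```

with transmittance `τ(d, ω)` from the two-term exponential FLIR model and
water-vapour content `ω(RH, T_atm)`.  Inside the incubator the air is
uniform, so `W_ref = W_atm = W_amb` and the four estimators are:

| id  | estimator | corrects |
|-----|-----------|----------|
| eq3 | `W_obj = (W_det1 − W_amb)/(ε_obj τ) + W_amb` | external errors only |
| eq8 | `W_COR1 = (W_det1 − W_det2)/(ε_obj τ) + W_TMT-rs` | + drift/offset (cancel in the in-scene difference) |
| eq9 | `W_COR2 = a·(W_det1 − W_det2)/(ε_obj τ) + W_TMT-rs + b` | + per-camera gain, (a, b) fitted over all conditions |
| eq10 | same form, (a′, b′) fitted from just the two extreme conditions | same, minimal calibration effort |

`W_det1`/`W_det2` are the detected radiances of the object and reference
trace areas (per-frame 10% two-sided trimmed means of apparent
temperature, converted through σT⁴), and `W_TMT-rs` is the radiance at
the reference's thermistor temperature.  Calibration is ordinary least
squares of `y = W_true − W_TMT-rs` on the difference-channel predictor,
one point per condition.  A condition passes the accuracy gate when its
mean absolute error (MAE) against the object's set temperature is within
0.3 °C, and the stability gate when the SD of the per-second absolute
errors is below 0.1 °C; equations are compared by a Pearson χ² test on
the 2×2 within/outside table (df = 1, no continuity correction).

## Worked example

```python
from nirtcal import SimulationConfig, simulate_grid, evaluate_pipeline, fit_grid_calibration

# 24 conditions (object 35-38 °C x incubator 30-39 °C / 50-90% RH),
# 1200 frames at 1 Hz, default uncooled-camera error model
grid = simulate_grid(SimulationConfig(), base_seed=1)
cal24 = fit_grid_calibration(grid, camera_id="demo")
cal2 = fit_grid_calibration(grid, camera_id="demo", two_point=True)
print(f"a={cal24.a:.6f} b={cal24.b:.6f} R2={cal24.r_squared:.6f}")
results, summary = evaluate_pipeline(grid, {"eq9": cal24, "eq10": cal2})
for eq, s in summary["equations"].items():
    print(eq, s["accuracy_pct"], "% within 0.3 °C")
```

prints

```
a=0.925944 b=0.000132 R2=1.000000
eq3 0.0 % within 0.3 °C
eq8 50.0 % within 0.3 °C
eq9 100.0 % within 0.3 °C
eq10 100.0 % within 0.3 °C
```

— the conventional equation is ruined by the simulated 8% gain error, the
in-scene reference rescues the conditions where object and air are close,
and the regression-calibrated equations (whose fitted slope `a ≈ 1/gain`
undoes the gain error) pass everywhere.

The same workflow is available from the shell:

```sh
nirtcal simulate --config grid.yaml --out runs/
nirtcal fit --sim-dir runs/ --out cal.json
nirtcal fit --sim-dir runs/ --out cal2.json --two-point
nirtcal evaluate --sim-dir runs/ --calibration cal.json --calibration2 cal2.json --out summary
nirtcal compare --a summary.json --b summary.json --eq-a eq8 --eq-b eq3
```

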