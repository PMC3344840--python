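# teedecomp

Decomposition of indirect-calorimetry **total energy expenditure (TEE)**
into a time-dependent **resting metabolic rate (RMR)** and
**activity-related energy expenditure (AEE)**, by penalised spline
regression.

## The problem

Metabolic chambers record a TEE trace (kcal/day, from O2 consumption and
CO2 production) and a physical-activity trace (infrared beam-break
counts) from a freely moving animal. How much of the expended energy is
due to activity? The classical answers — regress TEE on activity, or
average TEE over inactive periods — assume the resting component is
constant, which it is not: RMR carries a circadian rhythm, the thermic
effect of food, and thermoregulatory drift. Treating it as constant
biases both the RMR and the caloric cost of activity.

`teedecomp` is for researchers analysing rodent (or other small-animal)
indirect-calorimetry experiments with conventional equipment — CLAMS-style
chambers, beam-break activity monitors, respiratory exchange sampled
anywhere from seconds to tens of minutes.

## The model

With `y` the TEE samples at times `t_i` and `x` the activity counts at
times `t_j` (possibly a finer grid),

    y_i = Σ_k β_k B_k(t_i)  +  α · w_i  +  e_i

* `Σ β_k B_k(t)` — the RMR, a cubic B-spline on equidistant knots
  (default 15/day), fitted with a roughness penalty
  `λ ∫ r′(t)² dt`; `λ` is chosen by generalised cross-validation.
* `α` — the caloric cost of activity (CCA).
* `w` — the activity trace mapped to an intensity linearly related to
  AEE (optional power/saturating preprocessing, selected by residual
  sum of squares) and convolved with the chamber's gas-washout impulse
  response
  `h(t) = (e^{−(t−τ_d)/τ_c} − e^{−(t−τ_d)/τ_s}) / (τ_c − τ_s)`,
  which models the subject and chamber as two linear compartments plus
  a transport delay. Convolution happens on the fine activity grid, so
  high-rate activity data sharpen the fit even when gas exchange is
  sampled slowly.
* Because beam-break counts measure activity with error, the activity
  regressor is treated under a multiplicative errors-in-variables model
  and the normal equations corrected for regression dilution
  (`w'w → w'w / (1 + σ_u²)`), with `σ_u²` estimated from the residual
  heteroskedasticity and bounded by the counting noise the beam sensor
  can actually produce.

Comparison estimators (linear regression, zero-activity TEE averaging,
a causal Kalman filter with random-walk RMR), a metabolic-chamber
simulator with known ground truth, and a validation harness (band-limited
RMSE, bias–variance decomposition, downsampling-induced variability,
cosinor fits) are included.

## Worked example

Simulate a three-day mouse recording (10 s sampling) and decompose it:

```bash
teedecomp simulate --seed 7 --out mouse_a
teedecomp decompose --data mouse_a --out fit_a
```

prints the fit summary

```json
{
  "alpha": 3.2264743526620645,
  "sigma_u2": 0.001386443860583414,
  "lambda": 2.758847314696536e-09,
  "edf": 49.002699624388725,
  "daily_tee": 11.038177244537419,
  "daily_rmr": 9.943458777593394,
  "daily_aee": 1.094718466944028
}
```

Of the 11.04 kcal/day this animal expends, 9.94 kcal/day is resting
metabolism and 1.09 kcal/day is activity-related; each unit of measured
activity rate costs `α = 3.23` kcal/day while it lasts, and the
estimated multiplicative measurement-error variance of the activity
channel is small (`σ_u² ≈ 0.0014`), so the dilution correction is mild.
The simulator's ground truth for this seed is a mean RMR of 10 kcal/day
— the estimate is off by 0.6 %. `fit_a/traces.csv` holds the fitted
`RMR(t)` and `AEE(t)`:

```
time_s,rmr_kcal_day,aee_kcal_day
0.0,9.866122789988415,0.0
10.0,9.864594496657821,8.386092047189033e-16
...
```

The same pipeline is available as a library:

```python
from teedecomp import SimConfig, simulate_dataset, decompose

sim = simulate_dataset(SimConfig(), seed=7)
fit = decompose(sim.observed)
fit.summary()                      # same dict as above
fit.rmr_t, fit.aee_t               # fitted traces on the TEE grid
```

`teedecomp compare --data mouse_a` runs all four estimators on one
dataset; `teedecomp evaluate` drives a full simulation study from a
YAML config.

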