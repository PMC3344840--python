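# Methods

This note documents the models implemented in `teedecomp`, the choices
made where the design was genuinely open, and what the simulation-based
tests do and do not establish. No number in this note is asserted that
the test suite or `scripts/acceptance.py` does not itself compute.

## The decomposition model

Indirect calorimetry yields a total energy expenditure (TEE) trace
`y(t_i)` (kcal/day, from O2/CO2 exchange) and an activity trace `x(t_j)`
(infrared beam-break counts), usually on different time grids. The
package decomposes

    y_i = r(t_i) + alpha * w_i + e_i

where

* `r(t) = sum_j beta_j B_j(t)` is the resting metabolic rate (RMR),
  a smooth function built from cubic B-splines on equidistant knots
  (`knots_per_day`, default 15);
* `alpha` is the caloric cost of activity (CCA, kcal/day per activity
  unit), so `alpha * w` is the activity-related energy expenditure
  (AEE);
* `w` is the activity trace after (i) optional preprocessing to an
  intensity linearly related to AEE and (ii) convolution with the
  chamber's gas-washout impulse response, sampled at the TEE times.

Coefficients minimise the penalised least-squares criterion
`||y - alpha w - Z beta||^2 + lambda * integral r'(t)^2 dt`. The
first-derivative penalty leaves constants unpenalised; `lambda` is
selected by generalised cross-validation, `GCV(lambda) = n RSS /
(n - tr S)^2`, on a log grid refined by golden-section search.

### Gas-diffusion model

The sensor path is two linear compartments in series — the subject
(washout time `tau_s`, gas pools in blood/tissue) and the chamber
(`tau_c` = volume / flow rate) — plus a transport delay `tau_d`:

    h(t) = (exp(-(t - tau_d)/tau_c) - exp(-(t - tau_d)/tau_s)) / (tau_c - tau_s)

for `t >= tau_d` (confluent form when `tau_s = tau_c`). `h` integrates
to one: steady-state energy is conserved. Defaults `tau_s = 1 min`,
`tau_c = 5 min`, `tau_d = 0.5 min` describe a mouse-sized chamber at
~0.4 l/min flow; all are user-settable. The discrete kernel uses
midpoint sampling renormalised to exact unit discrete gain, which makes
the unit-gain invariant exact rather than approximate. When activity is
recorded faster than TEE, the convolution is evaluated on the fine PA
grid and only then sampled at the TEE times; this preserves sub-sample
bout timing and is the recommended acquisition mode.

The first `5 (tau_s + tau_c)` of the record (default 30 min) are flagged
burn-in: the convolution has no knowledge of pre-recording activity, so
this prefix is excluded from fitting and from every accuracy metric.

### Errors-in-variables correction

Beam-break counts measure true activity intensity with error that grows
with the activity level; we model it as multiplicative,
`w_obs = w_true (1 + u)`, `E u = 0`, `Var u = sigma_u^2`, i.i.d. across
samples. Ordinary least squares then suffers regression dilution
(`alpha` biased towards zero). The corrected-score estimator divides the
activity Gram term `w'w` by `(1 + sigma_u^2)` — cross terms with the
spline columns are unbiased — which restores unbiased normal equations.
`sigma_u^2` is estimated from the residuals of a preliminary
uncorrected fit by Gaussian maximum likelihood under
`Var(e_i) = sigma_e^2 + alpha^2 w_i^2 sigma_u^2`, optimised on the log
scale with an explicit check of the homoskedastic boundary.

**Guarding the correction.** The residual-ML estimate conflates two
sources of activity-scaled residual variance: genuine regressor noise
(which attenuates `alpha` and should be corrected) and activity-scaled
*model misfit* — per-bout variation in the cost of activity and timing
information lost at coarse PA sampling — which lives in the response and
does not attenuate anything. Correcting for the latter inflates `alpha`
and can push the average-RMR estimate off by several percent at coarse
sample times. `decompose` therefore caps the applied `sigma_u^2` at the
variance the counting process can actually have produced: treating
counts as Poisson, the counting-noise variance of `w_i` is one extra
convolution of the counts with the squared kernel, and the equivalent
multiplicative variance is `sum Var(w_i) / sum w_i^2`
(`counting_sigma_u2`). After diffusion filtering this bound is small at
high sample rates and essentially zero at coarse rates, which matches
the observation that convolution has already averaged the counting
noise away. The unguarded behaviour is available via
`DecompositionConfig(guard_counting=False)` or by fixing
`sigma_u2` explicitly; the correction itself is exercised (and shown to
remove the dilution bias) in tests with genuine multiplicative
regressor noise.

### Pipeline order

`decompose` runs: preprocessing → fine-grid convolution → preliminary
fit with GCV `lambda` → `sigma_u^2` estimation (guarded) → final
corrected fit with re-selected `lambda`. The spline basis is built on
the post-burn-in span (basis functions supported only in the excluded
prefix would be unidentifiable) and evaluated back onto the full grid
for plotting, clamped beyond the knot range.

## Activity preprocessing

Beam-break counts can relate nonlinearly to activity-related energy
(non-displacement behaviours break few beams per kcal). Two monotone,
zero-preserving one-parameter families are provided: a power law
`x^gamma` (grid 0.3–1.5, step 0.1) and a saturating form
`x / (x + x_half)`. Selection minimises the residual sum of squares of
the (preliminary, uncorrected) decomposition re-run per candidate; a
profile flat to within 0.5 % falls back to the identity. The functional
families are this package's choice; the selection-by-RSS criterion is
the principled part.

## Baseline estimators

* **Linear regression**: OLS of TEE on `[1, w]`; the intercept is a
  constant RMR. Fails to follow any time variation by construction.
* **Zero-activity averaging**: mean TEE over samples preceded by
  `lag_window` (default 15 min ≈ 3 `tau_c`) of complete inactivity.
  The lag removes washout contamination of quiet samples; note that
  with the lag in place, quiet periods over-represent the light phase
  (low RMR), so on realistic recordings the estimate is biased *low* —
  bias-dominated either way, which is the relevant property.
* **Kalman filter**: causal tracker with state `[RMR_t, alpha_t]`,
  random-walk dynamics `(q_rmr, q_alpha)` (default `q_alpha = 0`:
  constant cost of activity) and observation
  `y_t = RMR_t + alpha_t w_t + v_t`. TEE and activity must share one
  grid. Process variances are per step, so a tuned spec belongs to one
  sample interval. On simulated data `tune_kalman` grid-searches
  `(q_rmr, q_alpha, r_obs)` against the known truth, scoring the
  filter's *raw causal output* by plain RMSE; the zero-phase Butterworth
  low-pass at the evaluation cutoff is applied afterwards for reporting.
  Tuning through the post-filter instead would co-opt it into a
  non-causal smoother and erase the causal/non-causal distinction the
  comparison is about.

## The simulator

`simulate_dataset` emulates a three-day mouse chamber recording at 10 s
resolution (defaults; all parameters in `SimConfig`):

* **RMR**: 10 kcal/day mean + 24 h cosine (peak-to-peak 1.0 kcal/day,
  acrophase mid-dark) + low-pass filtered white noise (SD 0.45
  kcal/day, cutoff 6 cycles/day) for ultradian drift. The noise gain of
  the Butterworth filter is computed from its impulse response so the
  ensemble SD is exact.
* **Activity**: alternating renewal process; exponential inter-bout
  gaps with mean 10 min (dark) / 30 min (light), log-normal durations
  (mean 2.5 min, CV 0.8) and intensities (mean 4, CV 0.5) rastered on a
  1 s lattice.
* **Energetics**: each bout draws its own cost of activity (log-normal,
  mean 2.0 kcal/day per intensity unit, CV 0.2), so AEE is only
  on-average proportional to intensity — the realistic source of
  "multiplicative" activity error.
* **Sensors**: beam breaks are Poisson with rate 0.6 /s per intensity
  unit on the 1 s lattice, binned per sample interval (≈24 breaks per
  active 10 s bin); observed TEE is the washout-filtered instantaneous
  RMR+AEE plus N(0, 0.5²) kcal/day noise. The filter is warm-started
  with the initial RMR so the record does not ramp up from zero.

These values were fixed once so that simulated traces have the
qualitative structure of real mouse recordings (≈87 % of PA bins empty,
daily TEE ≈ 11 kcal/day, AEE ≈ 1 kcal/day, circadian TEE swing ≈ 1
kcal/day) and the decomposition's error levels sit near the reference
behaviour of real chamber systems. Lower sample rates are emulated by
decimating TEE (instantaneous readings) and block-summing PA (counts
accumulate), with a phase offset for the downsampling-variability
analysis.

What the simulator does **not** emulate: feeding-triggered thermic
transients, behaviour-class-dependent beam sensitivity (the nonlinearity
the preprocessing module addresses appears only if injected), O2/CO2
channels as separate sensors, drift in the reference air, and missing
data. Passing tests therefore demonstrate correct estimator behaviour
under the stated stochastic model, not performance on any particular
instrument.

## Evaluation conventions

* Errors are relative to the true ensemble-mean RMR (10 kcal/day).
* **Average-RMR error**: per-dataset difference of time-averaged
  estimate and truth (the DC term); ensembles report its RMSE, and its
  bias/variance decomposition uses population conventions so
  `MSE = bias² + variance` is an identity.
* **Time-dependent error**: the error trace's DFT is hard-zeroed above
  `f_c` and the RMS of the inverse transform reported. Default
  `f_c = 7.5` cycles/day — half the default knot rate, since components
  faster than `knots_per_day / 2` are not representable by the basis
  and would reduce every method to noise comparison. `f_c = 0` recovers
  the average-RMR error.
* **DIV** (downsampling-induced variability): the N phase-offset
  decimations of a high-rate TEE trace are each decomposed (PA stays at
  the base rate); DIV is the across-phase SD of the average-RMR
  estimates, and, for the time-dependent variant, the time-averaged
  across-phase SD of the RMR traces linearly interpolated onto the
  offset-0 coarse grid (burn-in and the outermost samples dropped).
* **Cosinor fit**: OLS of a 24 h cosine plus linear and quadratic trend
  terms; peak-to-peak amplitude `2 sqrt(A² + B²)`.

`run_validation_study` ties these together: one simulated ensemble,
every method at every TEE sample time (matched-PA and optionally
fine-PA regimes), Kalman tuning per rate on a training subset, tidy
DataFrame out. It is deterministic given its seed.

## Problem sizes

The shipped test suite runs ensembles of 3–12 datasets per check;
`scripts/acceptance.py` uses 100 datasets for accuracy and ranking
quantities, 20 datasets × 120 phases for DIV, and 8 training datasets
for Kalman tuning. These sizes put the Monte-Carlo error of ensemble
RMSEs in the few-percent range, commensurate with the ±30 % bands used
for stochastic checks.

## Numerical choices and edge cases

* Penalty matrix assembled exactly (3-point Gauss–Legendre per knot
  interval; the integrand is quartic). Basis time unit is days so
  penalty entries are O(1).
* Degree padding of the knot vector spawns B-splines with no support in
  the data span; their (identically zero) columns are dropped.
* GCV plateaus break towards the smallest `lambda` within 0.1 % of the
  minimum; a boundary minimum returns the boundary with a warning. With
  15 knots/day the basis itself caps flexibility and near-OLS smoothing
  is frequently optimal — the warning is informational.
* All-zero activity: `alpha` is pinned to 0 (with a warning) and the
  fit degrades gracefully to a penalised smooth of TEE.
* The `sigma_u^2` likelihood is optimised from two starts with a
  boundary check; `alpha <= 0` short-circuits to no correction.
* Kalman divergence (non-positive innovation variance) raises with the
  failing step; the filter uses a diffuse prior `P0 = 100 I`.
* CSV round trips write `%.17g` and read with
  `float_precision="round_trip"`, so datasets survive text storage
  bit-exactly. Single missing chamber rows are NaN-masked; longer
  irregularities are an error.

## Known limitations

* The counting bound on `sigma_u^2` assumes Poisson-like counts; for
  instruments reporting pre-smoothed activity the bound may be loose in
  either direction (override with `DecompositionConfig.sigma_u2`).
* The Kalman baseline is one member of a family; other state vectors or
  smoothing variants (RTS) would behave differently. Its tuned accuracy
  at coarse rates depends on details that published descriptions leave
  open; our implementation's average-RMR error at 20-min sampling sits
  near the P-spline's rather than below it.
* Confidence bands for `r(t)` are not provided (the smoother matrix
  would support them).
* `tau` values are rarely known; `DiffusionParams` defaults are
  mouse-chamber-typical, and a residual-minimising grid search is the
  recommended calibration when high-rate data are available.
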