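"""Accuracy metrics and the simulation-study harness.

The validation study quantifies how well each estimator recovers the
known RMR of simulated chamber recordings, as a function of the TEE/PA
sample intervals, the chamber washout time and the downsampling factor.

Two error scales are used throughout, both relative to the true mean RMR
(10 kcal/day by default):

* **average RMR** -- the error in the per-dataset time average (the
  ``f_c = 0`` limit of the band-limited error);
* **time-dependent RMR** -- the RMSE of the estimated trace after hard
  removal of DFT components above a cutoff ``f_c`` (default
  ``knots_per_day / 2`` cycles/day), because components faster than half
  the knot rate are not estimable by construction and would swamp the
  comparison with noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.fft import irfft, rfft, rfftfreq

from .baselines import (
    KalmanSpec,
    fit_kalman,
    fit_linear_regression,
    fit_zero_activity_average,
    tune_kalman,
)
from .diffusion import convolve_activity
from .simulate import SimConfig, SimDataset, downsample_dataset, simulate_dataset
from .splinefit import DecompositionConfig, decompose

__all__ = [
    "band_limited_error",
    "bias_variance",
    "BiasVariance",
    "div",
    "DivResult",
    "fit_circadian",
    "CircadianFit",
    "EvalReport",
    "run_validation_study",
    "DEFAULT_CUTOFF",
]

_SEC_PER_DAY = 86400.0

#: default evaluation cutoff, cycles/day: half the default knot rate
DEFAULT_CUTOFF = 7.5


def band_limited_error(
    est: np.ndarray, truth: np.ndarray, dt: float, f_c: float = DEFAULT_CUTOFF
) -> float:
    """RMSE of ``est - truth`` restricted to frequencies ``|f| <= f_c``.

    ``dt`` is the sample interval in seconds and ``f_c`` the cutoff in
    cycles/day.  The DFT of the error is computed, bins above the cutoff
    hard-zeroed, and the RMS of the inverse transform returned.  With
    ``f_c <= 0`` the absolute mean error (the DC component alone) is
    returned, i.e. the average-RMR error.
    """
    est = np.asarray(est, float)
    truth = np.asarray(truth, float)
    if est.shape != truth.shape:
        raise ValueError("est and truth must be on a common grid")
    err = est - truth
    if f_c <= 0:
        return float(abs(np.mean(err)))
    freqs = rfftfreq(err.size, d=dt / _SEC_PER_DAY)   # cycles/day
    spec = rfft(err)
    spec[freqs > f_c] = 0.0
    filt = irfft(spec, n=err.size)
    return float(np.sqrt(np.mean(filt**2)))


@dataclass
class BiasVariance:
    bias: float
    variance: float

    @property
    def mse(self) -> float:
        return self.bias**2 + self.variance


def bias_variance(avg_estimates, truth_avgs) -> BiasVariance:
    """Decompose the error in per-dataset averages into bias and variance.

    Population conventions, so ``mse == bias**2 + variance`` holds as an
    identity: ``bias = mean(est - truth)``, ``variance = var(est - truth)``.
    """
    est = np.asarray(avg_estimates, float)
    tru = np.asarray(truth_avgs, float)
    if est.size != tru.size or est.size < 2:
        raise ValueError("need >= 2 paired averages")
    err = est - tru
    return BiasVariance(bias=float(np.mean(err)), variance=float(np.var(err)))


@dataclass
class DivResult:
    """Downsampling-induced variability, percent of the reference RMR."""

    avg_div_pct: float
    timedep_div_pct: float
    n_phases: int
    N: int


def div(
    sim: SimDataset,
    N: int,
    config: DecompositionConfig | None = None,
    ref_rmr: float | None = None,
    n_phases: int | None = None,
) -> DivResult:
    """Spread among estimates from the N phase-offset decimations of TEE.

    The high-rate TEE trace is decimated by factor ``N`` at each possible
    phase (activity stays at the base rate -- the high-rate-PA pathway),
    each phase is decomposed, and the across-phase standard deviation of
    (a) the average-RMR estimates and (b) the RMR traces interpolated to
    a common grid (time-averaged) is reported as percent of the true mean
    RMR.  ``n_phases`` limits the work to evenly spaced offsets.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    cfg = config or DecompositionConfig()
    if ref_rmr is None:
        ref_rmr = sim.truth.config.mean_rmr
    if N == 1:
        return DivResult(0.0, 0.0, 1, 1)
    offsets = np.arange(N) if n_phases is None or n_phases >= N else \
        np.unique(np.linspace(0, N - 1, n_phases).astype(int))
    # common comparison grid: the offset-0 coarse grid, clipped so every
    # phase covers it, burn-in removed
    burn = cfg.burn_in_seconds
    if burn is None:
        burn = cfg.diffusion.burn_in_seconds
    base_t = sim.observed.t_y
    t_common = base_t[:: N][1:-1]
    t_common = t_common[t_common >= base_t[0] + burn]
    avg_est, traces = [], []
    failures = 0
    for off in offsets:
        ds, t_kept, _ = downsample_dataset(sim, N, None, int(off))
        try:
            fit = decompose(ds, cfg)
        except Exception as err:          # noqa: BLE001 - per-phase robustness
            failures += 1
            warnings.warn(f"phase {off} failed: {err}", stacklevel=2)
            continue
        avg_est.append(fit.daily_rmr)
        traces.append(np.interp(t_common, t_kept, fit.rmr_t))
    if len(avg_est) < 3:
        raise RuntimeError(f"too few successful phases ({len(avg_est)})")
    avg_est = np.asarray(avg_est)
    traces = np.vstack(traces)
    avg_div = float(np.std(avg_est))
    timedep_div = float(np.mean(np.std(traces, axis=0)))
    return DivResult(
        avg_div_pct=100.0 * avg_div / ref_rmr,
        timedep_div_pct=100.0 * timedep_div / ref_rmr,
        n_phases=len(avg_est),
        N=N,
    )


@dataclass
class CircadianFit:
    peak_to_peak: float
    acrophase_h: float
    coefficients: np.ndarray


def fit_circadian(t: np.ndarray, rmr_t: np.ndarray) -> CircadianFit:
    """Cosinor fit: 24 h cosine after removing linear and quadratic trends.

    OLS of ``a + b t + c t^2 + A cos(2 pi t / 24h) + B sin(2 pi t / 24h)``;
    returns the peak-to-peak amplitude ``2 sqrt(A^2 + B^2)`` and the
    acrophase (hours after t=0 at which the cosine peaks).
    """
    t = np.asarray(t, float)
    rmr_t = np.asarray(rmr_t, float)
    if t[-1] - t[0] < _SEC_PER_DAY:
        raise ValueError("circadian fit needs a trace spanning >= 24 h")
    td = (t - t[0]) / _SEC_PER_DAY
    omega = 2.0 * np.pi
    X = np.column_stack(
        [np.ones_like(td), td, td**2, np.cos(omega * td), np.sin(omega * td)]
    )
    coef, *_ = np.linalg.lstsq(X, rmr_t, rcond=None)
    A, B = coef[3], coef[4]
    return CircadianFit(
        peak_to_peak=float(2.0 * np.hypot(A, B)),
        acrophase_h=float((np.arctan2(B, A) % (2 * np.pi)) * 24.0 / (2 * np.pi)),
        coefficients=coef,
    )


@dataclass
class EvalReport:
    """Tidy per-method, per-rate results of a validation run."""

    table: pd.DataFrame
    f_c: float
    n_datasets: int
    failures: int = 0
    kalman_specs: dict = field(default_factory=dict)

    def get(self, method: str, T_tee_s: float, metric: str,
            pa_regime: str = "matched") -> float:
        q = self.table[
            (self.table.method == method)
            & (self.table.T_tee_s == T_tee_s)
            & (self.table.pa_regime == pa_regime)
            & (self.table.metric == metric)
        ]
        if q.empty:
            raise KeyError((method, T_tee_s, pa_regime, metric))
        return float(q.value.iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _prepare_matched(sim: SimDataset, N: int):
    if N == 1:
        ds = sim.observed
        return ds, ds.t_y, sim.truth.rmr
    ds, t_kept, truth = downsample_dataset(sim, N, N, 0)
    return ds, t_kept, truth


def _prepare_fine_pa(sim: SimDataset, N: int):
    if N == 1:
        ds = sim.observed
        return ds, ds.t_y, sim.truth.rmr
    ds, t_kept, truth = downsample_dataset(sim, N, None, 0)
    return ds, t_kept, truth


def _kalman_inputs(ds, dec_cfg: DecompositionConfig):
    """Common-grid (y, w) pair for the Kalman filter."""
    w = convolve_activity(ds.x / ds.dt_pa, ds.t_x, dec_cfg.diffusion, ds.t_y)
    return ds.y, w


def run_validation_study(
    n_datasets: int = 20,
    sample_times_s: tuple = (10.0, 600.0, 1200.0),
    methods: tuple = ("pspline", "linreg", "zeroact", "kalman"),
    seed: int = 0,
    sim_config: SimConfig | None = None,
    dec_config: DecompositionConfig | None = None,
    f_c: float = DEFAULT_CUTOFF,
    pa_regimes: tuple = ("matched",),
    n_tune: int = 8,
) -> EvalReport:
    """Simulate an ensemble and score every method at every sample rate.

    For each dataset and TEE sample interval the estimators are run in
    the ``matched`` regime (PA block-summed to the TEE rate) and
    optionally the ``fine`` regime (PA kept at the base rate; P-spline
    only -- the Kalman filter requires a common grid and the constant
    methods are rate-insensitive).  Kalman process noises are tuned per
    sample interval on the first ``n_tune`` datasets against the truth.
    Aggregates per cell: relative RMSE of the average RMR, relative
    band-limited RMSE of the time-dependent RMR, and the bias/variance
    decomposition of the average-RMR error.  Deterministic given ``seed``.
    """
    sim_cfg = sim_config or SimConfig()
    dec_cfg = dec_config or DecompositionConfig()
    base_dt = sim_cfg.dt
    ref = sim_cfg.mean_rmr
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_datasets)
    sims = [simulate_dataset(sim_cfg, int(s)) for s in seeds]

    factors = []
    for T in sample_times_s:
        N = int(round(T / base_dt))
        if N < 1 or abs(N * base_dt - T) > 1e-9:
            raise ValueError(f"sample time {T}s is not a multiple of dt={base_dt}s")
        factors.append(N)

    burn = dec_cfg.burn_in_seconds
    if burn is None:
        burn = dec_cfg.diffusion.burn_in_seconds

    kalman_specs: dict = {}
    if "kalman" in methods:
        for T, N in zip(sample_times_s, factors):
            training = []
            for sim in sims[: min(n_tune, n_datasets)]:
                ds, t_kept, truth = _prepare_matched(sim, N)
                y, w = _kalman_inputs(ds, dec_cfg)
                training.append((y, w, truth))
            spec, _ = tune_kalman(
                training, dt=T, base_spec=KalmanSpec(lowpass_cutoff=f_c))
            kalman_specs[T] = spec

    rows = []
    failures = 0
    records: dict = {}
    for T, N in zip(sample_times_s, factors):
        for regime in pa_regimes:
            prep = _prepare_matched if regime == "matched" else _prepare_fine_pa
            for method in methods:
                if regime == "fine" and method != "pspline":
                    continue
                key = (method, T, regime)
                records[key] = {"avg_est": [], "avg_tru": [], "td": []}
                for sim in sims:
                    ds, t_kept, truth = prep(sim, N)
                    keep = t_kept >= t_kept[0] + burn
                    try:
                        if method == "pspline":
                            fit = decompose(ds, dec_cfg)
                            trace = fit.rmr_t
                        elif method == "linreg":
                            y, w = _kalman_inputs(ds, dec_cfg)
                            cf = fit_linear_regression(y[keep], w[keep])
                            trace = cf.rmr_trace(t_kept.size)
                        elif method == "zeroact":
                            cf = fit_zero_activity_average(
                                ds.y, ds.t_y, ds.x, ds.t_x)
                            trace = cf.rmr_trace(t_kept.size)
                        elif method == "kalman":
                            y, w = _kalman_inputs(ds, dec_cfg)
                            kf = fit_kalman(y, w, kalman_specs[T], dt=T)
                            trace = kf.rmr_t
                        else:
                            raise ValueError(f"unknown method {method!r}")
                    except Exception as err:      # noqa: BLE001
                        failures += 1
                        warnings.warn(
                            f"{method} failed at T={T}s: {err}", stacklevel=2)
                        continue
                    rec = records[key]
                    rec["avg_est"].append(float(np.mean(trace[keep])))
                    rec["avg_tru"].append(float(np.mean(truth[keep])))
                    rec["td"].append(
                        band_limited_error(trace[keep], truth[keep], T, f_c))

    for (method, T, regime), rec in records.items():
        if not rec["avg_est"]:
            continue
        est = np.asarray(rec["avg_est"])
        tru = np.asarray(rec["avg_tru"])
        bv = bias_variance(est, tru) if est.size >= 2 else BiasVariance(
            float(est[0] - tru[0]), 0.0)
        avg_rmse = float(np.sqrt(np.mean((est - tru) ** 2)))
        td_rmse = float(np.mean(rec["td"]))
        for metric, value in (
            ("avg_rmse_pct", 100.0 * avg_rmse / ref),
            ("timedep_rmse_pct", 100.0 * td_rmse / ref),
            ("bias", bv.bias),
            ("variance", bv.variance),
        ):
            rows.append(
                {"method": method, "T_tee_s": T, "pa_regime": regime,
                 "metric": metric, "value": value}
            )
    table = pd.DataFrame(rows)
    return EvalReport(table=table, f_c=f_c, n_datasets=n_datasets,
                      failures=failures, kalman_specs=kalman_specs)
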