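"""Conventional estimators of RMR and AEE, for comparison.

Three approaches that predate the penalised-spline decomposition:

* **linear regression** -- OLS of TEE on activity plus an intercept; the
  intercept is a *constant* RMR estimate.
* **zero-activity averaging** -- mean TEE over samples preceded by a
  window of complete inactivity (so that chamber washout of earlier
  activity has decayed); also constant in time.
* **Kalman filtering** -- a causal state-space tracker with random-walk
  states for RMR (and optionally a slowly drifting caloric cost of
  activity), observation ``y_t = RMR_t + alpha_t * w_t + v_t``.  The
  process-noise variances must be supplied a priori; on simulated data
  they can be tuned by grid search against the known truth
  (:func:`tune_kalman`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product

import numpy as np
from scipy.signal import butter, sosfiltfilt

__all__ = [
    "KalmanSpec",
    "ConstantFit",
    "KalmanFit",
    "fit_linear_regression",
    "fit_zero_activity_average",
    "fit_kalman",
    "tune_kalman",
]


@dataclass(frozen=True)
class KalmanSpec:
    """Filter parameters.

    ``q_rmr``/``q_alpha`` are per-step random-walk variances, so a tuned
    spec is specific to one sample interval.  ``lowpass_cutoff`` (cycles
    per day) controls the zero-phase post-filter applied to the RMR state
    so the causal filter's high-frequency chatter does not dominate
    band-limited comparisons.
    """

    q_rmr: float = 1e-4
    q_alpha: float = 0.0
    r_obs: float = 0.25
    lowpass_cutoff: float = 7.5

    def __post_init__(self) -> None:
        if self.q_rmr < 0 or self.q_alpha < 0 or self.r_obs <= 0:
            raise ValueError("variances must be non-negative, r_obs positive")


@dataclass
class ConstantFit:
    """Constant-RMR estimate (linear regression or zero-activity mean)."""

    rmr: float
    alpha: float | None
    aee: float
    method: str

    def rmr_trace(self, n: int) -> np.ndarray:
        return np.full(n, self.rmr)

    def summary(self) -> dict:
        return {
            "method": self.method,
            "alpha": self.alpha,
            "daily_rmr": self.rmr,
            "daily_aee": self.aee,
        }


@dataclass
class KalmanFit:
    t: np.ndarray
    rmr_t: np.ndarray           # low-passed RMR state
    rmr_raw: np.ndarray         # unfiltered causal state
    alpha_t: np.ndarray
    rmr_sd: np.ndarray          # posterior SD of the RMR state
    spec: KalmanSpec

    @property
    def daily_rmr(self) -> float:
        return float(np.mean(self.rmr_t))

    def summary(self) -> dict:
        return {
            "method": "kalman",
            "alpha": float(np.mean(self.alpha_t)),
            "daily_rmr": self.daily_rmr,
        }


def fit_linear_regression(y: np.ndarray, w: np.ndarray) -> ConstantFit:
    """OLS of TEE on [1, w]; RMR = mean(y) - alpha * mean(w)."""
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if y.size != w.size or y.size < 2:
        raise ValueError("y and w must be equal-length vectors")
    if np.var(w) <= 0:
        raise ValueError("degenerate activity trace (zero variance)")
    X = np.column_stack([np.ones_like(w), w])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    rmr = float(coef[0])
    alpha = float(coef[1])
    return ConstantFit(rmr=rmr, alpha=alpha,
                       aee=float(np.mean(y) - rmr), method="linreg")


def fit_zero_activity_average(
    y: np.ndarray,
    t_y: np.ndarray,
    x: np.ndarray,
    t_x: np.ndarray,
    lag_window: float = 15.0,
) -> ConstantFit:
    """Mean TEE over samples preceded by ``lag_window`` minutes of rest.

    The lag lets the chamber washout of the preceding activity decay
    before a sample is declared activity-free; with ``lag_window = 0``
    recent-activity energy still contaminates the average.
    """
    y = np.asarray(y, float)
    t_y = np.asarray(t_y, float)
    x = np.asarray(x, float)
    t_x = np.asarray(t_x, float)
    lag_s = lag_window * 60.0
    # time of the most recent activity at or before each PA sample
    last_active = np.where(x > 0, t_x, -np.inf)
    last_active = np.maximum.accumulate(last_active)
    idx = np.searchsorted(t_x, t_y, side="right") - 1
    la_y = np.where(idx >= 0, last_active[np.clip(idx, 0, None)], -np.inf)
    quiet = (t_y - la_y) >= lag_s
    if not np.any(quiet):
        raise ValueError(
            f"no samples preceded by {lag_window:g} min of inactivity; "
            "try a smaller lag_window"
        )
    rmr = float(np.mean(y[quiet]))
    return ConstantFit(rmr=rmr, alpha=None,
                       aee=float(np.mean(y) - rmr), method="zeroact")


def fit_kalman(
    y: np.ndarray,
    w: np.ndarray,
    spec: KalmanSpec,
    t: np.ndarray | None = None,
    dt: float | None = None,
) -> KalmanFit:
    """Causal Kalman filter on the state [RMR_t, alpha_t].

    Random-walk dynamics with per-step variances (q_rmr, q_alpha) and
    scalar observation ``y_t = RMR_t + alpha_t w_t + v_t``.  TEE and
    activity must share one grid (supply ``t`` or ``dt`` for the
    post-hoc low-pass).  With both process variances zero the filter is
    recursive least squares and converges to the constant-parameter OLS
    solution.
    """
    y = np.asarray(y, float)
    w = np.asarray(w, float)
    if y.shape != w.shape:
        raise ValueError("Kalman filter needs TEE and activity on one grid")
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(w))):
        raise ValueError("non-finite values in inputs")
    n = y.size
    m0, m1 = float(np.mean(y)), 0.0
    p00, p01, p11 = 100.0, 0.0, 100.0     # diffuse prior
    q0, q1, r = spec.q_rmr, spec.q_alpha, spec.r_obs
    rmr = np.empty(n)
    alpha = np.empty(n)
    sd = np.empty(n)
    for i in range(n):
        p00 += q0
        p11 += q1
        wi = w[i]
        # innovation
        s = p00 + 2.0 * wi * p01 + wi * wi * p11 + r
        if not np.isfinite(s) or s <= 0:
            raise FloatingPointError(f"Kalman filter diverged at step {i}")
        k0 = (p00 + wi * p01) / s
        k1 = (p01 + wi * p11) / s
        innov = y[i] - (m0 + m1 * wi)
        m0 += k0 * innov
        m1 += k1 * innov
        # Joseph-free covariance update (standard form)
        h0, h1 = p00 + wi * p01, p01 + wi * p11
        p00 -= k0 * h0
        p01 -= k0 * h1
        p11 -= k1 * h1
        rmr[i] = m0
        alpha[i] = m1
        sd[i] = np.sqrt(max(p00, 0.0))
    if dt is None:
        dt = float(t[1] - t[0]) if t is not None and len(t) > 1 else None
    smooth = rmr
    if dt is not None and spec.lowpass_cutoff > 0:
        nyq = 0.5 / (dt / 86400.0)     # cycles/day
        if spec.lowpass_cutoff < nyq:
            sos = butter(4, spec.lowpass_cutoff / nyq, output="sos")
            pad = min(3 * (len(sos) + 1) * 10, n - 1)
            smooth = sosfiltfilt(sos, rmr, padlen=pad)
    return KalmanFit(
        t=t if t is not None else np.arange(n, dtype=float),
        rmr_t=smooth, rmr_raw=rmr, alpha_t=alpha, rmr_sd=sd, spec=spec,
    )


_DEFAULT_Q_GRID = (1e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 1e-2)
_DEFAULT_R_GRID = (0.05, 0.25, 1.0, 4.0)


def tune_kalman(
    training: list[tuple[np.ndarray, np.ndarray, np.ndarray]],
    dt: float,
    q_rmr_grid=_DEFAULT_Q_GRID,
    r_obs_grid=_DEFAULT_R_GRID,
    q_alpha_grid=(0.0,),
    base_spec: KalmanSpec | None = None,
    error_fn=None,
    use_raw: bool = True,
) -> tuple[KalmanSpec, dict]:
    """Grid-search the process/observation variances against known truth.

    ``training`` is a list of ``(y, w, rmr_truth)`` triples on a common
    grid with interval ``dt`` seconds; ``error_fn(est, truth)`` defaults
    to plain RMSE.  With ``use_raw`` (default) the error is evaluated on
    the filter's own causal output: the parameters characterise the
    filter, while the zero-phase reporting low-pass is a separate,
    post-hoc step.  Returns the best spec and the error surface.  The
    optimum is per sample interval: per-step random-walk variances do not
    transfer across rates.
    """
    if not training:
        raise ValueError("no training datasets")
    base = base_spec or KalmanSpec()
    if error_fn is None:
        def error_fn(est, truth):
            return float(np.sqrt(np.mean((est - truth) ** 2)))
    surface = {}
    best_key, best_err = None, np.inf
    for q0, q1, r in product(q_rmr_grid, q_alpha_grid, r_obs_grid):
        spec = replace(base, q_rmr=q0, q_alpha=q1, r_obs=r)
        errs = []
        try:
            for y, w, truth in training:
                fit = fit_kalman(y, w, spec, dt=dt)
                est = fit.rmr_raw if use_raw else fit.rmr_t
                errs.append(error_fn(est, truth))
        except FloatingPointError:
            continue
        surface[(q0, q1, r)] = float(np.mean(errs))
        if surface[(q0, q1, r)] < best_err:
            best_err = surface[(q0, q1, r)]
            best_key = (q0, q1, r)
    if best_key is None:
        raise RuntimeError("Kalman tuning failed on every grid point")
    spec = replace(base, q_rmr=best_key[0], q_alpha=best_key[1], r_obs=best_key[2])
    return spec, {"surface": surface, "best_error": best_err}
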