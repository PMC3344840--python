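"""Penalised-spline decomposition of total energy expenditure.

The measured TEE trace ``y`` at times ``t`` is modelled as

    y_i = r(t_i) + alpha * w_i + e_i,

where ``r(t) = sum_j beta_j B_j(t)`` is the resting metabolic rate built
from cubic B-splines on equidistant knots, ``alpha`` is the caloric cost
of activity (CCA) and ``w`` is the activity trace after preprocessing and
diffusion filtering (module :mod:`teedecomp.diffusion`).  The coefficients
minimise a penalised least-squares criterion with a roughness penalty on
the squared first derivative of ``r``; the smoothing parameter is chosen
by generalised cross-validation (GCV).

Because beam-break counts measure true activity intensity only noisily,
the regression of TEE on ``w`` suffers regression dilution.  We assume a
multiplicative error model, ``w_obs = w_true * (1 + u)`` with
``E u = 0`` and ``Var u = sigma_u^2`` i.i.d., and use the corrected
least-squares (corrected score) estimator: the Gram contribution of the
activity column, ``w'w``, overstates the true signal energy by the factor
``(1 + sigma_u^2)`` while all cross terms with the spline columns are
unbiased, so dividing ``w'w`` by ``(1 + sigma_u^2)`` restores an unbiased
normal-equation system.  ``sigma_u^2`` itself is estimated from the
heteroskedastic residuals of a preliminary uncorrected fit via maximum
likelihood with ``Var(e_i) = sigma_e^2 + alpha^2 w_i^2 sigma_u^2``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import LinAlgError, cho_factor, cho_solve
from scipy.optimize import minimize

from .diffusion import DiffusionParams, convolve_activity, impulse_response
from .io import CalorimetryDataset

__all__ = [
    "SplineModel",
    "DecompositionFit",
    "DecompositionConfig",
    "build_basis",
    "fit_penalized",
    "select_lambda_gcv",
    "estimate_sigma_u",
    "counting_sigma_u2",
    "predict_rmr",
    "decompose",
]

_SEC_PER_DAY = 86400.0

# 3-point Gauss-Legendre on [0, 1]: exact for the quartic integrand
# B_i'(t) B_j'(t) on each knot interval
_GL_NODES = (np.array([-np.sqrt(0.6), 0.0, np.sqrt(0.6)]) + 1.0) / 2.0
_GL_WEIGHTS = np.array([5.0, 8.0, 5.0]) / 18.0


@dataclass
class SplineModel:
    """Cubic B-spline basis with first-derivative roughness penalty.

    Time is handled internally in days so that penalty entries are O(1).
    ``knots`` is the full (degree-padded) knot vector; ``Z`` the n x K
    design matrix at the data times; ``P`` the K x K penalty matrix
    ``P[i, j] = integral B_i'(t) B_j'(t) dt`` over the data span.
    """

    t: np.ndarray            # sample times, seconds
    knots: np.ndarray        # full knot vector, days
    knots_per_day: float
    Z: np.ndarray
    P: np.ndarray
    # basis functions supported on the span (degree padding spawns dead ones)
    col_slice: slice = field(default_factory=lambda: slice(None))
    lam: float | None = None

    @property
    def n_basis(self) -> int:
        return self.Z.shape[1]


def build_basis(t_y: np.ndarray, knots_per_day: float = 15) -> SplineModel:
    """Build the cubic B-spline basis on equidistant knots.

    The knot grid extends one interval beyond the data span on each side
    (plus the usual 3 repeated-spacing boundary knots) so that every basis
    function overlapping the data is complete and the basis keeps its
    partition-of-unity property on the whole span.
    """
    t_y = np.asarray(t_y, dtype=float)
    if t_y.ndim != 1 or t_y.size < 2:
        raise ValueError("t_y must be a 1-d grid with >= 2 points")
    if np.any(np.diff(t_y) <= 0):
        raise ValueError("t_y must be strictly increasing")
    if knots_per_day < 1:
        raise ValueError("knots_per_day must be >= 1")
    td = t_y / _SEC_PER_DAY
    h = 1.0 / knots_per_day
    span = td[-1] - td[0]
    if span < h:
        raise ValueError("data span shorter than one knot interval")
    lo = td[0] - h
    n_int = int(np.ceil((td[-1] + h - lo) / h - 1e-12))
    knots = lo + h * np.arange(-3, n_int + 4)
    K_all = knots.size - 4
    # keep only basis functions whose support intersects the data span:
    # the degree-padding knots spawn splines living entirely in the margin,
    # whose design columns would be identically zero (singular Gram)
    eps = 1e-9 * h
    keep = [j for j in range(K_all)
            if knots[j + 4] > td[0] + eps and knots[j] < td[-1] - eps]
    sl = slice(keep[0], keep[-1] + 1)
    Z = BSpline.design_matrix(td, knots, 3).toarray()[:, sl]
    K = K_all

    # derivative of the cubic basis: degree-2 basis on knots[1:-1] times a
    # scaled first-difference matrix
    diff = np.zeros((K - 1, K))
    denom = knots[4 : K + 3] - knots[1:K]
    rows = np.arange(K - 1)
    diff[rows, rows] = -3.0 / denom
    diff[rows, rows + 1] = 3.0 / denom
    diff = diff[:, sl]

    # assemble integral of B' B'^T by Gauss quadrature on each knot
    # interval clipped to the data span
    P = np.zeros((Z.shape[1], Z.shape[1]))
    edges = knots[3 : 3 + n_int + 1]
    nodes = []
    wts = []
    for a, b in zip(edges[:-1], edges[1:]):
        a = max(a, td[0])
        b = min(b, td[-1])
        if b - a <= 0:
            continue
        nodes.append(a + (b - a) * _GL_NODES)
        wts.append((b - a) * _GL_WEIGHTS)
    if nodes:
        xq = np.concatenate(nodes)
        wq = np.concatenate(wts)
        D = BSpline.design_matrix(xq, knots[1:-1], 2).toarray() @ diff
        P = (D * wq[:, None]).T @ D
        P = 0.5 * (P + P.T)
    return SplineModel(t=t_y, knots=knots, knots_per_day=knots_per_day,
                       Z=Z, P=P, col_slice=sl)


def predict_rmr(model: SplineModel, beta: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Evaluate the fitted RMR spline at arbitrary times (seconds).

    Times outside the basis' base interval (e.g. in the burn-in prefix
    beyond the knot margin) are clamped to the nearest boundary, so the
    returned trace is defined everywhere but constant beyond the span.
    """
    td = np.asarray(t, dtype=float) / _SEC_PER_DAY
    lo, hi = model.knots[3], model.knots[-4]
    eps = 1e-12 * max(abs(lo), abs(hi), 1.0)
    td = np.clip(td, lo, hi - eps)
    Z = BSpline.design_matrix(td, model.knots, 3).toarray()[:, model.col_slice]
    return Z @ beta


@dataclass
class DecompositionFit:
    """Result of a penalised decomposition fit.

    ``rmr_t + aee_t + residuals == y`` holds exactly by construction on
    the fitted rows.  ``edf`` is the trace of the smoother matrix.
    """

    alpha: float
    beta: np.ndarray
    sigma_u2: float
    sigma_e2: float
    lam: float
    edf: float
    t: np.ndarray
    y: np.ndarray
    w: np.ndarray
    rmr_t: np.ndarray
    aee_t: np.ndarray
    residuals: np.ndarray
    mask: np.ndarray
    model: SplineModel | None = None
    warnings_: list = field(default_factory=list)
    transform: object = None

    @property
    def daily_tee(self) -> float:
        return float(np.mean(self.y[self.mask]))

    @property
    def daily_rmr(self) -> float:
        return float(np.mean(self.rmr_t[self.mask]))

    @property
    def daily_aee(self) -> float:
        return float(np.mean(self.aee_t[self.mask]))

    def summary(self) -> dict:
        out = {
            "alpha": float(self.alpha),
            "sigma_u2": float(self.sigma_u2),
            "lambda": float(self.lam),
            "edf": float(self.edf),
            "daily_tee": self.daily_tee,
            "daily_rmr": self.daily_rmr,
            "daily_aee": self.daily_aee,
        }
        if self.transform is not None and hasattr(self.transform, "to_dict"):
            out["transform"] = self.transform.to_dict()
        if self.warnings_:
            out["warnings"] = list(self.warnings_)
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2))

    def traces_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.t,
                "rmr_kcal_day": self.rmr_t,
                "aee_kcal_day": self.aee_t,
            }
        )


class _PenalizedSystem:
    """Cached normal-equation pieces for the augmented design [w, Z].

    Shared by the fitter and the GCV search so the n-dependent products
    are formed once.
    """

    def __init__(self, y: np.ndarray, w: np.ndarray, model: SplineModel,
                 rows: np.ndarray | None = None):
        Z = model.Z if rows is None else model.Z[rows]
        yy = y if rows is None else y[rows]
        ww = w if rows is None else w[rows]
        self.X = np.column_stack([ww, Z])
        self.y = yy
        self.n = yy.size
        self.G = self.X.T @ self.X
        self.Xty = self.X.T @ yy
        self.yty = float(yy @ yy)
        K = model.n_basis
        self.Pfull = np.zeros((K + 1, K + 1))
        self.Pfull[1:, 1:] = model.P
        # natural scale of lambda: balances data and penalty curvature
        trP = np.trace(model.P)
        self.lam_scale = np.trace(self.G[1:, 1:]) / trP if trP > 0 else 1.0

    def solve(self, lam: float, sigma_u2: float) -> tuple[np.ndarray, float, float]:
        """Return (theta, rss, edf) for the given penalty and correction."""
        Gc = self.G.copy()
        Gc[0, 0] /= 1.0 + sigma_u2
        A = Gc + lam * self.Pfull
        if self.G[0, 0] <= 0.0:
            # all-zero activity column: pin alpha = 0 instead of failing
            A[0, 0] = 1.0
        try:
            c = cho_factor(A, lower=True)
        except LinAlgError as err:
            raise LinAlgError(
                f"singular penalised system (rank deficiency) at lambda={lam:g}; "
                "increase lambda or reduce the number of basis functions"
            ) from err
        theta = cho_solve(c, self.Xty)
        rss = self.yty - 2.0 * theta @ self.Xty + theta @ (self.G @ theta)
        edf = float(np.trace(cho_solve(c, self.G)))
        return theta, max(rss, 0.0), edf

    def gcv(self, lam: float, sigma_u2: float) -> float:
        _, rss, edf = self.solve(lam, sigma_u2)
        denom = self.n - edf
        if denom <= 0:
            return np.inf
        return self.n * rss / denom**2


def fit_penalized(
    y: np.ndarray,
    w: np.ndarray,
    model: SplineModel,
    lam: float,
    sigma_u2: float = 0.0,
    mask: np.ndarray | None = None,
) -> DecompositionFit:
    """Solve the penalised, attenuation-corrected normal equations.

    With ``sigma_u2 == 0`` and ``lam == 0`` this reduces to ordinary least
    squares on the augmented design ``[w, Z]``.  ``mask`` selects the rows
    used for fitting (burn-in / missing-data exclusion); fitted traces are
    returned on the full grid.
    """
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if y.size != model.Z.shape[0] or w.size != y.size:
        raise ValueError("y, w and the basis must have matching lengths")
    if lam < 0 or sigma_u2 < 0:
        raise ValueError("lambda and sigma_u2 must be non-negative")
    rows = None if mask is None else np.flatnonzero(mask)
    sys = _PenalizedSystem(y, w, model, rows)
    theta, _, edf = sys.solve(lam, sigma_u2)
    alpha = float(theta[0])
    beta = theta[1:]
    warns = []
    if alpha < 0:
        warns.append("negative caloric cost of activity (model misfit?)")
        warnings.warn(warns[-1], stacklevel=2)
    rmr = model.Z @ beta
    aee = alpha * w
    resid = y - rmr - aee
    full_mask = np.ones(y.size, bool) if mask is None else np.asarray(mask, bool)
    sigma_e2 = float(np.mean(resid[full_mask] ** 2))
    return DecompositionFit(
        alpha=alpha, beta=beta, sigma_u2=sigma_u2, sigma_e2=sigma_e2,
        lam=lam, edf=edf, t=model.t, y=y, w=w, rmr_t=rmr, aee_t=aee,
        residuals=resid, mask=full_mask, model=model, warnings_=warns,
    )


def select_lambda_gcv(
    y: np.ndarray,
    w: np.ndarray,
    model: SplineModel,
    sigma_u2: float = 0.0,
    mask: np.ndarray | None = None,
    grid_decades: tuple[float, float] = (-10.0, 7.0),
    grid_size: int = 35,
) -> float:
    """Minimise GCV(lambda) = n RSS / (n - tr S)^2 over lambda.

    A log-spaced grid (centred on the natural data/penalty scale) is
    scanned first and the bracketing interval refined by golden-section
    search on log-lambda.  GCV plateaus are broken towards the smallest
    lambda within 0.1 % of the minimum; a monotone profile returns the
    boundary with a warning.
    """
    rows = None if mask is None else np.flatnonzero(mask)
    sys = _PenalizedSystem(np.asarray(y, float), np.asarray(w, float), model, rows)
    grid = sys.lam_scale * np.logspace(grid_decades[0], grid_decades[1], grid_size)
    scores = np.array([sys.gcv(l, sigma_u2) for l in grid])
    i_min = int(np.argmin(scores))
    # plateau tie-break: smallest lambda within 0.1 % of the minimum
    close = np.flatnonzero(scores <= scores[i_min] * 1.001)
    i_min = int(close[0])
    if i_min in (0, grid.size - 1):
        warnings.warn(
            "GCV minimised at the boundary of the lambda grid", stacklevel=2
        )
        return float(grid[i_min])
    lo, hi = np.log(grid[i_min - 1]), np.log(grid[i_min + 1])
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c_ = b - invphi * (b - a)
    d_ = a + invphi * (b - a)
    fc = sys.gcv(np.exp(c_), sigma_u2)
    fd = sys.gcv(np.exp(d_), sigma_u2)
    for _ in range(40):
        if b - a < 1e-3:
            break
        if fc < fd:
            b, d_, fd = d_, c_, fc
            c_ = b - invphi * (b - a)
            fc = sys.gcv(np.exp(c_), sigma_u2)
        else:
            a, c_, fc = c_, d_, fd
            d_ = a + invphi * (b - a)
            fd = sys.gcv(np.exp(d_), sigma_u2)
    return float(np.exp((a + b) / 2.0))


def estimate_sigma_u(
    residuals: np.ndarray,
    w: np.ndarray,
    alpha: float,
    sigma_e2_init: float | None = None,
) -> tuple[float, float]:
    """ML estimate of the multiplicative activity-error variance.

    Residuals of an uncorrected preliminary fit are heteroskedastic when
    activity is measured with multiplicative error:
    ``Var(e_i) = sigma_e^2 + alpha^2 w_i^2 sigma_u^2``.  The Gaussian
    likelihood is maximised over (log sigma_e^2, log sigma_u^2); if the
    homoskedastic boundary fits better, ``sigma_u^2 = 0`` is returned.
    """
    e2 = np.asarray(residuals, dtype=float) ** 2
    w = np.asarray(w, dtype=float)
    if e2.size != w.size:
        raise ValueError("residuals and w must have the same length")
    n = e2.size
    if alpha <= 0 or not np.any(w > 0):
        return 0.0, float(np.mean(e2))
    a2w2 = (alpha * w) ** 2

    def nll(p):
        v = np.exp(p[0]) + a2w2 * np.exp(p[1])
        return 0.5 * np.sum(np.log(v) + e2 / v)

    # start near the homoskedastic solution with a small error share
    se2_0 = sigma_e2_init or max(float(np.mean(e2[w <= np.median(w)])), 1e-12)
    best = None
    for su2_0 in (1e-3, 1e-1):
        res = minimize(
            nll, x0=[np.log(se2_0), np.log(su2_0)], method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-8 * n, "maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
    nll0 = 0.5 * n * (np.log(np.mean(e2)) + 1.0)
    if nll0 <= best.fun:
        return 0.0, float(np.mean(e2))
    se2, su2 = np.exp(best.x)
    return float(su2), float(se2)


def counting_sigma_u2(
    x: np.ndarray,
    t_x: np.ndarray,
    params: DiffusionParams,
    t_y: np.ndarray,
    w: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Upper bound on the attenuating error variance of ``w`` from counting noise.

    Regression dilution is caused by error in the *regressor*.  After
    diffusion filtering, the only regressor noise left in ``w`` is the
    beam-break counting noise propagated through the kernel: treating the
    counts per interval as Poisson (variance = observed count), the noise
    variance of ``w_i = sum_j h(t_i - t_j) dt x_j`` is
    ``sum_j h^2(t_i - t_j) dt^2 Var(x_j)``, one extra convolution with the
    squared kernel.  Expressed as an equivalent multiplicative variance,
    ``sigma_u^2 <= sum_i Var(w_i) / sum_i w_i^2``.  Residual-likelihood
    estimates above this bound are attributable to activity-scaled model
    misfit (e.g. per-bout cost variation), which lives in the response,
    not the regressor, and does not attenuate the slope.
    """
    from scipy.signal import fftconvolve

    x = np.asarray(x, dtype=float)
    t_x = np.asarray(t_x, dtype=float)
    dt_x = float(np.median(np.diff(t_x)))
    _, h = impulse_response(params, dt_x)
    # with x in counts/interval and w built from the rate x/dt, the dt
    # factors cancel: Var(w_i) = (h^2 * counts)_i
    var_w = fftconvolve(np.maximum(x, 0.0), h * h)[: x.size]
    if t_y.size != t_x.size or not np.allclose(t_y, t_x):
        var_w = np.interp(t_y, t_x, var_w)
    if mask is not None:
        var_w = var_w[mask]
        w = w[mask]
    denom = float(np.sum(w**2))
    if denom <= 0:
        return 0.0
    return float(np.sum(var_w) / denom)


@dataclass
class DecompositionConfig:
    """Tunable parameters of the full decomposition pipeline."""

    knots_per_day: float = 15
    diffusion: DiffusionParams = field(default_factory=DiffusionParams)
    transform: object = None          # ActivityTransform or None (identity)
    correct_attenuation: bool = True
    # cap the ML sigma_u^2 by the variance the beam-break counting process
    # can generate (see counting_sigma_u2); residual heteroskedasticity in
    # excess of that bound reflects model misfit, which must not be
    # "corrected" as if it were regressor noise
    guard_counting: bool = True
    sigma_u2: float | None = None          # fixed override of the estimate
    reselect_lambda: bool = True
    burn_in_seconds: float | None = None   # None -> 5*(tau_s+tau_c)
    lam: float | None = None               # fixed lambda instead of GCV

    def to_dict(self) -> dict:
        d = {
            "knots_per_day": self.knots_per_day,
            "correct_attenuation": self.correct_attenuation,
            **self.diffusion.to_dict(),
        }
        if self.transform is not None:
            d["transform"] = getattr(self.transform, "to_dict", lambda: str(self.transform))()
        return d


def decompose(
    dataset: CalorimetryDataset,
    config: DecompositionConfig | None = None,
    model: SplineModel | None = None,
) -> DecompositionFit:
    """Full decomposition pipeline on a calorimetry dataset.

    Steps: (1) preprocess raw activity counts to an intensity linearly
    related to AEE, (2) diffusion-filter the activity on its own (fine)
    grid and sample it at the TEE times, (3) preliminary uncorrected fit
    with GCV-selected smoothing, (4) estimate ``sigma_u^2`` from the
    residual heteroskedasticity, (5) final corrected fit with re-selected
    smoothing.  The first ``burn_in_seconds`` are excluded from fitting.
    """
    cfg = config or DecompositionConfig()
    t_y, y = dataset.t_y, dataset.y
    x = dataset.x
    if cfg.transform is not None:
        x = cfg.transform(x)
    # convert counts per interval to a rate so that w has dataset-rate
    # independent units (alpha then transfers across sampling regimes)
    dt_x = dataset.dt_pa
    w = convolve_activity(x / dt_x, dataset.t_x, cfg.diffusion, t_y)

    finite = np.isfinite(y) & np.isfinite(w)
    burn = cfg.burn_in_seconds
    if burn is None:
        burn = cfg.diffusion.burn_in_seconds
    mask = finite & (t_y >= t_y[0] + burn)
    if mask.sum() < 10:
        raise ValueError("too few usable samples after burn-in/missing-data masking")

    # the basis lives on the fitted span only: basis functions supported
    # solely in the burn-in prefix would be unidentifiable
    if model is None:
        model = build_basis(t_y[mask], cfg.knots_per_day)

    yk, wk = y[mask], w[mask]

    zero_activity = not np.any(wk > 0)
    if zero_activity:
        warnings.warn(
            "activity is identically zero: caloric cost of activity is "
            "undefined; returning a penalised smooth of TEE with alpha=0",
            stacklevel=2,
        )

    lam = cfg.lam if cfg.lam is not None else select_lambda_gcv(yk, wk, model, 0.0)
    fit = fit_penalized(yk, wk, model, lam, 0.0)

    sigma_u2 = 0.0
    if not zero_activity and cfg.correct_attenuation and fit.alpha > 0:
        if cfg.sigma_u2 is not None:
            sigma_u2 = cfg.sigma_u2
        else:
            sigma_u2, _ = estimate_sigma_u(fit.residuals, wk, fit.alpha)
            if cfg.guard_counting and sigma_u2 > 0:
                bound = counting_sigma_u2(
                    x, dataset.t_x, cfg.diffusion, t_y, w, mask)
                sigma_u2 = min(sigma_u2, bound)
    if sigma_u2 > 0:
        lam2 = lam
        if cfg.reselect_lambda and cfg.lam is None:
            lam2 = select_lambda_gcv(yk, wk, model, sigma_u2)
        fit = fit_penalized(yk, wk, model, lam2, sigma_u2)
    if zero_activity:
        fit.warnings_.append("alpha undefined (zero activity)")

    # expand the fitted spline back to the full grid (burn-in included,
    # for plotting; all summary statistics respect the mask)
    rmr_full = predict_rmr(model, fit.beta, t_y)
    aee_full = fit.alpha * w
    fit.t, fit.y, fit.w = t_y, y, w
    fit.rmr_t = rmr_full
    fit.aee_t = aee_full
    fit.residuals = y - rmr_full - aee_full
    fit.mask = mask
    fit.transform = cfg.transform
    return fit
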