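"""Penalised-spline estimator: basis, penalty, GCV, EIV correction."""

import numpy as np
import pytest

from teedecomp import (
    CalorimetryDataset,
    DecompositionConfig,
    DiffusionParams,
    decompose,
)
from teedecomp.splinefit import (
    _PenalizedSystem,
    build_basis,
    estimate_sigma_u,
    fit_penalized,
    predict_rmr,
    select_lambda_gcv,
)

SEC_PER_DAY = 86400.0


@pytest.fixture(scope="module")
def grid_3d():
    return np.arange(0, 3 * SEC_PER_DAY, 60.0)


@pytest.fixture(scope="module")
def model_3d(grid_3d):
    return build_basis(grid_3d, knots_per_day=15)


class TestBasis:
    def test_partition_of_unity(self, model_3d):
        assert np.allclose(model_3d.Z.sum(axis=1), 1.0, atol=1e-10)

    def test_penalty_annihilates_constants(self, model_3d):
        one = np.ones(model_3d.n_basis)
        assert abs(one @ model_3d.P @ one) < 1e-10

    def test_penalty_positive_semidefinite_symmetric(self, model_3d):
        P = model_3d.P
        assert np.allclose(P, P.T)
        assert np.min(np.linalg.eigvalsh(P)) > -1e-10

    def test_linear_ramp_penalty_equals_span_times_slope_squared(self, grid_3d):
        model = build_basis(grid_3d, knots_per_day=5)
        # cubic B-splines on equidistant knots reproduce a linear ramp with
        # coefficients at the Greville abscissae
        k = model.knots
        sl = model.col_slice
        greville = np.array([(k[j + 1] + k[j + 2] + k[j + 3]) / 3.0
                             for j in range(k.size - 4)])[sl]
        slope = 2.5       # kcal/day per day
        beta = slope * greville
        span = (grid_3d[-1] - grid_3d[0]) / SEC_PER_DAY
        assert beta @ model.P @ beta == pytest.approx(span * slope**2, rel=1e-9)

    def test_penalty_matches_fine_grid_quadrature_oracle(self, grid_3d, rng):
        # independent oracle: numerical derivative + trapezoid at 1 s
        model = build_basis(grid_3d, knots_per_day=15)
        beta = rng.normal(size=model.n_basis)
        tf = np.arange(grid_3d[0], grid_3d[-1] + 1.0, 1.0)
        r = predict_rmr(model, beta, tf)
        dr = np.gradient(r, 1.0 / SEC_PER_DAY)
        oracle = np.trapezoid(dr**2, dx=1.0 / SEC_PER_DAY)
        assert beta @ model.P @ beta == pytest.approx(oracle, rel=1e-5)

    def test_rejects_bad_grids(self):
        with pytest.raises(ValueError):
            build_basis(np.array([0.0, -1.0, 2.0]))
        with pytest.raises(ValueError):
            build_basis(np.arange(0, 100, 10.0), knots_per_day=15)  # < 1 interval
        with pytest.raises(ValueError):
            build_basis(np.arange(0, SEC_PER_DAY, 60.0), knots_per_day=0.5)


class TestPenalizedFit:
    def test_ols_limit(self, rng):
        # sigma_u2 = 0, lambda = 0 reduces to OLS on [w, Z]
        t = np.arange(0, SEC_PER_DAY, 300.0)
        model = build_basis(t, knots_per_day=4)
        w = rng.exponential(1.0, t.size)
        y = 10.0 + 2.0 * w + rng.normal(0, 0.3, t.size)
        fit = fit_penalized(y, w, model, lam=0.0, sigma_u2=0.0)
        X = np.column_stack([w, model.Z])
        theta, *_ = np.linalg.lstsq(X, y, rcond=None)
        assert fit.alpha == pytest.approx(theta[0], rel=1e-8)
        assert np.allclose(fit.beta, theta[1:], rtol=1e-6, atol=1e-8)

    def test_infinite_smoothing_matches_two_parameter_regression(self, rng):
        # lambda -> inf forces a constant RMR; closed-form 2x2 oracle
        t = np.arange(0, SEC_PER_DAY, 300.0)
        model = build_basis(t, knots_per_day=4)
        w = rng.exponential(1.0, t.size)
        y = 10.0 + 2.0 * w + rng.normal(0, 0.3, t.size)
        fit = fit_penalized(y, w, model, lam=1e12)
        n = t.size
        su2 = 0.0
        A = np.array([[w @ w / (1 + su2), w.sum()], [w.sum(), n]])
        b = np.array([w @ y, y.sum()])
        alpha, const = np.linalg.solve(A, b)
        assert np.ptp(fit.rmr_t) < 1e-4
        assert fit.alpha == pytest.approx(alpha, abs=1e-4)
        assert np.mean(fit.rmr_t) == pytest.approx(const, abs=1e-3)

    def test_exact_decomposition_identity(self, rng):
        t = np.arange(0, SEC_PER_DAY, 120.0)
        model = build_basis(t, knots_per_day=10)
        w = rng.exponential(1.0, t.size)
        y = 10.0 + 2.0 * w + rng.normal(0, 0.5, t.size)
        fit = fit_penalized(y, w, model, lam=3.0, sigma_u2=0.1)
        assert np.allclose(fit.rmr_t + fit.aee_t + fit.residuals, y, atol=1e-10)

    def test_smoother_linear_in_y(self, rng):
        t = np.arange(0, SEC_PER_DAY, 300.0)
        model = build_basis(t, knots_per_day=6)
        w = rng.exponential(1.0, t.size)
        y1 = rng.normal(10, 1, t.size)
        y2 = rng.normal(10, 1, t.size)
        a, b = 0.7, -1.3
        f = lambda y: fit_penalized(y, w, model, lam=5.0, sigma_u2=0.05)
        lhs = f(a * y1 + b * y2)
        assert np.allclose(
            lhs.rmr_t + lhs.aee_t,
            a * (f(y1).rmr_t + f(y1).aee_t) + b * (f(y2).rmr_t + f(y2).aee_t),
            atol=1e-8,
        )

    def test_edf_strictly_decreasing_in_lambda(self, rng):
        t = np.arange(0, SEC_PER_DAY, 300.0)
        model = build_basis(t, knots_per_day=8)
        w = rng.exponential(1.0, t.size)
        y = rng.normal(10, 1, t.size)
        edfs = [fit_penalized(y, w, model, lam=l).edf
                for l in (0.0, 1.0, 10.0, 100.0, 1e4)]
        assert np.all(np.diff(edfs) < 0)

    def test_singular_unpenalised_system_raises_informatively(self):
        t = np.arange(0, SEC_PER_DAY, 7000.0)   # 13 points, 48+ basis fns
        model = build_basis(t, knots_per_day=15)
        w = np.ones(t.size)
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            fit_penalized(np.full(t.size, 10.0), w, model, lam=0.0)

    def test_negative_alpha_flagged(self, rng):
        t = np.arange(0, SEC_PER_DAY, 300.0)
        model = build_basis(t, knots_per_day=4)
        w = rng.exponential(1.0, t.size)
        y = 10.0 - 1.0 * w + rng.normal(0, 0.1, t.size)
        with pytest.warns(UserWarning, match="negative caloric cost"):
            fit = fit_penalized(y, w, model, lam=0.0)
        assert fit.alpha < 0
        assert fit.warnings_


class TestAttenuationCorrection:
    def test_corrected_alpha_unbiased_uncorrected_attenuated(self, rng):
        # Monte-Carlo oracle: with multiplicative regressor noise of
        # variance su2, OLS attenuates alpha by ~ su2/(1+su2); the
        # corrected score removes the bias.
        su = 0.3
        alpha_true = 2.0
        t = np.arange(0, SEC_PER_DAY, 30.0)
        model = build_basis(t, knots_per_day=2)
        alphas_unc, alphas_cor = [], []
        for _ in range(200):
            w_true = rng.exponential(1.0, t.size)
            y = 10.0 + alpha_true * w_true + rng.normal(0, 0.3, t.size)
            w_obs = w_true * (1.0 + rng.normal(0, su, t.size))
            alphas_unc.append(fit_penalized(y, w_obs, model, 0.0, 0.0).alpha)
            alphas_cor.append(fit_penalized(y, w_obs, model, 0.0, su**2).alpha)
        bias_unc = np.mean(alphas_unc) - alpha_true
        bias_cor = np.mean(alphas_cor) - alpha_true
        # attenuation of the uncentred regression: noise variance is
        # E[w^2] su^2 against signal variance Var(w); for Exp(1), E w^2 = 2,
        # Var w = 1
        attenuation = 2 * su**2 / (1.0 + 2 * su**2)
        assert bias_unc == pytest.approx(-alpha_true * attenuation, rel=0.25)
        assert abs(bias_cor) < abs(bias_unc) / 3


class TestGCV:
    def test_brute_force_grid_oracle(self, rng):
        t = np.arange(0, SEC_PER_DAY, 300.0)
        model = build_basis(t, knots_per_day=10)
        w = rng.exponential(1.0, t.size)
        y = 10.0 + 2.0 * w + 0.5 * np.sin(2 * np.pi * t / SEC_PER_DAY) \
            + rng.normal(0, 0.4, t.size)
        lam = select_lambda_gcv(y, w, model)
        sys = _PenalizedSystem(y, w, model)
        dense = sys.lam_scale * np.logspace(-10, 7, 400)
        scores = np.array([sys.gcv(l, 0.0) for l in dense])
        lam_star = dense[np.argmin(scores)]
        step = np.log(dense[1] / dense[0])
        assert sys.gcv(lam, 0.0) <= scores.min() * (1 + 1e-3) or \
            abs(np.log(lam / lam_star)) <= np.log(dense[2] / dense[0])

    def test_white_noise_resists_overfitting(self, rng):
        # flat truth + white noise: GCV should keep the fit far from
        # interpolation (median edf well below the basis size)
        t = np.arange(0, 2 * SEC_PER_DAY, 120.0)
        model = build_basis(t, knots_per_day=15)
        w = np.zeros(t.size)
        edfs = []
        for _ in range(5):
            y = 10.0 + rng.normal(0, 0.5, t.size)
            lam = select_lambda_gcv(y, w, model)
            edfs.append(fit_penalized(y, w, model, lam).edf)
        assert np.median(edfs) <= 0.2 * model.n_basis

    def test_constant_noiseless_signal_indifferent_to_smoothing(self):
        # a constant lies in the penalty null space: every lambda yields
        # the same (exact) fit, so the GCV choice is inconsequential
        t = np.arange(0, 2 * SEC_PER_DAY, 300.0)
        model = build_basis(t, knots_per_day=15)
        y = np.full(t.size, 10.0)
        w = np.zeros(t.size)
        lam = select_lambda_gcv(y, w, model)
        # tolerance reflects conditioning of the heavily penalised system
        for l, atol in ((lam, 1e-6), (1e12, 1e-3)):
            fit = fit_penalized(y, w, model, l)
            assert np.allclose(fit.rmr_t, 10.0, atol=atol)


class TestSigmaUEstimation:
    def test_homoskedastic_residuals_give_zero(self, rng):
        e = rng.normal(0, 0.5, 5000)
        w = rng.exponential(1.0, 5000)
        su2, se2 = estimate_sigma_u(e, w, alpha=2.0)
        assert su2 == pytest.approx(0.0, abs=5e-3)
        assert se2 == pytest.approx(0.25, rel=0.1)

    def test_recovers_generating_parameters(self, rng):
        # residuals drawn from the stated variance model
        n = 20000
        alpha, su, se = 2.0, 0.25, 0.4
        w = rng.exponential(1.0, n)
        v = se**2 + alpha**2 * w**2 * su**2
        e = rng.normal(0, np.sqrt(v))
        su2, se2 = estimate_sigma_u(e, w, alpha=alpha)
        assert su2 == pytest.approx(su**2, rel=0.10)
        assert se2 == pytest.approx(se**2, rel=0.10)

    def test_alpha_scale_identity(self, rng):
        # doubling alpha at fixed residuals quarters sigma_u^2
        n = 20000
        w = rng.exponential(1.0, n)
        v = 0.16 + 4.0 * w**2 * 0.0625
        e = rng.normal(0, np.sqrt(v), n)
        su2_1, _ = estimate_sigma_u(e, w, alpha=2.0)
        su2_2, _ = estimate_sigma_u(e, w, alpha=4.0)
        assert su2_2 == pytest.approx(su2_1 / 4.0, rel=0.05)


class TestDecomposePipeline:
    def test_noiseless_rmr_recovery(self, noiseless_sim):
        # no TEE noise, noise-free PA, exact linear PA-AEE link:
        # pointwise RMR error < 0.5 % of the mean RMR outside burn-in
        fit = decompose(noiseless_sim.observed)
        truth = noiseless_sim.truth
        err = np.abs(fit.rmr_t[fit.mask] - truth.rmr[fit.mask])
        assert err.max() < 0.005 * truth.rmr.mean()

    def test_zero_activity_constant_tee(self):
        t = np.arange(0, 2 * SEC_PER_DAY, 60.0)
        ds = CalorimetryDataset(
            t_y=t, y=np.full(t.size, 7.5), t_x=t.copy(), x=np.zeros(t.size))
        with pytest.warns(UserWarning, match="zero"):
            fit = decompose(ds)
        assert fit.alpha == 0.0
        assert "alpha undefined (zero activity)" in fit.warnings_
        assert np.allclose(fit.rmr_t[fit.mask], 7.5, atol=1e-6)
        assert np.all(fit.aee_t == 0)

    def test_summary_identities(self, quick_sim):
        fit = decompose(quick_sim.observed)
        s = fit.summary()
        assert s["daily_tee"] == pytest.approx(
            s["daily_rmr"] + s["daily_aee"]
            + np.mean(fit.residuals[fit.mask]), abs=1e-9)
        assert s["alpha"] >= 0
        assert s["sigma_u2"] >= 0

    def test_decomposition_identity_on_fitted_rows(self, quick_sim):
        fit = decompose(quick_sim.observed)
        m = fit.mask
        assert np.allclose(
            fit.rmr_t[m] + fit.aee_t[m] + fit.residuals[m],
            quick_sim.observed.y[m], atol=1e-9)

    def test_frequency_selectivity_of_knot_number(self, standard_sims):
        # more knots track faster RMR components; the average is insensitive
        from teedecomp.evaluation import band_limited_error

        lo_band, lo_avg, hi_band, hi_avg = [], [], [], []
        for sim in standard_sims[:5]:
            tr = sim.truth
            for k, band, avg in ((4, lo_band, lo_avg), (15, hi_band, hi_avg)):
                fit = decompose(sim.observed, DecompositionConfig(knots_per_day=k))
                m = fit.mask
                band.append(band_limited_error(
                    fit.rmr_t[m], tr.rmr[m], 10.0, f_c=7.5))
                avg.append(abs(np.mean(fit.rmr_t[m]) - np.mean(tr.rmr[m])))
        assert np.mean(hi_band) < np.mean(lo_band)
        assert np.mean(hi_avg) == pytest.approx(np.mean(lo_avg), abs=0.05)
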