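"""Telescoped SIC estimation: initialisation, Newton steps, fits and ΔBIC."""

import numpy as np
import pytest
from scipy import optimize, stats

from conftest import make_instance, oracle_best_subset
from sicreg.estimator import (
    delta_bic,
    fit_mpr_sic,
    fit_spr_sic,
    init_params,
    newton_step,
    sandwich_cov,
)
from sicreg.exceptions import DegenerateResponseError
from sicreg.model import Dataset, MPRParams, full_information, sic_objective
from sicreg.penalty import make_schedule

FAST_SCHEDULE = make_schedule(10, 1e-5, 100)


class TestInit:
    def test_intercept_only_model(self):
        data = Dataset.from_arrays(np.array([-1.0, 1.0]), np.empty((2, 0)))
        start = init_params(data)
        assert start.beta == pytest.approx([0.0])
        assert start.alpha == pytest.approx([0.0])  # s^2 = 2/(2-0) = 1

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        Xp = rng.standard_normal((20, 3))
        y = rng.standard_normal(20)
        data = Dataset.from_arrays(y, Xp)
        start = init_params(data)
        X = data.X
        beta_oracle = np.linalg.inv(X.T @ X) @ X.T @ y
        assert np.allclose(start.beta, beta_oracle, atol=1e-10)
        resid = y - X @ beta_oracle
        assert start.alpha[0] == pytest.approx(np.log(resid @ resid / (20 - 3)))
        assert np.all(start.alpha[1:] == 0)

    def test_exactly_linear_response_raises(self):
        rng = np.random.default_rng(4)
        Xp = rng.standard_normal((15, 2))
        y = 2.0 + Xp @ np.array([1.0, -1.0])
        with pytest.raises(DegenerateResponseError):
            init_params(Dataset.from_arrays(y, Xp, scale=False))


class TestNewtonStep:
    def test_fixed_point_at_stationary_point(self):
        data, _, _ = make_instance(21, n=60, p=2)
        mle = fit_mpr_sic(data, penalty_weight=0.0).params_hat
        stepped = newton_step(mle, data, eps=1e-5, penalty_weight=0.0)
        assert np.allclose(stepped.theta, mle.theta, atol=1e-10)

    def test_single_unpenalized_beta_step_lands_on_ols(self):
        data, _, _ = make_instance(22, n=40, p=3)
        beta_start = np.array([5.0, -2.0, 1.0, 0.0])
        params = MPRParams(beta_start, np.array([0.7, 0.0, 0.0, 0.0]))
        stepped = newton_step(params, data, eps=1.0, penalty_weight=0.0, components=("beta",))
        beta_ols, *_ = np.linalg.lstsq(data.X, data.y, rcond=None)
        assert np.allclose(stepped.beta, beta_ols, atol=1e-8)
        assert np.allclose(stepped.alpha, params.alpha)

    def test_agrees_with_dense_newton_oracle(self):
        data, _, _ = make_instance(23, n=30, p=3)
        params = init_params(data)
        eps, lam = 5.0, np.log(data.n)
        stepped = newton_step(params, data, eps, lam)

        def obj(theta):
            return sic_objective(MPRParams(theta[:4], theta[4:]), data, eps, lam)

        h = 1e-5
        t0 = params.theta
        d = t0.size
        g = np.array([(obj(t0 + h * e) - obj(t0 - h * e)) / (2 * h) for e in np.eye(d)])
        H = np.zeros((d, d))
        for i in range(d):
            for j in range(d):
                tpp = t0.copy(); tpp[i] += h; tpp[j] += h
                tpm = t0.copy(); tpm[i] += h; tpm[j] -= h
                tmp = t0.copy(); tmp[i] -= h; tmp[j] += h
                tmm = t0.copy(); tmm[i] -= h; tmm[j] -= h
                H[i, j] = (obj(tpp) - obj(tpm) - obj(tmp) + obj(tmm)) / (4 * h * h)
        H[:4, 4:] = 0.0  # RS scheme drops the cross blocks
        H[4:, :4] = 0.0
        oracle = t0 + np.linalg.solve(-H, g)
        assert np.allclose(stepped.theta, oracle, atol=1e-6)

    def test_accepted_step_never_decreases_objective(self):
        for seed in (31, 32, 33):
            data, _, _ = make_instance(seed, n=50, p=3)
            params = init_params(data)
            for eps in (5.0, 0.5, 0.01):
                obj0 = sic_objective(params, data, eps)
                params = newton_step(params, data, eps)
                assert sic_objective(params, data, eps) >= obj0 - 1e-9


class TestFit:
    def test_unpenalized_fit_matches_direct_mle(self):
        data, _, _ = make_instance(41, n=200, p=3)
        fit = fit_mpr_sic(data, penalty_weight=0.0)

        def nll(th):
            mu = data.X @ th[:4]
            var = np.exp(np.clip(data.X @ th[4:], -30, 30))
            return -np.sum(stats.norm.logpdf(data.y, mu, np.sqrt(var)))

        res = optimize.minimize(nll, np.zeros(8), method="BFGS",
                                options={"gtol": 1e-10, "maxiter": 3000})
        assert np.allclose(fit.params_hat.theta, res.x, atol=1e-6)

    def test_sparse_entries_zero_or_identical_and_bic_identity(self):
        data, _, _ = make_instance(42, n=300, p=3, beta=[0.2, 1.0, 0.0, 0.0],
                                   alpha=[0.0, 0.0, 1.0, 0.0])
        fit = fit_mpr_sic(data, schedule=FAST_SCHEDULE)
        for raw, sparse in ((fit.params_hat.beta, fit.params_sparse.beta),
                            (fit.params_hat.alpha, fit.params_sparse.alpha)):
            assert np.all((sparse == 0.0) | (sparse == raw))
        assert 0 in fit.active_beta and 0 in fit.active_alpha
        from sicreg.model import mpr_loglik

        k = (fit.active_beta.size - 1) + (fit.active_alpha.size - 1) + 2
        assert fit.bic == pytest.approx(
            -2 * mpr_loglik(fit.params_sparse, data) + fit.penalty_weight * k
        )

    @pytest.mark.parametrize("seed", [51, 52])
    def test_support_and_bic_match_exhaustive_oracle(self, seed):
        data, _, _ = make_instance(seed, n=500, p=2,
                                   beta=[0.3, 1.0, 0.0], alpha=[0.0, 0.0, 1.0])
        fit = fit_mpr_sic(data, schedule=FAST_SCHEDULE)
        sb, sa, bic = oracle_best_subset(data, np.log(data.n))
        assert tuple((fit.params_sparse.beta[1:] != 0).astype(int)) == sb
        assert tuple((fit.params_sparse.alpha[1:] != 0).astype(int)) == sa
        assert fit.bic == pytest.approx(bic, abs=1e-4)

    def test_scale_equivariance(self):
        data, _, _ = make_instance(53, n=400, p=3, beta=[0.0, 1.0, 0.0, 0.8],
                                   alpha=[0.2, 0.0, 0.9, 0.0])
        fit1 = fit_mpr_sic(data, schedule=FAST_SCHEDULE)
        c = 3.0
        data_c = Dataset(y=c * data.y, X=data.X, scale_factors=data.scale_factors)
        fit2 = fit_mpr_sic(data_c, schedule=FAST_SCHEDULE)
        assert np.allclose(fit2.params_hat.beta, c * fit1.params_hat.beta, atol=1e-4)
        assert fit2.params_hat.alpha[0] == pytest.approx(
            fit1.params_hat.alpha[0] + 2 * np.log(c), abs=1e-4
        )
        assert np.array_equal(fit1.params_sparse.beta != 0, fit2.params_sparse.beta != 0)

    def test_warm_start_continuity_logged_in_trace(self):
        data, _, _ = make_instance(54, n=200, p=2, beta=[0.0, 1.0, 0.0],
                                   alpha=[0.0, 0.0, 0.0])
        fit = fit_mpr_sic(data, schedule=FAST_SCHEDULE)
        assert len(fit.trace) == len(FAST_SCHEDULE)
        assert fit.trace[0].eps == pytest.approx(10.0)
        assert fit.trace[-1].eps == pytest.approx(1e-5)


class TestSprFit:
    def test_homoscedastic_unpenalized_recovers_classical_mle(self):
        data, _, _ = make_instance(61, n=150, p=3, alpha=[0.0, 0, 0, 0])
        fit = fit_spr_sic(data, penalty_weight=0.0)
        beta_ols, *_ = np.linalg.lstsq(data.X, data.y, rcond=None)
        assert np.allclose(fit.params_hat.beta, beta_ols, atol=1e-6)
        resid = data.y - data.X @ beta_ols
        assert np.exp(fit.params_hat.alpha[0]) == pytest.approx(
            np.mean(resid**2), abs=1e-6
        )
        assert np.all(fit.params_hat.alpha[1:] == 0)

    def test_spr_and_mpr_agree_on_homoscedastic_support(self):
        data, _, _ = make_instance(62, n=1000, p=4,
                                   beta=[0.0, 1.0, 0.0, 0.7, 0.0],
                                   alpha=[0.0, 0, 0, 0, 0])
        f_spr = fit_spr_sic(data, schedule=FAST_SCHEDULE)
        f_mpr = fit_mpr_sic(data, schedule=FAST_SCHEDULE)
        assert np.array_equal(f_spr.params_sparse.beta != 0, f_mpr.params_sparse.beta != 0)

    def test_spr_support_matches_exhaustive_oracle(self):
        data, _, _ = make_instance(63, n=500, p=3,
                                   beta=[0.2, 1.0, 0.0, 0.6], alpha=[0.1, 0, 0, 0])
        fit = fit_spr_sic(data, schedule=FAST_SCHEDULE)
        sb, _, _ = oracle_best_subset(data, np.log(data.n), spr=True)
        assert tuple((fit.params_sparse.beta[1:] != 0).astype(int)) == sb


class TestSandwich:
    def test_collapses_to_inverse_information_without_penalty(self):
        data, _, _ = make_instance(71, n=120, p=2)
        fit = fit_mpr_sic(data, penalty_weight=0.0)
        C = sandwich_cov(fit, data)
        _, I0 = full_information(fit.params_hat, data, 1e-5, 0.0)
        assert np.allclose(C, np.linalg.inv(I0), atol=1e-8)

    def test_symmetric_positive_semidefinite(self):
        data, _, _ = make_instance(72, n=300, p=3, beta=[0.0, 1.0, 0.0, 0.0],
                                   alpha=[0.0, 0.0, 0.8, 0.0])
        fit = fit_mpr_sic(data, schedule=FAST_SCHEDULE)
        C = fit.cov_hat
        assert np.max(np.abs(C - C.T)) < 1e-10
        assert np.linalg.eigvalsh(C).min() > -1e-10


class TestDeltaBic:
    def test_matches_two_independent_fits(self):
        data, _, _ = make_instance(81, n=300, p=2, beta=[0.0, 1.0, 0.0],
                                   alpha=[0.0, 0.0, 1.0])
        full = fit_mpr_sic(data, schedule=FAST_SCHEDULE)
        d = delta_bic(data, full, index=1, component="location", schedule=FAST_SCHEDULE)
        mask = np.array([True, False, True])
        restricted = fit_mpr_sic(data, schedule=FAST_SCHEDULE, beta_mask=mask)
        assert d == pytest.approx(restricted.bic - full.bic, abs=1e-8)
        assert np.all(restricted.params_hat.beta[~mask] == 0)

    def test_inactive_coefficient_returns_zero_with_warning(self):
        data, _, _ = make_instance(82, n=300, p=2, beta=[0.0, 1.0, 0.0],
                                   alpha=[0.0, 0.0, 0.0])
        fit = fit_mpr_sic(data, schedule=FAST_SCHEDULE)
        assert 2 not in fit.active_beta
        with pytest.warns(UserWarning, match="already"):
            assert delta_bic(data, fit, index=2, component="location") == 0.0

    def test_strong_effect_has_larger_delta_bic_than_weak(self):
        data, _, _ = make_instance(83, n=1000, p=3,
                                   beta=[0.0, 1.0, 0.5, 0.0], alpha=[0.0, 0, 0, 0])
        fit = fit_mpr_sic(data, schedule=FAST_SCHEDULE)
        strong = delta_bic(data, fit, index=1, component="location")
        weak = delta_bic(data, fit, index=2, component="location")
        assert strong > weak > 0
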