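"""Penalized GLM / Cox fitters: closed forms, shrinkage limits, smoothing
selection, and equivalence with independent solvers at λ=0."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from quantindex.models import (
    BinaryOutcome,
    SmoothingConfig,
    SurvivalOutcome,
    fit_penalized_cox,
    fit_penalized_glm,
    fit_unpenalized,
    select_lambda,
)


def _surv(time, event):
    return SurvivalOutcome(list(range(len(time))), np.asarray(time, float),
                           np.asarray(event, float))


def cox_partial_loglik_oracle(beta, X, time, event):
    """Independent textbook Breslow partial log-likelihood (naive loops)."""
    beta = np.atleast_1d(beta)
    eta = X @ beta
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = time >= time[i]
            ll += eta[i] - np.log(np.sum(np.exp(eta[risk])))
    return ll


class TestPenalizedGLM:
    def test_gaussian_lambda0_is_ols(self, rng):
        X = rng.normal(size=(30, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.normal(size=30)
        fit = fit_penalized_glm(X, y, family="gaussian")
        Xa = np.column_stack([np.ones(30), X])
        beta_ols = np.linalg.lstsq(Xa, y, rcond=None)[0]
        np.testing.assert_allclose(
            np.concatenate([[fit.intercept], fit.coef]), beta_ols, atol=1e-10
        )
        assert fit.edf == pytest.approx(4.0)

    def test_intercept_only_logit_closed_form(self):
        y = np.array([1.0, 0, 0, 0] * 5)  # mean 0.25 -> logit = -log 3
        fit = fit_penalized_glm(np.zeros((20, 0)), y, family="binomial")
        assert fit.intercept == pytest.approx(np.log(1 / 3), abs=1e-8)

    def test_infinite_shrinkage_drives_slopes_to_zero(self, rng):
        X = rng.normal(size=(40, 3))
        y = (rng.random(40) < 0.4).astype(float)
        fit = fit_penalized_glm(X, y, penalty=np.eye(3), lam=1e12,
                                family="binomial")
        np.testing.assert_allclose(fit.coef, 0.0, atol=1e-8)
        assert fit.edf == pytest.approx(1.0, abs=1e-6)  # intercept only
        m = y.mean()
        assert fit.intercept == pytest.approx(np.log(m / (1 - m)), abs=1e-6)

    def test_separation_flagged(self):
        x = np.r_[np.zeros(10), np.ones(10)][:, None]
        y = np.r_[np.zeros(10), np.ones(10)]
        fit = fit_penalized_glm(x, y, family="binomial")
        assert not fit.converged
        assert "separation" in fit.message

    def test_singular_at_lambda0_advises_penalty(self, rng):
        X = rng.normal(size=(10, 3))
        X = np.column_stack([X, X[:, 0]])  # exact collinearity
        y = X[:, 0] + rng.normal(size=10)
        with pytest.raises(np.linalg.LinAlgError, match="lambda > 0"):
            fit_penalized_glm(X, y, family="gaussian")

    def test_penalized_score_equation_holds(self, rng):
        """Gradient of the penalized objective vanishes at the optimum."""
        X = rng.normal(size=(50, 4))
        y = (rng.random(50) < 0.5).astype(float)
        S = np.eye(4)
        fit = fit_penalized_glm(X, y, penalty=S, lam=2.5, family="binomial")
        assert fit.grad_norm <= 1e-6

    def test_shrinkage_monotone_in_lambda(self, rng):
        X = rng.normal(size=(60, 4))
        y = (rng.random(60) < 1 / (1 + np.exp(-X[:, 0]))).astype(float)
        S = np.eye(4)
        norms = [
            fit_penalized_glm(X, y, S, lam, family="binomial").coef @
            fit_penalized_glm(X, y, S, lam, family="binomial").coef
            for lam in [0.0, 0.1, 1.0, 10.0, 100.0]
        ]
        assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))


class TestPenalizedCox:
    def test_three_subject_closed_form(self):
        """Events at t=1,2,3 with x=(1,0,1): β̂ = −½·log 2 (u² = ½)."""
        X = np.array([[1.0], [0.0], [1.0]])
        fit = fit_penalized_cox(X, _surv([1, 2, 3], [1, 1, 1]))
        assert fit.coef[0] == pytest.approx(-0.5 * np.log(2), abs=1e-8)

    def test_null_covariate_gives_zero(self):
        X = np.zeros((5, 1))
        fit = fit_penalized_cox(X, _surv([1, 2, 3, 4, 5], [1, 1, 0, 1, 0]))
        assert fit.coef[0] == 0.0

    def test_infinite_shrinkage(self, rng):
        X = rng.normal(size=(30, 2))
        t = rng.exponential(1, 30)
        fit = fit_penalized_cox(X, _surv(t, np.ones(30)), np.eye(2), 1e12)
        np.testing.assert_allclose(fit.coef, 0.0, atol=1e-8)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            fit_penalized_cox(np.ones((3, 1)), _surv([1, 2, 3], [0, 0, 0]))

    def test_rank_invariance_under_time_transform(self, rng):
        """Partial likelihood depends on event-time ranks only."""
        X = rng.normal(size=(40, 2))
        t = rng.exponential(1, 40)
        e = (rng.random(40) < 0.7).astype(float)
        f1 = fit_penalized_cox(X, _surv(t, e))
        f2 = fit_penalized_cox(X, _surv(np.exp(t), e))  # strictly monotone
        np.testing.assert_allclose(f1.coef, f2.coef, atol=1e-8)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-8)

    def test_matches_scipy_optimizer_oracle(self, rng):
        X = rng.normal(size=(25, 2))
        t = rng.exponential(1, 25)
        e = (rng.random(25) < 0.8).astype(float)
        fit = fit_penalized_cox(X, _surv(t, e))
        res = minimize(
            lambda b: -cox_partial_loglik_oracle(b, X, t, e),
            np.zeros(2), method="BFGS", tol=1e-12,
        )
        np.testing.assert_allclose(fit.coef, res.x, atol=1e-6)

    def test_breslow_ties_against_r_convention(self):
        """Tied event times share the full tied risk set (Breslow)."""
        X = np.array([[1.0], [0.0], [1.0], [0.0]])
        t = np.array([1.0, 1.0, 2.0, 3.0])
        e = np.array([1.0, 1.0, 1.0, 0.0])
        fit = fit_penalized_cox(X, _surv(t, e))

        def breslow_ll(b):
            eta = X[:, 0] * b
            r1 = np.log(np.exp(eta).sum())  # both events at t=1: same risk set
            r2 = np.log(np.exp(eta[2:]).sum())
            return eta[0] + eta[1] - 2 * r1 + eta[2] - r2

        res = minimize(lambda b: -breslow_ll(b[0]), [0.0], tol=1e-12)
        assert fit.coef[0] == pytest.approx(res.x[0], abs=1e-6)


class TestSelectLambda:
    def test_single_candidate_returned(self, rng):
        X = rng.normal(size=(30, 3))
        y = (rng.random(30) < 0.5).astype(float)
        lam, fit = select_lambda(
            lambda l: fit_penalized_glm(X, y, np.eye(3), l, family="binomial"),
            SmoothingConfig(lambda_grid=[3.0]),
        )
        assert lam == 3.0

    def test_tie_breaks_toward_larger_lambda(self):
        """Two λ with identical criterion: the smoother fit wins."""
        from quantindex.models import PenalizedFit

        def fake_fitter(lam):
            return PenalizedFit(
                coef=np.zeros(1), intercept=0.0, lam=lam, edf=1.0,
                converged=True, loglik=-1.0, criterion_value=5.0,
                family="binomial", n_obs=10,
            )

        lam, _ = select_lambda(fake_fitter, SmoothingConfig(lambda_grid=[0.1, 10.0]))
        assert lam == 10.0

    def test_noise_gets_smoothed_harder_than_signal(self, rng):
        """Average selected λ is larger for pure-noise than strong-signal
        responses on the same design (15 paired replicates)."""
        S = np.eye(5)
        noise_lams, signal_lams = [], []
        for _ in range(15):
            X = rng.normal(size=(40, 5))
            y_noise = rng.normal(size=40)
            y_signal = X @ np.full(5, 2.0) + 0.1 * rng.normal(size=40)
            cfg = SmoothingConfig(lambda_grid=np.logspace(-3, 3, 10))
            ln, _ = select_lambda(
                lambda l: fit_penalized_glm(X, y_noise, S, l, family="gaussian"), cfg)
            ls, _ = select_lambda(
                lambda l: fit_penalized_glm(X, y_signal, S, l, family="gaussian"), cfg)
            noise_lams.append(np.log(ln))
            signal_lams.append(np.log(ls))
        assert np.mean(noise_lams) >= np.mean(signal_lams)

    def test_all_nonconverged_raises(self):
        from quantindex.models import PenalizedFit

        def bad_fitter(lam):
            return PenalizedFit(
                coef=np.zeros(1), intercept=None, lam=lam, edf=1.0,
                converged=False, loglik=np.nan, criterion_value=np.nan,
                family="cox", n_obs=5,
            )

        with pytest.raises(RuntimeError):
            select_lambda(bad_fitter, SmoothingConfig(lambda_grid=[1.0]))


class TestUnpenalized:
    def test_two_by_two_odds_ratio(self):
        """Counts (20,30;10,40): OR = 20·40/(30·10) = 8/3."""
        x = np.r_[np.ones(50), np.zeros(50)][:, None]
        y = np.r_[np.ones(20), np.zeros(30), np.ones(10), np.zeros(40)]
        summ = fit_unpenalized(x, BinaryOutcome(list(range(100)), y), "binomial")
        assert summ["effect"].iloc[0] == pytest.approx(8 / 3, rel=1e-6)
        assert summ["effect_label"].iloc[0] == "OR"
        assert summ["ci_low"].iloc[0] < 8 / 3 < summ["ci_high"].iloc[0]

    def test_zero_covariate_hazard_ratio_one(self):
        summ = fit_unpenalized(
            np.zeros((5, 1)), _surv([1, 2, 3, 4, 5], [1, 1, 1, 0, 0]), "cox")
        assert summ["effect"].iloc[0] == pytest.approx(1.0)

    def test_exact_gaussian_slope(self):
        x = np.arange(10.0)[:, None]
        summ = fit_unpenalized(x, 2.0 * x[:, 0], "gaussian")
        assert summ["coef"].iloc[0] == pytest.approx(2.0, abs=1e-10)

    def test_wald_se_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        X = rng.normal(size=(80, 2))
        y = (rng.random(80) < 1 / (1 + np.exp(-X[:, 0]))).astype(float)
        summ = fit_unpenalized(X, BinaryOutcome(list(range(80)), y), "binomial")
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(summ["coef"], ref.params[1:], atol=1e-6)
        np.testing.assert_allclose(summ["se"], ref.bse[1:], atol=1e-5)
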