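"""Two-part (logistic + Gamma/GenGamma), Tobit and Poisson fitters."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.special import expit

from tweediecost import core
from tweediecost.competitors import (
    fit_logistic_part,
    fit_poisson,
    fit_positive_part,
    fit_tobit,
    fit_two_part,
    two_part_combine,
)
from tweediecost.glm import fit_tweedie_glm
from tweediecost.models import simulate_outcomes


class TestLogisticPart:
    def test_balanced_independent_outcome_gives_null_coefficients(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4000, 2))
        y = np.tile([0.0, 1.0], 2000)  # balanced, independent of X
        fit = fit_logistic_part(X, y)
        assert np.all(np.abs(fit.coef.to_numpy()) < 0.12)

    def test_recovers_simulated_coefficients(self):
        rng = np.random.default_rng(1)
        n = 5000
        X = rng.normal(size=(n, 2))
        beta = np.array([0.5, 0.8, -0.5])
        pos = rng.random(n) < expit(beta[0] + X @ beta[1:])
        fit = fit_logistic_part(X, pos.astype(float) * 3.0)
        se = np.sqrt(np.diag(fit.vcov))
        assert np.all(np.abs(fit.coef.to_numpy() - beta) < 1.96 * se)

    def test_fitted_probabilities_average_to_positive_fraction(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(2000, 2))
        y = (rng.random(2000) < 0.3).astype(float)
        fit = fit_logistic_part(X, y)
        assert fit.predict_mean(X).mean() == pytest.approx(y.mean(), abs=1e-6)

    @pytest.mark.parametrize("value,label", [(1.0, "zero"), (0.0, "positive")])
    def test_single_class_raises_naming_the_missing_class(self, value, label):
        with pytest.raises(ValueError, match=label):
            fit_logistic_part(np.random.default_rng(0).normal(size=(50, 1)),
                              np.full(50, value))


class TestPositivePart:
    def test_gamma_intercept_only_mean_is_exact(self, gamma_glm_data):
        y = gamma_glm_data["y"][:1000]
        fit = fit_positive_part(np.empty((1000, 0)), y, family="gamma")
        assert np.exp(fit.coef.iloc[0]) == pytest.approx(y.mean(), rel=1e-8)

    def test_gamma_shape_recovery(self, gamma_glm_data):
        d = gamma_glm_data
        fit = fit_positive_part(d["X"], d["y"], family="gamma")
        assert fit.aux["shape"] == pytest.approx(d["shape"], rel=0.1)

    def test_gengamma_nests_gamma(self, gamma_glm_data):
        d = gamma_glm_data
        g = fit_positive_part(d["X"], d["y"], family="gamma")
        gg = fit_positive_part(d["X"], d["y"], family="gengamma")
        assert gg.loglik >= g.loglik - 1e-4
        # Gamma is the q = sigma special case of the generalized Gamma
        assert gg.aux["q"] == pytest.approx(gg.aux["sigma"], abs=0.15)

    def test_gengamma_nests_lognormal_shape(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(3000, 1))
        y = np.exp(1.0 + 0.5 * X[:, 0] + 0.4 * rng.standard_normal(3000))
        g = fit_positive_part(X, y, family="gamma")
        gg = fit_positive_part(X, y, family="gengamma")
        assert gg.loglik >= g.loglik - 1e-4
        assert gg.aux["q"] < 0.35  # near the log-normal corner

    def test_rejects_nonpositive_outcomes(self):
        with pytest.raises(ValueError, match="positive"):
            fit_positive_part(np.ones((5, 1)), np.array([1.0, 0.0, 2.0, 3.0, 4.0]))


class TestTwoPart:
    def test_combined_aic_is_sum_of_parts(self, gamma_glm_data):
        rng = np.random.default_rng(3)
        d = gamma_glm_data
        y = d["y"].copy()
        y[rng.random(len(y)) < 0.3] = 0.0
        tp = fit_two_part(d["X"], y, family="gamma")
        assert tp.combined_aic == pytest.approx(
            tp.binary_part.aic + tp.positive_part.aic
        )

    def test_covariate_mismatch_raises(self, gamma_glm_data):
        d = gamma_glm_data
        y = d["y"].copy()
        y[::3] = 0.0
        binary = fit_logistic_part(d["X"], y)
        positive = fit_positive_part(d["X"][y > 0, :1], y[y > 0], family="gamma")
        with pytest.raises(ValueError, match="mismatch"):
            two_part_combine(binary, positive)

    def test_expected_value_matches_two_stage_simulation(self, gamma_glm_data):
        rng = np.random.default_rng(4)
        d = gamma_glm_data
        y = d["y"].copy()
        y[rng.random(len(y)) < expit(-0.5 + d["X"][:, 0])] = 0.0
        tp = fit_two_part(d["X"], y, family="gamma")
        Xq = d["X"][:5]
        draws = np.stack(
            [simulate_outcomes(tp, Xq, np.random.default_rng(s)) for s in range(4000)]
        )
        mc = draws.mean(axis=0)
        se = draws.std(axis=0) / np.sqrt(len(draws))
        assert np.all(np.abs(tp.predict_mean(Xq) - mc) < 4 * se + 1e-9)


class TestTobit:
    def test_without_censoring_equals_least_squares(self, gamma_glm_data):
        d = gamma_glm_data
        with pytest.warns(UserWarning, match="censored"):
            fit = fit_tobit(d["X"], d["y"])
        Xc = sm.add_constant(d["X"])
        ols = np.linalg.lstsq(Xc, d["y"], rcond=None)[0]
        assert fit.coef.to_numpy() == pytest.approx(ols, rel=1e-4, abs=1e-4)

    def test_recovers_censored_normal_parameters(self):
        rng = np.random.default_rng(6)
        n = 5000
        X = rng.normal(size=(n, 2))
        beta = np.array([0.8, 2.0, -1.0])
        sigma = 1.5
        y = np.maximum(0.0, beta[0] + X @ beta[1:] + sigma * rng.standard_normal(n))
        assert 0.2 < (y == 0).mean() < 0.4
        fit = fit_tobit(X, y)
        se = np.sqrt(np.diag(fit.vcov))
        assert np.all(np.abs(fit.coef.to_numpy() - beta) < 1.96 * se)
        assert fit.aux["sigma"] == pytest.approx(sigma, rel=0.05)

    def test_sigma_is_local_maximum(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(2000, 1))
        y = np.maximum(0.0, 1.0 + X[:, 0] + rng.standard_normal(2000))
        fit = fit_tobit(X, y)
        from tweediecost.competitors import _tobit_negll

        Xc = sm.add_constant(X)
        theta = fit.meta["theta"]
        base = _tobit_negll(theta, Xc, y, y == 0)
        for f in (0.9, 1.1):
            t2 = theta.copy()
            t2[-1] = np.log(fit.aux["sigma"] * f)
            assert _tobit_negll(t2, Xc, y, y == 0) > base


class TestPoisson:
    def test_integer_outcome_matches_textbook_regression(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(2000, 2))
        y = rng.poisson(np.exp(0.5 + 0.3 * X[:, 0])).astype(float)
        fit = fit_poisson(X, y)
        ref = sm.GLM(y, sm.add_constant(X), family=sm.families.Poisson()).fit()
        assert fit.coef.to_numpy() == pytest.approx(np.asarray(ref.params), abs=1e-6)
        assert fit.loglik == pytest.approx(ref.llf)

    def test_fitted_means_average_to_outcome_mean(self, tweedie_glm_data):
        d = tweedie_glm_data
        fit = fit_poisson(d["X"], d["y"])
        assert fit.predict_mean(d["X"]).mean() == pytest.approx(d["y"].mean(), rel=1e-6)

    def test_overdispersed_costs_favour_tweedie_over_poisson(self, tweedie_glm_data):
        d = tweedie_glm_data
        po = fit_poisson(d["X"], d["y"])
        tw = fit_tweedie_glm(d["X"], d["y"], p_init=1.5)
        assert po.aic > tw.aic


def test_all_families_share_the_aic_identity(gamma_glm_data):
    d = gamma_glm_data
    rng = np.random.default_rng(10)
    y = d["y"].copy()
    y[rng.random(len(y)) < 0.25] = 0.0
    models = [
        fit_tweedie_glm(d["X"], y, p_init=1.5),
        fit_two_part(d["X"], y, family="gamma").positive_part,
        fit_logistic_part(d["X"], y),
        fit_tobit(d["X"], y),
        fit_poisson(d["X"], y),
    ]
    for m in models:
        assert m.aic == pytest.approx(-2 * m.loglik + 2 * m.n_params)
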