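"""Comparison models: two-part (logistic + Gamma / generalized Gamma),
Tobit, and Poisson.

All fitters return the common :class:`~tweediecost.models.FittedModel`
contract so AIC and predictions are directly comparable with the Tweedie GLM.

Conventions worth noting:

* The two-part combined AIC is the sum of the parts' AICs (the parts share
  no parameters and the joint likelihood factorizes).
* Poisson is fitted to dollar costs, which are not integers; its
  log-likelihood uses the continuous extension with ``log Gamma(y+1)`` in
  place of the factorial, the only extension consistent with the GLM
  deviance.  On integer outcomes it coincides with the textbook Poisson fit.
* The Tobit model is the type-I *censored* normal: a latent normal outcome
  observed only when positive, contributing ``Phi(-x'b/sigma)`` for zeros
  and a normal density term otherwise.
* The generalized Gamma uses the log-location-scale (Prentice)
  parameterization with covariates in the location, scale ``sigma`` and
  shape ``q``: ``q=1`` is Weibull, ``q=sigma`` is Gamma, ``q -> 0`` is
  log-normal.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_hess

from .models import FittedModel, TwoPartModel, design_matrix, _check_rank

__all__ = [
    "fit_logistic_part",
    "fit_positive_part",
    "two_part_combine",
    "fit_two_part",
    "fit_tobit",
    "fit_poisson",
]


def _glm_fit(Xc, y, family):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.GLM(y, Xc, family=family).fit(maxiter=200, tol=1e-9)


def _safe_inv_hess(negll, theta):
    """Observed-information covariance via a numerical Hessian.

    Falls back to a pseudo-inverse (with a warning flag) when the Hessian is
    not positive definite at the reported optimum.
    """
    with np.errstate(over="ignore", invalid="ignore"):
        H = approx_hess(theta, negll)
    H = 0.5 * (H + H.T)
    try:
        cov = np.linalg.inv(H)
        if np.any(np.diag(cov) <= 0):
            raise np.linalg.LinAlgError
        flag = False
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
        flag = True
    return 0.5 * (cov + cov.T), flag


def fit_logistic_part(X, y) -> FittedModel:
    """Logistic regression on the indicator 1{y > 0}."""
    Xc, names = design_matrix(X)
    y = np.asarray(y, dtype=float)
    ind = (y > 0).astype(float)
    if ind.all():
        raise ValueError("degenerate outcome: every observation is positive (no zero class)")
    if not ind.any():
        raise ValueError("degenerate outcome: every observation is zero (no positive class)")
    _check_rank(Xc, names)
    res = _glm_fit(Xc, ind, sm.families.Binomial())
    k = len(names)
    # Clipped log-likelihood stays finite under (quasi-)complete separation,
    # where the unpenalized MLE diverges and fitted probabilities pin to 0/1;
    # the near-zero deviance it reports is the honest description of that fit.
    p_hat = np.clip(np.asarray(res.mu), 1e-10, 1.0 - 1e-10)
    ll = float(np.sum(ind * np.log(p_hat) + (1.0 - ind) * np.log(1.0 - p_hat)))
    separated = bool(np.any((np.asarray(res.mu) < 1e-10) | (np.asarray(res.mu) > 1 - 1e-10)))
    vcov = pd.DataFrame(np.asarray(res.cov_params()), index=names, columns=names)
    return FittedModel(
        family="logistic",
        link="logit",
        coef=pd.Series(np.asarray(res.params), index=names),
        aux={},
        loglik=ll,
        n_params=k,
        aic=-2 * ll + 2 * k,
        vcov=vcov,
        n_obs=len(y),
        meta={"full_names": names, "full_vcov": vcov, "separation": separated},
    )


def _gamma_shape_loglik(k, y, mu):
    return float(
        np.sum(k * np.log(k / mu) + (k - 1.0) * np.log(y) - k * y / mu - gammaln(k))
    )


def _fit_gamma(Xc, names, y_pos) -> FittedModel:
    res = _glm_fit(Xc, y_pos, sm.families.Gamma(link=sm.families.links.Log()))
    mu = res.mu
    opt = minimize_scalar(
        lambda lk: -_gamma_shape_loglik(np.exp(lk), y_pos, mu),
        bounds=(-10.0, 10.0),
        method="bounded",
        options={"xatol": 1e-6},
    )
    shape = float(np.exp(opt.x))
    ll = -float(opt.fun)
    k = len(names) + 1
    # MLE-based dispersion 1/shape replaces statsmodels' moment scale.
    vcov = np.asarray(res.cov_params()) * ((1.0 / shape) / res.scale)
    vcov = pd.DataFrame(vcov, index=names, columns=names)
    return FittedModel(
        family="gamma",
        link="log",
        coef=pd.Series(np.asarray(res.params), index=names),
        aux={"shape": shape},
        loglik=ll,
        n_params=k,
        aic=-2 * ll + 2 * k,
        vcov=vcov,
        n_obs=len(y_pos),
        meta={"full_names": names, "full_vcov": vcov},
    )


def gengamma_loglik(theta, Xc, log_y):
    """Prentice generalized-Gamma log-likelihood; theta = (coef, log sigma, q)."""
    k = Xc.shape[1]
    eta = Xc @ theta[:k]
    sigma = np.exp(theta[k])
    q = theta[k + 1]
    w = (log_y - eta) / sigma
    if abs(q) < 1e-5:  # log-normal limit
        lp = -0.5 * w ** 2 - 0.5 * np.log(2 * np.pi)
    else:
        a = q ** -2.0
        qw = np.clip(q * w, -700.0, 700.0)
        lp = np.log(abs(q)) + a * np.log(a) - gammaln(a) + a * (qw - np.exp(qw))
    return float(np.sum(lp - np.log(sigma) - log_y))


def _fit_gengamma(Xc, names, y_pos, start=None) -> FittedModel:
    log_y = np.log(y_pos)
    if start is None:
        # log-normal starting values: OLS on log costs.
        coef0, *_ = np.linalg.lstsq(Xc, log_y, rcond=None)
        resid = log_y - Xc @ coef0
        sigma0 = max(np.std(resid), 1e-3)
        start_q = [1.0, 0.5]
        starts = [np.concatenate([coef0, [np.log(sigma0), q0]]) for q0 in start_q]
    else:
        starts = [np.asarray(start, dtype=float)]

    def neg(theta):
        return -gengamma_loglik(theta, Xc, log_y)

    kx = Xc.shape[1]
    # q is kept positive (and away from 0) so the fitted mean exists; the
    # near-zero boundary is numerically indistinguishable from log-normal.
    bounds = [(None, None)] * kx + [(-7.0, 7.0), (0.03, 10.0)]

    best = None
    for theta0 in starts:
        with np.errstate(over="ignore", invalid="ignore"):
            res = minimize(neg, theta0, method="L-BFGS-B", bounds=bounds,
                           options={"maxiter": 500})
        if best is None or (res.success and res.fun < best.fun) or (
            not best.success and res.fun < best.fun
        ):
            best = res
        if best.success:
            break
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("generalized-Gamma MLE failed to converge: " + str(best))

    theta = best.x
    ll = -float(best.fun)
    nparams = kx + 2
    full_names = names + ["log_sigma", "q"]
    cov, flag = _safe_inv_hess(neg, theta)
    full_vcov = pd.DataFrame(cov, index=full_names, columns=full_names)
    return FittedModel(
        family="gengamma",
        link="log",
        coef=pd.Series(theta[:kx], index=names),
        aux={"sigma": float(np.exp(theta[kx])), "q": float(theta[kx + 1])},
        loglik=ll,
        n_params=nparams,
        aic=-2 * ll + 2 * nparams,
        vcov=full_vcov.iloc[:kx, :kx],
        n_obs=len(y_pos),
        meta={
            "full_names": full_names,
            "full_vcov": full_vcov,
            "theta": theta,
            "vcov_pinv_fallback": flag,
            "optimizer": {"success": bool(best.success), "message": str(best.message)},
        },
    )


def fit_positive_part(X, y_pos, family: str = "gamma", start=None) -> FittedModel:
    """Continuous model for strictly positive costs (log link).

    ``family`` is ``"gamma"`` (log-link Gamma GLM, shape by MLE given the
    fitted means) or ``"gengamma"`` (three-parameter generalized Gamma MLE
    with covariates in the log-scale location).
    """
    Xc, names = design_matrix(X)
    y_pos = np.asarray(y_pos, dtype=float)
    if np.any(y_pos <= 0):
        raise ValueError("positive-part outcome must be strictly positive")
    _check_rank(Xc, names)
    if family == "gamma":
        return _fit_gamma(Xc, names, y_pos)
    if family == "gengamma":
        return _fit_gengamma(Xc, names, y_pos, start=start)
    raise ValueError(f"unknown positive-part family {family!r}")


def two_part_combine(binary: FittedModel, positive: FittedModel) -> TwoPartModel:
    """Combine the logistic and positive parts; AIC adds, E[y|x] multiplies."""
    return TwoPartModel(binary_part=binary, positive_part=positive)


def fit_two_part(X, y, family: str = "gamma", start=None) -> TwoPartModel:
    """Fit both parts on one dataset (positive part on the y > 0 rows)."""
    y = np.asarray(y, dtype=float)
    binary = fit_logistic_part(X, y)
    pos_rows = y > 0
    X_arr = X.loc[pos_rows] if isinstance(X, pd.DataFrame) else np.asarray(X)[pos_rows]
    positive = fit_positive_part(X_arr, y[pos_rows], family=family, start=start)
    return two_part_combine(binary, positive)


def _tobit_negll(theta, Xc, y, zero):
    k = Xc.shape[1]
    beta, log_sigma = theta[:k], theta[k]
    sigma = np.exp(log_sigma)
    eta = Xc @ beta
    ll = 0.0
    if zero.any():
        ll += norm.logcdf(-eta[zero] / sigma).sum()
    pos = ~zero
    if pos.any():
        r = (y[pos] - eta[pos]) / sigma
        ll += np.sum(-0.5 * r ** 2 - 0.5 * np.log(2 * np.pi) - log_sigma)
    return -float(ll)


def fit_tobit(X, y) -> FittedModel:
    """Type-I Tobit MLE: latent normal outcome left-censored at zero."""
    Xc, names = design_matrix(X)
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("y must be non-negative")
    _check_rank(Xc, names)
    zero = y == 0
    if zero.all():
        raise ValueError("all observations are zero: Tobit likelihood is degenerate")
    if not zero.any():
        warnings.warn(
            "no censored observations: Tobit reduces to plain normal MLE",
            stacklevel=2,
        )

    coef0, *_ = np.linalg.lstsq(Xc, y, rcond=None)
    sigma0 = max(np.std(y - Xc @ coef0), 1e-6)
    theta0 = np.concatenate([coef0, [np.log(sigma0)]])
    with np.errstate(over="ignore", invalid="ignore"):
        res = minimize(
            _tobit_negll, theta0, args=(Xc, y, zero), method="BFGS",
            options={"maxiter": 500, "gtol": 1e-6},
        )
    theta = res.x
    kx = len(names)
    ll = -float(res.fun)
    nparams = kx + 1
    full_names = names + ["log_sigma"]
    cov, flag = _safe_inv_hess(lambda t: _tobit_negll(t, Xc, y, zero), theta)
    full_vcov = pd.DataFrame(cov, index=full_names, columns=full_names)
    return FittedModel(
        family="tobit",
        link="identity",
        coef=pd.Series(theta[:kx], index=names),
        aux={"sigma": float(np.exp(theta[kx]))},
        loglik=ll,
        n_params=nparams,
        aic=-2 * ll + 2 * nparams,
        vcov=full_vcov.iloc[:kx, :kx],
        n_obs=len(y),
        meta={
            "full_names": full_names,
            "full_vcov": full_vcov,
            "theta": theta,
            "vcov_pinv_fallback": flag,
            "n_censored": int(zero.sum()),
        },
    )


def fit_poisson(X, y) -> FittedModel:
    """Log-link Poisson GLM with the continuous log-likelihood extension."""
    Xc, names = design_matrix(X)
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("y must be non-negative")
    _check_rank(Xc, names)
    res = _glm_fit(Xc, y, sm.families.Poisson())
    mu = res.mu
    ll = float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))
    k = len(names)
    vcov = pd.DataFrame(np.asarray(res.cov_params()), index=names, columns=names)
    return FittedModel(
        family="poisson",
        link="log",
        coef=pd.Series(np.asarray(res.params), index=names),
        aux={},
        loglik=ll,
        n_params=k,
        aic=-2 * ll + 2 * k,
        vcov=vcov,
        n_obs=len(y),
        meta={"full_names": names, "full_vcov": vcov},
    )
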