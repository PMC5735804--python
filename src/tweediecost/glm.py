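"""Tweedie GLM with log link, fitted by profile likelihood.

Estimation follows the two-step scheme that is standard for this family:

1. For a candidate power ``p``, the regression coefficients solve the
   quasi-likelihood score equations of a GLM with variance function
   ``mu**p`` and log link -- they do not depend on the dispersion ``phi``.
   Given the fitted means, ``phi`` is then estimated by maximizing the exact
   compound Poisson-Gamma log-likelihood in one dimension.  The resulting
   maximized value is the profile log-likelihood at ``p``.
2. ``p`` itself is chosen by maximizing that profile over a bounded interval
   (coarse grid, then Brent refinement), after which the coefficients,
   dispersion and covariance are re-evaluated at the optimum.

AIC counts ``phi`` and ``p`` as estimated parameters (``k = n_coef + 2``)
because both are maximized over; this convention is configurable via
``count_aux``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from . import core
from .models import FittedModel, design_matrix, _check_rank

__all__ = ["profile_loglik", "fit_tweedie_glm", "predict_mean"]

P_BOUNDS_DEFAULT = (1.05, 1.95)
PHI_BOUNDS = (1e-4, 1e4)


class _SeriesWorkspace:
    """Caches the m-indexed gammaln table of the Tweedie series for fixed p.

    The log of the m-th series term is ``m*c_i - gammaln(m+1) -
    gammaln(m*alpha)``; only the slope ``c_i`` depends on (mu_i, phi), so a
    single table ``G[m] = gammaln(m+1) + gammaln(m*alpha)`` serves every
    likelihood evaluation during the 1-D dispersion search.
    """

    def __init__(self, y: np.ndarray):
        self.y = np.asarray(y, dtype=float)
        self.pos = self.y > 0
        self.z = self.y[self.pos]
        self.log_z = np.log(self.z)
        self._p = None
        self._table = None

    def _table_for(self, p: float, m_max: int) -> np.ndarray:
        alpha = (2.0 - p) / (p - 1.0)
        if self._p != p or self._table is None or len(self._table) <= m_max:
            m = np.arange(0, int(1.3 * m_max) + 16, dtype=float)
            with np.errstate(invalid="ignore"):
                self._table = gammaln(m + 1.0) + gammaln(m * alpha)
            self._p = p
        return self._table

    def loglik(self, mu: np.ndarray, phi: float, p: float) -> float:
        """Exact Tweedie log-likelihood at per-observation means ``mu``."""
        alpha = (2.0 - p) / (p - 1.0)
        lam = mu ** (2.0 - p) / (phi * (2.0 - p))
        total = -lam[~self.pos].sum() if (~self.pos).any() else 0.0

        if self.z.size == 0:
            return float(total)

        mu_pos = mu[self.pos]
        lam_pos = lam[self.pos]
        log_beta = np.log(phi * (p - 1.0)) + (p - 1.0) * np.log(mu_pos)
        c = np.log(lam_pos) + alpha * (self.log_z - log_beta)
        m_star = np.exp((c - alpha * np.log(alpha)) / (1.0 + alpha))
        m_lo, m_hi, stride = core._window_and_stride(m_star, alpha)

        table = self._table_for(p, int(m_hi.max()))
        log_series = core._strided_logsum(c, m_lo, m_hi, stride, table)

        total += (
            log_series - lam_pos - self.log_z - self.z * np.exp(-log_beta)
        ).sum()
        return float(total)


def _fit_coefs(Xc, y, p, start=None):
    """Quasi-likelihood (IRLS) coefficients for fixed p; phi-free."""
    fam = sm.families.Tweedie(var_power=p, link=sm.families.links.Log())
    model = sm.GLM(y, Xc, family=fam)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(start_params=start, maxiter=100, tol=1e-8)
    return res


def _opt_phi(ws: _SeriesWorkspace, mu, p, phi0=None, xatol=4e-3):
    """Maximize the exact likelihood over phi (1-D search in log phi)."""
    lo, hi = np.log(PHI_BOUNDS[0]), np.log(PHI_BOUNDS[1])
    if phi0 is None:
        # Pearson-type moment estimate seeds the bracket.
        phi0 = float(np.mean((ws.y - mu) ** 2 / mu ** p))
    center = np.clip(np.log(max(phi0, PHI_BOUNDS[0])), lo, hi)

    def neg(lphi):
        return -ws.loglik(mu, float(np.exp(lphi)), p)

    a, b = max(lo, center - 2.5), min(hi, center + 2.5)
    res = minimize_scalar(neg, bounds=(a, b), method="bounded", options={"xatol": xatol})
    # Re-run over the full bounds if the warm window clipped the optimum.
    if (res.x - a < 2 * xatol and a > lo + 1e-9) or (b - res.x < 2 * xatol and b < hi - 1e-9):
        res = minimize_scalar(neg, bounds=(lo, hi), method="bounded", options={"xatol": xatol})
    return float(np.exp(res.x)), -float(res.fun)


def _validate_xy(X, y):
    Xc, names = design_matrix(X)
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) != len(Xc):
        raise ValueError("y must be a vector matching the design matrix rows")
    if np.any(y < 0) or not np.all(np.isfinite(y)):
        raise ValueError("y must be non-negative and finite")
    if not np.any(y > 0):
        raise ValueError("no positive outcomes: cannot fit a Tweedie GLM to all-zero y")
    _check_rank(Xc, names)
    return Xc, names, y


def profile_loglik(p: float, X, y, _ws=None, _start=None):
    """Profile log-likelihood of the Tweedie GLM at fixed power ``p``.

    Returns ``(loglik, phi_hat, coef)``: coefficients from the
    phi-free quasi-likelihood fit, the exact-likelihood-maximizing
    dispersion given those means, and the maximized log-likelihood.
    """
    Xc, names, y = _validate_xy(X, y)
    ws = _ws if _ws is not None else _SeriesWorkspace(y)
    res = _fit_coefs(Xc, y, p, start=_start)
    mu = res.mu
    phi_hat, ll = _opt_phi(ws, mu, p)
    return ll, phi_hat, res.params


def fit_tweedie_glm(
    X,
    y,
    p_bounds=P_BOUNDS_DEFAULT,
    n_grid: int = 10,
    p_tol: float = 1e-3,
    p_init: float = None,
    count_aux: int = 2,
) -> FittedModel:
    """Fit the log-link Tweedie GLM, estimating (p, phi) by profile likelihood.

    ``p`` is maximized over ``p_bounds`` by a coarse grid followed by bounded
    Brent refinement to ``p_tol``.  Passing ``p_init`` replaces the grid with
    a narrow bracket around it (used to warm-start cross-validation refits).
    ``count_aux`` is the number of auxiliary parameters charged to the AIC on
    top of the coefficients (default 2: phi and p).
    """
    Xc, names, y = _validate_xy(X, y)
    ws = _SeriesWorkspace(y)
    lo, hi = p_bounds
    cache = {}

    start = None

    def profile(p):
        nonlocal start
        p = float(p)
        if p not in cache:
            res = _fit_coefs(Xc, y, p, start=start)
            start = res.params
            phi_hat, ll = _opt_phi(ws, res.mu, p)
            cache[p] = (ll, phi_hat, res)
        return cache[p]

    if p_init is not None:
        # warm start (e.g. cross-validation refits): narrow bracket, and no
        # need to localize p much more finely than the profile curvature
        a, b = max(lo, p_init - 0.1), min(hi, p_init + 0.1)
        xatol = max(p_tol, 3e-3)
    else:
        grid = np.linspace(lo, hi, n_grid)
        lls = [profile(p)[0] for p in grid]
        i = int(np.argmax(lls))
        a = grid[max(0, i - 1)]
        b = grid[min(len(grid) - 1, i + 1)]
        xatol = p_tol

    opt = minimize_scalar(
        lambda p: -profile(p)[0], bounds=(a, b), method="bounded", options={"xatol": xatol}
    )
    # bounded Brent never evaluates the endpoints; when the profile is
    # monotone the maximum sits exactly on a bound
    p_hat = max((float(p) for p in (opt.x, a, b)), key=lambda p: profile(p)[0])
    ll, phi_hat, res = profile(p_hat)

    at_bound = min(p_hat - lo, hi - p_hat) < 5 * p_tol
    k = len(names) + count_aux
    aic = -2.0 * ll + 2.0 * k

    # Wald covariance of the coefficients: phi_hat * (X' W X)^-1 with the
    # quasi-likelihood weights; statsmodels' cov_params is scale*(X'WX)^-1.
    vcov = np.asarray(res.cov_params()) * (phi_hat / res.scale)

    return FittedModel(
        family="tweedie",
        link="log",
        coef=pd.Series(np.asarray(res.params), index=names),
        aux={"phi": phi_hat, "p": p_hat},
        loglik=ll,
        n_params=k,
        aic=aic,
        vcov=pd.DataFrame(vcov, index=names, columns=names),
        n_obs=len(y),
        meta={
            "p_bounds": tuple(p_bounds),
            "p_at_bound": bool(at_bound),
            "full_names": names,
            "full_vcov": pd.DataFrame(vcov, index=names, columns=names),
        },
    )


def predict_mean(model: FittedModel, X) -> np.ndarray:
    """exp(X beta) for the log-link Tweedie GLM (delegates to the model)."""
    return model.predict_mean(X)


def tweedie_loglik(y, mu, phi, p) -> float:
    """Exact Tweedie log-likelihood (convenience wrapper over the kernel)."""
    return float(np.sum(core.log_density_glm(np.asarray(y, float), mu, phi, p)))
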