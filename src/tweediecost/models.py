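"""Shared fitted-model containers and family dispatch.

Every regression model in the package -- Tweedie, the two two-part model
parts (logistic, Gamma/generalized Gamma), Tobit and Poisson -- is reported
through the same :class:`FittedModel` contract: named coefficients, auxiliary
distribution parameters, the exact log-likelihood, a parameter count, AIC and
a coefficient covariance.  Two-part models pair a binary and a positive-part
:class:`FittedModel` in :class:`TwoPartModel`.

The mean-prediction and outcome-simulation dispatch for all families lives
here so that evaluation code (cross-validation, quantile diagnostics) treats
every model identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, gammaln
from scipy.stats import norm

__all__ = ["FittedModel", "TwoPartModel", "design_matrix", "predict_mean", "simulate_outcomes"]

INTERCEPT = "const"


def design_matrix(X, add_intercept: bool = True):
    """Coerce ``X`` to a float matrix with a leading intercept column.

    Returns ``(matrix, names)`` where names include :data:`INTERCEPT` first.
    Accepts a 2-D array, DataFrame, or anything array-like; column names are
    taken from the DataFrame or default to ``x1..xk``.
    """
    if isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 1:
            arr = arr[:, None]
        names = [f"x{j + 1}" for j in range(arr.shape[1])]
    if not np.all(np.isfinite(arr)):
        raise ValueError("design matrix contains non-finite values")
    if add_intercept:
        arr = np.column_stack([np.ones(len(arr)), arr])
        names = [INTERCEPT] + names
    return arr, names


def _check_rank(Xc, names):
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError(f"design matrix is rank deficient (columns {names})")


@dataclass
class FittedModel:
    """A fitted regression model in the common comparison contract.

    ``coef`` is indexed by covariate name with the intercept first.  ``aux``
    holds distribution parameters that are not regression coefficients
    (``phi``/``p`` for Tweedie, ``shape`` for Gamma, ``sigma``/``q`` for the
    generalized Gamma, ``sigma`` for Tobit).  ``vcov`` covers the regression
    coefficients; the covariance of the full parameter vector (used for
    delta-method standard errors involving auxiliary parameters) is stored in
    ``meta['full_vcov']`` with names ``meta['full_names']``.
    """

    family: str
    link: str
    coef: pd.Series
    aux: dict
    loglik: float
    n_params: int
    aic: float
    vcov: pd.DataFrame
    n_obs: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        expected = -2.0 * self.loglik + 2.0 * self.n_params
        if np.isfinite(self.loglik) and abs(self.aic - expected) > 1e-8 * max(1.0, abs(expected)):
            raise ValueError("aic does not equal -2*loglik + 2*n_params")

    def linear_predictor(self, X) -> np.ndarray:
        Xc, names = design_matrix(X)
        if Xc.shape[1] != len(self.coef):
            raise ValueError(
                f"design matrix has {Xc.shape[1] - 1} covariates, model expects {len(self.coef) - 1}"
            )
        return Xc @ self.coef.to_numpy()

    def predict_mean(self, X) -> np.ndarray:
        return predict_mean(self, X)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "link": self.link,
            "coef": {k: float(v) for k, v in self.coef.items()},
            "aux": {k: float(v) for k, v in self.aux.items()},
            "loglik": float(self.loglik),
            "n_params": int(self.n_params),
            "aic": float(self.aic),
            "n_obs": int(self.n_obs),
        }


@dataclass
class TwoPartModel:
    """Logistic zero/positive part combined with a positive-cost regression.

    The combined AIC (and log-likelihood) is the sum over the two parts: the
    joint density factorizes as Pr(y>0)^{1{y>0}} Pr(y=0)^{1{y=0}} * f(y|y>0),
    and the two parts share no parameters.
    """

    binary_part: FittedModel
    positive_part: FittedModel
    combined_aic: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.binary_part.family != "logistic":
            raise ValueError("binary part must be a logistic model")
        if list(self.binary_part.coef.index) != list(self.positive_part.coef.index):
            raise ValueError(
                "covariate mismatch between two-part components: "
                f"{list(self.binary_part.coef.index)} vs {list(self.positive_part.coef.index)}"
            )
        self.combined_aic = self.binary_part.aic + self.positive_part.aic

    @property
    def family(self) -> str:
        return f"twopart_{self.positive_part.family}"

    @property
    def loglik(self) -> float:
        return self.binary_part.loglik + self.positive_part.loglik

    @property
    def n_params(self) -> int:
        return self.binary_part.n_params + self.positive_part.n_params

    @property
    def aic(self) -> float:
        return self.combined_aic

    def predict_mean(self, X) -> np.ndarray:
        """E[y|x] = Pr(y>0|x) * E[y | y>0, x]."""
        return self.binary_part.predict_mean(X) * self.positive_part.predict_mean(X)


def gengamma_mean_factor(sigma: float, q: float) -> float:
    """E[exp(sigma*w)] for the generalized-Gamma standardized log residual.

    With w = log(q^2 G)/q, G ~ Gamma(q^-2, 1), the mean of T = exp(mu + sigma*w)
    is exp(mu) * (q^2)^(sigma/q) * Gamma(q^-2 + sigma/q) / Gamma(q^-2), valid
    for q^-2 + sigma/q > 0.  The q -> 0 limit is the log-normal exp(sigma^2/2).
    """
    if abs(q) < 1e-6:
        return float(np.exp(0.5 * sigma ** 2))
    a = q ** -2.0
    if a + sigma / q <= 0:
        raise ValueError(f"generalized-Gamma mean does not exist for sigma={sigma}, q={q}")
    log_factor = gammaln(a + sigma / q) - gammaln(a) + (sigma / q) * np.log(q ** 2)
    return float(np.inf) if log_factor > 700.0 else float(np.exp(log_factor))


def tobit_censored_mean(eta: np.ndarray, sigma: float) -> np.ndarray:
    """E[max(0, eta + sigma*eps)] for standard-normal eps."""
    z = eta / sigma
    return norm.cdf(z) * eta + sigma * norm.pdf(z)


def predict_mean(model, X) -> np.ndarray:
    """Model-implied E[y|x] (probability of a positive, for the logistic)."""
    if isinstance(model, TwoPartModel):
        return model.predict_mean(X)
    eta = model.linear_predictor(X)
    fam = model.family
    if fam in ("tweedie", "gamma", "poisson"):
        return np.exp(eta)
    if fam == "gengamma":
        return np.exp(eta) * gengamma_mean_factor(model.aux["sigma"], model.aux["q"])
    if fam == "logistic":
        return expit(eta)
    if fam == "tobit":
        return tobit_censored_mean(eta, model.aux["sigma"])
    raise ValueError(f"unknown family {fam!r}")


def sample_gengamma(eta, sigma, q, rng):
    """Draws from the Prentice generalized Gamma with log-location eta."""
    eta = np.asarray(eta, dtype=float)
    if abs(q) < 1e-6:
        w = rng.standard_normal(eta.shape)
    else:
        g = rng.gamma(q ** -2.0, 1.0, size=eta.shape)
        w = np.log(q ** 2 * g) / q
    return np.exp(eta + sigma * w)


def simulate_outcomes(model, X, rng) -> np.ndarray:
    """Draw one outcome per row of ``X`` from the fitted model's distribution."""
    from . import core  # local import: core does not know about models

    if isinstance(model, TwoPartModel):
        p_pos = model.binary_part.predict_mean(X)
        y = simulate_outcomes(model.positive_part, X, rng)
        return np.where(rng.random(len(y)) < p_pos, y, 0.0)

    eta = model.linear_predictor(X)
    fam = model.family
    if fam == "tweedie":
        return core.sample_glm(np.exp(eta), model.aux["phi"], model.aux["p"], rng)
    if fam == "gamma":
        k = model.aux["shape"]
        return rng.gamma(k, np.exp(eta) / k)
    if fam == "gengamma":
        return sample_gengamma(eta, model.aux["sigma"], model.aux["q"], rng)
    if fam == "tobit":
        return np.maximum(0.0, eta + model.aux["sigma"] * rng.standard_normal(eta.shape))
    if fam == "poisson":
        return rng.poisson(np.exp(eta)).astype(float)
    if fam == "logistic":
        return (rng.random(eta.shape) < expit(eta)).astype(float)
    raise ValueError(f"unknown family {fam!r}")
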