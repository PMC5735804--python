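"""Compound Poisson-Gamma (Tweedie, 1 < p < 2) numerical kernel.

A Tweedie random variable with mean-variance power ``p`` strictly between 1
and 2 is a Poisson sum of iid Gamma variables: ``Z = X_1 + ... + X_M`` with
``M ~ Poisson(lam)`` and ``X_i ~ Gamma(alpha, scale=beta)``.  ``Z`` therefore
carries a point mass ``Pr(Z = 0) = exp(-lam)`` at zero together with a
continuous, right-skewed density on the positive half-line -- exactly the
shape of semicontinuous utilization-cost outcomes, where ``M`` counts the
utilization events in a period and ``X_i`` is the cost of the i-th event.

The module provides the parameter mappings between the GLM parameterization
``(mu, phi, p)`` (mean, dispersion, power; ``Var = phi * mu**p``) and the
compound representation ``(lam, alpha, beta)``, a numerically stable
log-density, and a random sampler.  The density has no closed form; it is
evaluated as a log-space series over the latent event count, summed across a
window around the dominant term (the standard stable strategy for this
family).  The Wright generalized Bessel function that appears in the
exponential-dispersion-model normalizer is never computed as a named special
function -- the mixture series is mathematically identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

__all__ = [
    "TweedieParams",
    "CompoundPoissonParams",
    "map_to_compound",
    "invert_compound",
    "log_density",
    "sample",
]

# Hard power-parameter bounds: the (mu, phi, p) -> (lam, alpha, beta) mapping
# divides by (2 - p) and (p - 1), so the open-interval endpoints are
# ill-conditioned.  The upper bound leaves room for the Gamma-limit check
# (p -> 2); GLM fitting uses the tighter [1.05, 1.95] (see tweediecost.glm).
P_MIN = 1.01
P_MAX = 1.999

# Series terms more than ~39 log-units below the peak are < 1e-17 of it.
_LOG_TERM_CUTOFF = -np.log(1e-17)


def _window_and_stride(m_star, alpha):
    """Summation window and stride for the latent-event-count series.

    The log-term sequence is unimodal with curvature -(1+alpha)/m at its
    peak, i.e. a quasi-Gaussian bump of sd ``sigma = sqrt(m*/(1+alpha))``.
    The window covers everything above 1e-17 of the peak (padded).  When
    ``sigma`` is large, the sum over every integer m is indistinguishable
    from the integral, so every k-th term (times k) reproduces it with
    aliasing error O(exp(-2 pi^2 (sigma/k)^2)); ``k = sigma/6`` keeps that
    below 1e-300 while bounding the work per observation.
    """
    sigma = np.sqrt(m_star / (1.0 + alpha))
    half = np.ceil(1.2 * np.sqrt(2.0 * _LOG_TERM_CUTOFF) * sigma) + 5
    m_lo = np.maximum(1, np.floor(m_star) - half).astype(np.int64)
    m_hi = (np.floor(m_star) + half).astype(np.int64)
    stride = np.maximum(1, np.floor(sigma / 6.0)).astype(np.int64)
    return m_lo, m_hi, stride


def _strided_logsum(c, m_lo, m_hi, stride, table, max_cells: int = 4_000_000):
    """log sum_m exp(m*c - table[m]) over strided windows, per row.

    ``table[m]`` must hold ``gammaln(m+1) + gammaln(m*alpha)`` for every
    index up to ``m_hi.max() + stride.max()``.  Rows are processed in chunks
    so the term matrix stays bounded in memory.
    """
    n = c.shape[0]
    counts = (m_hi - m_lo) // stride + 1
    out = np.empty(n)
    start = 0
    while start < n:
        stop = n
        width = int(counts[start:stop].max())
        while (stop - start) * width > max_cells and stop - start > 1:
            stop = start + max(1, (stop - start) // 2)
            width = int(counts[start:stop].max())
        # overshoot beyond m_hi lands on genuine (negligible) series terms
        m = m_lo[start:stop, None] + stride[start:stop, None] * np.arange(
            width, dtype=np.int64
        )
        np.minimum(m, len(table) - 1, out=m)
        terms = m * c[start:stop, None] - table[m]
        row_max = terms.max(axis=1)
        out[start:stop] = row_max + np.log(
            np.exp(terms - row_max[:, None]).sum(axis=1)
        )
        start = stop
    return out + np.log(stride)


@dataclass(frozen=True)
class TweedieParams:
    """Mean/dispersion/power triple of a Tweedie distribution with p in (1,2).

    Parameters
    ----------
    mu : float
        Mean of the outcome, in cost units.  Must be positive.
    phi : float
        Dispersion; the variance is ``phi * mu**p``.  Must be positive.
    p : float
        Mean-variance power.  Restricted to ``[1.01, 1.99]``.
    """

    mu: float
    phi: float
    p: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu) and self.mu > 0):
            raise ValueError(f"mu must be positive and finite, got {self.mu}")
        if not (np.isfinite(self.phi) and self.phi > 0):
            raise ValueError(f"phi must be positive and finite, got {self.phi}")
        if not (P_MIN <= self.p <= P_MAX):
            raise ValueError(
                f"p must lie in [{P_MIN}, {P_MAX}] (compound Poisson-Gamma "
                f"range, away from the ill-conditioned boundaries), got {self.p}"
            )

    @property
    def variance(self) -> float:
        return self.phi * self.mu ** self.p


@dataclass(frozen=True)
class CompoundPoissonParams:
    """Poisson rate and per-event Gamma shape/scale of the compound form.

    ``lam`` is the Poisson rate of utilization events, ``alpha`` the Gamma
    shape and ``beta`` the Gamma scale (cost units) of each event's cost.
    """

    lam: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.lam) and self.lam >= 0):
            raise ValueError(f"lam must be non-negative and finite, got {self.lam}")
        if not (np.isfinite(self.alpha) and self.alpha > 0):
            raise ValueError(f"alpha must be positive and finite, got {self.alpha}")
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"beta must be positive and finite, got {self.beta}")


def map_to_compound(params: TweedieParams) -> CompoundPoissonParams:
    """Convert (mu, phi, p) to the compound representation (lam, alpha, beta).

    lam = mu**(2-p) / (phi * (2-p)),  alpha = (2-p)/(p-1),
    beta = phi * (p-1) * mu**(p-1).
    """
    mu, phi, p = params.mu, params.phi, params.p
    lam = mu ** (2.0 - p) / (phi * (2.0 - p))
    alpha = (2.0 - p) / (p - 1.0)
    beta = phi * (p - 1.0) * mu ** (p - 1.0)
    return CompoundPoissonParams(lam=lam, alpha=alpha, beta=beta)


def invert_compound(cp: CompoundPoissonParams) -> TweedieParams:
    """Algebraic inverse of :func:`map_to_compound`.

    ``p`` is recovered from the shape alone via ``p = (alpha + 2)/(alpha + 1)``;
    the mean is ``lam * alpha * beta`` (Wald identity for the Poisson sum),
    and ``phi`` follows from the beta formula.
    """
    if cp.lam <= 0:
        raise ValueError("lam must be strictly positive to invert (zero mean otherwise)")
    p = (cp.alpha + 2.0) / (cp.alpha + 1.0)
    mu = cp.lam * cp.alpha * cp.beta
    phi = cp.beta / ((p - 1.0) * mu ** (p - 1.0))
    return TweedieParams(mu=mu, phi=phi, p=p)


def _series_logpdf(z, lam, alpha, log_beta):
    """Log-density of positive compound Poisson-Gamma outcomes.

    Sums, in log space, ``Poisson(m; lam) * Gamma(z; m*alpha, beta)`` over the
    latent event count ``m >= 1``.  The term sequence is unimodal in ``m``;
    the dominant index is approximately ``m* = lam * (z / (lam*alpha*beta))
    ** ... `` -- in GLM terms ``z**(2-p) / (phi (2-p))`` -- and the window is
    widened by a multiple of ``sqrt(m*/(1+alpha))`` so that excluded terms are
    below 1e-17 of the peak.

    All inputs broadcast; ``z`` must be strictly positive.
    """
    z = np.asarray(z, dtype=float)
    lam = np.broadcast_to(np.asarray(lam, dtype=float), z.shape)
    log_beta = np.broadcast_to(np.asarray(log_beta, dtype=float), z.shape)

    # Slope of the linear-in-m part of the log-term.
    c = np.log(lam) + alpha * (np.log(z) - log_beta)
    # Dominant index: solve c = log m + alpha*log(m*alpha) approximately.
    m_star = np.exp((c - alpha * np.log(alpha)) / (1.0 + alpha))
    m_lo, m_hi, stride = _window_and_stride(m_star, alpha)

    m_table = np.arange(0, int(m_hi.max()) + 1, dtype=float)
    with np.errstate(invalid="ignore"):
        table = gammaln(m_table + 1.0) + gammaln(m_table * alpha)
    log_series = _strided_logsum(c, m_lo, m_hi, stride, table)

    return log_series - lam - np.log(z) - z * np.exp(-log_beta)


def log_density(z, params: TweedieParams):
    """Log probability mass/density of the Tweedie distribution at ``z``.

    ``z == 0`` (exact equality; costs are taken as given) returns the log
    point mass ``-lam``; positive ``z`` returns the log mixture density.
    Accepts a scalar or array ``z`` and returns a matching shape.
    """
    cp = map_to_compound(params)
    z_arr = np.atleast_1d(np.asarray(z, dtype=float))
    if not np.all(np.isfinite(z_arr)):
        raise ValueError("z must be finite")
    if np.any(z_arr < 0):
        raise ValueError("z must be non-negative")

    out = np.full(z_arr.shape, -cp.lam)
    pos = z_arr > 0
    if np.any(pos):
        out[pos] = _series_logpdf(
            z_arr[pos], cp.lam, cp.alpha, np.log(cp.beta)
        )
    return out[0] if np.isscalar(z) or np.ndim(z) == 0 else out


def log_density_glm(z, mu, phi, p):
    """Vectorized log-density with per-observation means (GLM likelihood).

    Same series evaluation as :func:`log_density` but ``mu`` may be an array
    aligned with ``z`` while ``phi`` and ``p`` are scalars, which is the shape
    of a regression log-likelihood.  Used by the profile-likelihood fitter.
    """
    if not (P_MIN <= p <= P_MAX):
        raise ValueError(f"p must lie in [{P_MIN}, {P_MAX}], got {p}")
    if phi <= 0:
        raise ValueError("phi must be positive")
    z = np.asarray(z, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), z.shape)
    if np.any(mu <= 0):
        raise ValueError("mu must be strictly positive")

    lam = mu ** (2.0 - p) / (phi * (2.0 - p))
    alpha = (2.0 - p) / (p - 1.0)
    log_beta = np.log(phi * (p - 1.0)) + (p - 1.0) * np.log(mu)

    out = -lam.copy()
    pos = z > 0
    if np.any(pos):
        out[pos] = _series_logpdf(z[pos], lam[pos], alpha, log_beta[pos])
    return out


def sample(n: int, params: TweedieParams, seed) -> np.ndarray:
    """Draw ``n`` Tweedie outcomes via the compound construction.

    Each draw is 0 when the Poisson event count ``M`` is 0, otherwise a
    Gamma(M*alpha, scale=beta) variate (the sum of M iid event costs).
    Deterministic given ``seed`` (an int or a :class:`numpy.random.Generator`).
    """
    if n < 1:
        raise ValueError(f"n must be a positive integer, got {n}")
    rng = np.random.default_rng(seed)
    cp = map_to_compound(params)
    m = rng.poisson(cp.lam, size=n)
    z = np.zeros(n)
    pos = m > 0
    z[pos] = rng.gamma(shape=m[pos] * cp.alpha, scale=cp.beta)
    return z


def sample_glm(mu, phi, p, rng) -> np.ndarray:
    """Per-observation compound Poisson-Gamma draws for a fitted GLM."""
    mu = np.asarray(mu, dtype=float)
    lam = mu ** (2.0 - p) / (phi * (2.0 - p))
    alpha = (2.0 - p) / (p - 1.0)
    beta = phi * (p - 1.0) * mu ** (p - 1.0)
    m = rng.poisson(lam)
    z = np.zeros(mu.shape)
    pos = m > 0
    z[pos] = rng.gamma(shape=m[pos] * alpha, scale=beta[pos])
    return z
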