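import numpy as np
import pytest

from tweediecost import core


@pytest.fixture(scope="session")
def tweedie_glm_data():
    """Fixed-seed dataset from the package's own sampler with known
    coefficients (intercept 1.0, slopes 0.3/-0.2), phi=1, p=1.5, n=5000."""
    rng = np.random.default_rng(20171219)
    n = 5000
    X = rng.normal(size=(n, 2))
    beta = np.array([1.0, 0.3, -0.2])
    mu = np.exp(beta[0] + X @ beta[1:])
    y = core.sample_glm(mu, 1.0, 1.5, rng)
    return {"X": X, "y": y, "beta": beta, "phi": 1.0, "p": 1.5, "mu": mu}


@pytest.fixture(scope="session")
def gamma_glm_data():
    """Positive-only Gamma GLM data (shape 3) with known coefficients."""
    rng = np.random.default_rng(7)
    n = 5000
    X = rng.normal(size=(n, 2))
    beta = np.array([1.0, 0.3, -0.2])
    mu = np.exp(beta[0] + X @ beta[1:])
    y = rng.gamma(3.0, mu / 3.0)
    return {"X": X, "y": y, "beta": beta, "shape": 3.0}


def brute_force_log_density(z, mu, phi, p, n_terms=10_000):
    """Independent oracle: direct log-space summation of the Poisson-Gamma
    mixture over the first ``n_terms`` event counts."""
    from scipy.special import gammaln, logsumexp

    lam = mu ** (2 - p) / (phi * (2 - p))
    if z == 0:
        return -lam
    alpha = (2 - p) / (p - 1)
    beta = phi * (p - 1) * mu ** (p - 1)
    m = np.arange(1, n_terms + 1, dtype=float)
    terms = (
        m * np.log(lam)
        - lam
        - gammaln(m + 1)
        + (m * alpha - 1) * np.log(z)
        - z / beta
        - m * alpha * np.log(beta)
        - gammaln(m * alpha)
    )
    return float(logsumexp(terms))
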