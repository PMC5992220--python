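"""Student's-t mixture densities, responsibilities and scaling weights.

The template points y_n act as the component centroids of a heavy-tailed
mixture: each component is a multivariate Student's-t distribution with
shared isotropic scale sigma^2 * I and a per-component degrees-of-freedom
gamma_n.  Small gamma_n yields heavy tails that down-weight outliers and
points whose true partner is missing; as gamma_n -> infinity every
component becomes the isotropic Gaussian N(y_n, sigma^2 I), recovering a
plain Gaussian mixture.

The t distribution is handled in its scale-mixture-of-Gaussians form: a
latent Gamma((gamma_n)/2, (gamma_n)/2) scale u makes x | u Gaussian with
covariance sigma^2 / u.  Its conditional expectation

    u_mn = (gamma_n + D) / (gamma_n + d_mn),

with d_mn the squared Mahalanobis distance, is the per-pair robustness
weight used throughout the M-step.

All density arithmetic is carried out in log space: sigma^2 shrinks by
orders of magnitude over the EM iterations and raw densities overflow or
underflow long before convergence.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.spatial.distance import cdist
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "MixtureState",
    "mahalanobis_sq",
    "student_t_logpdf",
    "log_density_matrix",
    "scaling_weights",
    "posteriors",
    "objective",
]


@dataclasses.dataclass(eq=False)
class MixtureState:
    """All per-iteration EM quantities.

    Attributes
    ----------
    Y_cur : (N, D) current template positions in normalized space.
    sigma2 : shared isotropic variance, > 0.
    gamma : (N,) per-component degrees of freedom, > 0.
    Wprior : (M, N) per-pair mixture proportions w_mn; rows on the open simplex.
    P : (M, N) posterior responsibilities p_mn; rows sum to 1.
    U : (M, N) latent scaling weights u_mn, > 0.
    alpha_bar : Dirichlet spatial-concentration coefficient, > 0.
    """

    Y_cur: np.ndarray
    sigma2: float
    gamma: np.ndarray
    Wprior: np.ndarray
    P: np.ndarray
    U: np.ndarray
    alpha_bar: float

    def check(self, atol: float = 1e-9) -> None:
        """Raise AssertionError if any state invariant is violated."""
        assert self.sigma2 > 0, "sigma2 must be positive"
        assert np.all(self.gamma > 0), "all gamma_n must be positive"
        assert np.all(self.U > 0), "all u_mn must be positive"
        assert np.all(self.Wprior > 0) and np.all(self.Wprior < 1), (
            "w_mn must lie strictly in (0, 1)"
        )
        np.testing.assert_allclose(self.Wprior.sum(axis=1), 1.0, atol=atol)
        assert np.all(self.P >= 0), "posteriors must be nonnegative"
        np.testing.assert_allclose(self.P.sum(axis=1), 1.0, atol=atol)
        assert self.alpha_bar > 0, "alpha_bar must be positive"


def _coords(x) -> np.ndarray:
    return x.coords if hasattr(x, "coords") else np.asarray(x, dtype=float)


def mahalanobis_sq(x: np.ndarray, y: np.ndarray, sigma2: float) -> float:
    """Squared Mahalanobis distance (x-y)'(x-y)/sigma^2 for isotropic scale."""
    if not sigma2 > 0:
        raise ValueError("sigma2 must be positive")
    diff = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    return float(np.dot(diff, diff) / sigma2)


def student_t_logpdf(
    x: np.ndarray, y: np.ndarray, sigma2: float, gamma: float, dim: int | None = None
) -> float:
    """Log density of the multivariate Student's-t S(x | y, sigma^2 I, gamma).

    Uses the standard normalizer
    Gamma((gamma+D)/2) / (Gamma(gamma/2) (gamma pi)^{D/2} sigma^D) so that
    the density integrates to 1 for every gamma; this matters in the
    responsibility ratio because gamma differs per component.
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite input point")
    if not (sigma2 > 0 and gamma > 0):
        raise ValueError("sigma2 and gamma must be positive")
    D = int(dim) if dim is not None else x.shape[0]
    d = mahalanobis_sq(x, y, sigma2)
    return float(
        gammaln((gamma + D) / 2.0)
        - gammaln(gamma / 2.0)
        - 0.5 * D * np.log(gamma * np.pi)
        - 0.5 * D * np.log(sigma2)
        - 0.5 * (D + gamma) * np.log1p(d / gamma)
    )


def log_density_matrix(
    X, Y_cur: np.ndarray, sigma2: float, gamma: np.ndarray
) -> np.ndarray:
    """(M, N) matrix of log S(x_m | y_n, sigma^2, gamma_n), vectorized."""
    Xc = _coords(X)
    Yc = np.asarray(Y_cur, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    D = Xc.shape[1]
    d = cdist(Xc, Yc, "sqeuclidean") / sigma2  # (M, N)
    const = (
        gammaln((gamma + D) / 2.0)
        - gammaln(gamma / 2.0)
        - 0.5 * D * np.log(gamma * np.pi)
        - 0.5 * D * np.log(sigma2)
    )  # (N,)
    return const[None, :] - 0.5 * (D + gamma)[None, :] * np.log1p(d / gamma[None, :])


def scaling_weights(
    X, Y_cur: np.ndarray, sigma2: float, gamma: np.ndarray
) -> np.ndarray:
    """Latent Gaussian-scale weights u_mn = (gamma_n + D)/(gamma_n + d_mn).

    Strictly positive; equal to 1 in the Gaussian limit gamma -> inf and
    strictly decreasing in the Mahalanobis distance d_mn, so distant
    (outlying) observations are down-weighted in the M-step.
    """
    Xc = _coords(X)
    Yc = np.asarray(Y_cur, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    D = Xc.shape[1]
    d = cdist(Xc, Yc, "sqeuclidean") / sigma2
    return (gamma[None, :] + D) / (gamma[None, :] + d)


def posteriors(
    X, Y_cur: np.ndarray, sigma2: float, gamma: np.ndarray, Wprior: np.ndarray
) -> np.ndarray:
    """Posterior responsibilities p_mn = w_mn S_mn / sum_n' w_mn' S_mn'.

    Computed row-wise in log space (log-sum-exp).  A row whose terms are
    all non-finite (fully degenerate) falls back to the uniform row 1/N so
    the EM iteration survives extreme-outlier fixtures; a warning is logged.
    """
    logS = log_density_matrix(X, Y_cur, sigma2, gamma)
    logW = np.log(np.asarray(Wprior, dtype=float))
    logit = logW + logS
    norm = logsumexp(logit, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        P = np.exp(logit - norm)
    bad = ~np.all(np.isfinite(P), axis=1)
    if np.any(bad):
        logger.warning(
            "posteriors: %d degenerate row(s) fell back to uniform", int(bad.sum())
        )
        P[bad] = 1.0 / P.shape[1]
    return P


def objective(X, state: MixtureState) -> float:
    """Negative incomplete-data log-likelihood -sum_m log sum_n w_mn S_mn."""
    logS = log_density_matrix(X, state.Y_cur, state.sigma2, state.gamma)
    val = -float(np.sum(logsumexp(np.log(state.Wprior) + logS, axis=1)))
    if not np.isfinite(val):
        raise FloatingPointError("objective is non-finite")
    return val
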