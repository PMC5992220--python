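"""Per-pair mixture proportions from a Dirichlet model with spatial smoothing.

This is the distinctive piece of the registration model.  Instead of one
shared mixture proportion per component, every observation-component pair
(m, n) carries its own prior w_mn.  Treating the component labels as
random variables with a Dirichlet prior whose concentration parameters are

    alpha_mn = exp( (alpha_bar / N_n) * sum_{i in neigh(n)} p_mi ),

i.e. an exponentiated moving average of the current posteriors over the
spatial neighbors of template point n, yields the closed-form proportions

    w_mn = alpha_mn / sum_n' alpha_mn'            (a softmax over components).

The smoothing couples neighboring template points — coherent regions end
up voting together for their correspondences — and the single scalar
concentration coefficient alpha_bar is re-estimated each EM iteration by
a one-dimensional root solve, so the prior model adds only one parameter.

With alpha_bar = 0 every w_mn collapses to 1/N and the model degenerates
to the uniform proportions of classic coherent-drift registration.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from scipy.special import softmax

logger = logging.getLogger(__name__)

__all__ = [
    "Neighborhood",
    "build_neighborhood",
    "smoothed_posterior",
    "dirichlet_alpha",
    "mixture_proportions",
    "softmax_proportions",
    "alpha_residual",
    "solve_alpha_bar",
]


@dataclasses.dataclass(frozen=True, eq=False)
class Neighborhood:
    """k-nearest-neighbor index sets over the template points.

    ``indices[n]`` lists the template indices whose points lie in the
    window around y_n (always including n itself); ``sizes[n]`` is N_n.
    """

    indices: np.ndarray  # (N, k) int
    sizes: np.ndarray  # (N,) int

    @property
    def n_points(self) -> int:
        return self.indices.shape[0]

    def averaging_matrix(self) -> np.ndarray:
        """(N, N) matrix A with A[i, n] = 1/N_n for i in neigh(n), else 0."""
        N = self.n_points
        A = np.zeros((N, N))
        for n in range(N):
            A[self.indices[n], n] += 1.0 / self.sizes[n]
        return A


def build_neighborhood(Y, k: int) -> Neighborhood:
    """k nearest template points (Euclidean, self included) for each y_n."""
    Yc = Y.coords if hasattr(Y, "coords") else np.asarray(Y, dtype=float)
    N = Yc.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > N:
        raise ValueError(f"k={k} exceeds the number of template points N={N}")
    _, idx = cKDTree(Yc).query(Yc, k=k)
    idx = np.atleast_2d(np.asarray(idx, dtype=int))
    if k == 1:
        idx = idx.reshape(N, 1)
    # duplicate points can tie the self index out of the k-list; force it in
    for n in range(N):
        if n not in idx[n]:
            idx[n, -1] = n
    return Neighborhood(indices=idx, sizes=np.full(N, k, dtype=int))


def smoothed_posterior(P: np.ndarray, nbhd: Neighborhood) -> np.ndarray:
    """Moving average s_mn = (1/N_n) sum_{i in neigh(n)} p_mi."""
    return np.asarray(P, dtype=float) @ nbhd.averaging_matrix()


def dirichlet_alpha(S: np.ndarray, alpha_bar: float) -> np.ndarray:
    """Dirichlet concentration parameters alpha_mn = exp(alpha_bar * s_mn).

    Exposed for inspection; the registration path never materializes this
    matrix and evaluates the softmax of alpha_bar * S directly instead.
    """
    if alpha_bar < 0:
        raise ValueError("alpha_bar must be nonnegative")
    z = alpha_bar * np.asarray(S, dtype=float)
    if np.max(z) > 700.0:
        raise OverflowError(
            "alpha_bar * s exceeds exp() range; use a smaller alpha_bar bound "
            "(or the stable softmax_proportions path)"
        )
    return np.exp(z)


def mixture_proportions(A: np.ndarray) -> np.ndarray:
    """Per-observation proportions w_mn = alpha_mn / sum_n' alpha_mn'."""
    A = np.asarray(A, dtype=float)
    if not np.all(A > 0):
        raise ValueError("all alpha_mn must be positive")
    return A / A.sum(axis=1, keepdims=True)


def softmax_proportions(S: np.ndarray, alpha_bar: float) -> np.ndarray:
    """Numerically stable w_mn = softmax_n(alpha_bar * s_mn).

    Identical to ``mixture_proportions(dirichlet_alpha(S, alpha_bar))`` but
    safe for large alpha_bar (per-row max subtraction).  alpha_bar = 0 gives
    exactly uniform rows 1/N.  The softmax is strictly interior to the
    simplex in exact arithmetic; entries are clipped to the open interval
    (1e-300, 1 - ulp) to preserve that under floating-point underflow at
    extreme concentration.
    """
    W = softmax(alpha_bar * np.asarray(S, dtype=float), axis=1)
    return np.clip(W, 1e-300, np.nextafter(1.0, 0.0))


def alpha_residual(alpha_bar: float, P: np.ndarray, S: np.ndarray) -> float:
    """Stationarity residual g(alpha_bar) of the concentration coefficient.

    g(a) = sum_n sum_m p_mn * ( s_mn - <s_.n>_a ), where <s_.n>_a is the
    softmax-weighted (over observations m', weights exp(a s_m'n)) mean of
    column n of S.  The estimate alpha_bar* is the root g(alpha_bar*) = 0.
    """
    P = np.asarray(P, dtype=float)
    S = np.asarray(S, dtype=float)
    w = softmax(alpha_bar * S, axis=0)  # (M, N), columns sum to 1
    col_mean = np.sum(S * w, axis=0)  # (N,)
    return float(np.sum(P * S) - np.sum(P.sum(axis=0) * col_mean))


def solve_alpha_bar(
    P: np.ndarray,
    nbhd: Neighborhood,
    bounds: tuple = (1e-3, 100.0),
    tol: float = 1e-8,
    hi_cap: float = 1e4,
) -> float:
    """Estimate alpha_bar by a bracketed root search on g(alpha_bar).

    The bracket expands by doubling the upper bound (up to ``hi_cap``) if
    no sign change is found; if none exists the bound with the smaller
    |g| is returned and a warning logged.
    """
    S = smoothed_posterior(P, nbhd)
    return _solve_alpha_bar_from_smoothed(P, S, bounds, tol, hi_cap)


def _solve_alpha_bar_from_smoothed(
    P: np.ndarray, S: np.ndarray, bounds: tuple, tol: float = 1e-8, hi_cap: float = 1e4
) -> float:
    lo, hi = float(bounds[0]), float(bounds[1])
    if not (0 < lo < hi):
        raise ValueError(f"invalid alpha_bar bounds {bounds}")
    g = lambda a: alpha_residual(a, P, S)
    g_lo = g(lo)
    if abs(g_lo) <= tol:
        return lo
    g_hi = g(hi)
    if abs(g_hi) <= tol:
        return hi
    while g_lo * g_hi > 0 and hi < hi_cap:
        hi = min(2.0 * hi, hi_cap)
        g_hi = g(hi)
    if g_lo * g_hi > 0:
        best = lo if abs(g_lo) <= abs(g_hi) else hi
        logger.warning(
            "solve_alpha_bar: no sign change on [%g, %g]; returning bound %g "
            "(|g|=%.3g)", lo, hi, best, min(abs(g_lo), abs(g_hi)),
        )
        return best
    root = brentq(g, lo, hi, xtol=1e-12, rtol=8.881784197001252e-16)
    return float(root)
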