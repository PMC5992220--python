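"""Coherent non-rigid deformation via Gaussian radial basis functions.

The template moves by a displacement field v(y) = sum_n G(y, y_n) w_n
anchored at the (initial) template points, with the Gaussian kernel

    g_ij = exp(-||y_i - y_j||^2 / (2 beta^2)).

beta sets the spatial coherence scale of the motion (large beta forces
nearly rigid translation, small beta allows local warps); the coefficient
matrix W is obtained from the weighted, regularized least-squares problem

    (diag(d) G + lambda sigma^2 I) W = P_hat' X - diag(d) Y_prev,

where P_hat = P * U is the posterior matrix corrected by the latent
t-scale weights and d = column sums of P_hat.  lambda trades data fit
against the motion-coherence penalty tr(W' G W).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "GRBFModel",
    "grbf_kernel",
    "solve_coefficients",
    "apply_transform",
    "update_sigma2",
]

SIGMA2_FLOOR = 1e-10  # normalized units; keeps u_mn finite at a perfect fit


@dataclasses.dataclass(eq=False)
class GRBFModel:
    """Gaussian-kernel deformation model over the template points."""

    G: np.ndarray  # (N, N) kernel matrix, built once from the initial template
    beta: float
    lam: float
    Wcoef: np.ndarray | None = None  # (N, D) last solved coefficients

    def __post_init__(self) -> None:
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        if not self.lam > 0:
            raise ValueError("lam must be positive")


def grbf_kernel(Y0, beta: float) -> np.ndarray:
    """Symmetric Gaussian kernel matrix g_ij = exp(-||y_i-y_j||^2/(2 beta^2))."""
    if not beta > 0:
        raise ValueError("beta must be positive")
    Yc = Y0.coords if hasattr(Y0, "coords") else np.asarray(Y0, dtype=float)
    return np.exp(-cdist(Yc, Yc, "sqeuclidean") / (2.0 * beta**2))


def solve_coefficients(
    G: np.ndarray,
    P_hat: np.ndarray,
    X,
    Y_prev: np.ndarray,
    lam: float,
    sigma2_prev: float,
) -> np.ndarray:
    """Solve the regularized normal equations for the GRBF coefficients W.

    Raises if the regularized system is numerically singular or the
    relative residual exceeds 1e-8.
    """
    Xc = X.coords if hasattr(X, "coords") else np.asarray(X, dtype=float)
    G = np.asarray(G, dtype=float)
    P_hat = np.asarray(P_hat, dtype=float)
    if np.any(P_hat < 0):
        raise ValueError("P_hat entries must be nonnegative")
    if not (lam > 0 and sigma2_prev > 0):
        raise ValueError("lam and sigma2_prev must be positive")
    d = P_hat.sum(axis=0)  # (N,) per-component weights
    A = d[:, None] * G + lam * sigma2_prev * np.eye(G.shape[0])
    rhs = P_hat.T @ Xc - d[:, None] * np.asarray(Y_prev, dtype=float)
    W = np.linalg.solve(A, rhs)
    denom = max(np.linalg.norm(rhs), 1.0)
    resid = np.linalg.norm(A @ W - rhs) / denom
    if resid > 1e-8:
        raise np.linalg.LinAlgError(
            f"GRBF coefficient solve ill-conditioned (relative residual {resid:.2e})"
        )
    return W


def apply_transform(Y_prev: np.ndarray, G: np.ndarray, Wcoef: np.ndarray) -> np.ndarray:
    """Incremental template update Y_new = Y_prev + G W."""
    return np.asarray(Y_prev, dtype=float) + np.asarray(G, dtype=float) @ np.asarray(
        Wcoef, dtype=float
    )


def update_sigma2(P_hat: np.ndarray, X, Y_new: np.ndarray, dim: int) -> float:
    """Weighted residual variance after the transform update.

    sigma^2 = sum_mn p_hat_mn ||x_m - y_n_new||^2 / (D sum_mn p_hat_mn),
    floored at SIGMA2_FLOOR for a perfect fit.
    """
    Xc = X.coords if hasattr(X, "coords") else np.asarray(X, dtype=float)
    P_hat = np.asarray(P_hat, dtype=float)
    total = float(P_hat.sum())
    if total <= 0:
        raise ValueError("sum of P_hat must be positive")
    sq = cdist(Xc, np.asarray(Y_new, dtype=float), "sqeuclidean")
    sigma2 = float(np.sum(P_hat * sq) / (dim * total))
    return max(sigma2, SIGMA2_FLOOR)
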