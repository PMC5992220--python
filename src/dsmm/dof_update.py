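"""Per-component degrees-of-freedom updates for the Student's-t mixture.

Each EM iteration re-estimates gamma_n from the stationarity condition

    h(gamma) = -psi(gamma/2) + ln(gamma/2) + 1
               + sum_m p_mn (ln u_mn - u_mn) / sum_m p_mn
               + psi((gamma_prev + D)/2) - ln((gamma_prev + D)/2) = 0,

with psi the digamma function.  Since ln x - psi(x) is positive and
strictly decreasing to 0, h is strictly decreasing in gamma; a root is
bracketed on a geometric grid and polished with Brent's method.  For
perfectly Gaussian-like data (all u_mn = 1) h stays positive and gamma is
capped: beyond ~1e6 the t component is numerically a Gaussian anyway.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.optimize import brentq
from scipy.special import digamma

logger = logging.getLogger(__name__)

__all__ = ["dof_residual", "solve_dof", "solve_dof_all"]

_GRID_SIZE = 33


def dof_residual(
    gamma: float, const: float, gamma_prev: float, dim: int
) -> float:
    """h(gamma) with the data term already collapsed into ``const``.

    ``const`` is sum_m p_mn (ln u_mn - u_mn) / sum_m p_mn  (always <= -1,
    with equality iff every u_mn = 1).
    """
    z_prev = (gamma_prev + dim) / 2.0
    return float(
        -digamma(gamma / 2.0)
        + np.log(gamma / 2.0)
        + 1.0
        + const
        + digamma(z_prev)
        - np.log(z_prev)
    )


def _data_const(P_col: np.ndarray, U_col: np.ndarray) -> float:
    P_col = np.asarray(P_col, dtype=float)
    U_col = np.asarray(U_col, dtype=float)
    sp = float(P_col.sum())
    if sp <= 0:
        return np.nan  # caller treats the component as inactive
    return float(np.sum(P_col * (np.log(U_col) - U_col)) / sp)


def _solve_from_const(
    const: float, gamma_prev: float, dim: int, bounds: tuple
) -> float:
    lo, hi = float(bounds[0]), float(bounds[1])
    grid = np.geomspace(lo, hi, _GRID_SIZE)
    hvals = np.array([dof_residual(g, const, gamma_prev, dim) for g in grid])
    return _root_from_grid(grid, hvals, const, gamma_prev, dim)


def _root_from_grid(
    grid: np.ndarray, hvals: np.ndarray, const: float, gamma_prev: float, dim: int
) -> float:
    sign_change = np.nonzero(np.diff(np.sign(hvals)) != 0)[0]
    if sign_change.size == 0:
        if np.all(hvals > 0):
            logger.debug("solve_dof: h > 0 over bracket; gamma capped at %g", grid[-1])
            return float(grid[-1])
        return float(grid[0])
    i = int(sign_change[0])
    if hvals[i] == 0.0:
        return float(grid[i])
    root = brentq(
        lambda g: dof_residual(g, const, gamma_prev, dim),
        grid[i],
        grid[i + 1],
        xtol=1e-14,
        rtol=8.881784197001252e-16,
    )
    return float(root)


def solve_dof(
    P_col: np.ndarray,
    U_col: np.ndarray,
    gamma_prev: float,
    dim: int,
    bounds: tuple = (1e-2, 1e6),
) -> float:
    """Solve h(gamma) = 0 for one component.

    Returns ``gamma_prev`` unchanged when the component is inactive
    (sum_m p_mn = 0); returns the upper bound when h > 0 over the whole
    bracket (clean Gaussian-like data), the lower bound when h < 0.
    """
    if not gamma_prev > 0:
        raise ValueError("gamma_prev must be positive")
    const = _data_const(P_col, U_col)
    if not np.isfinite(const):
        logger.debug("solve_dof: inactive component (sum p = 0); gamma unchanged")
        return float(gamma_prev)
    return _solve_from_const(const, gamma_prev, dim, bounds)


def solve_dof_all(
    P: np.ndarray,
    U: np.ndarray,
    gamma_prev: np.ndarray,
    dim: int,
    bounds: tuple = (1e-2, 1e6),
) -> np.ndarray:
    """Vectorized gamma update for all N components.

    The grid part of h is separable — h(g; n) = a(g) + b(n) — so the
    bracketing scan is shared across components; only the Brent polish
    runs per component.
    """
    P = np.asarray(P, dtype=float)
    U = np.asarray(U, dtype=float)
    gamma_prev = np.asarray(gamma_prev, dtype=float)
    N = P.shape[1]
    sp = P.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        const = np.einsum("mn,mn->n", P, np.log(U) - U) / sp
    lo, hi = float(bounds[0]), float(bounds[1])
    grid = np.geomspace(lo, hi, _GRID_SIZE)
    a = -digamma(grid / 2.0) + np.log(grid / 2.0) + 1.0  # (G,)
    z_prev = (gamma_prev + dim) / 2.0
    b = const + digamma(z_prev) - np.log(z_prev)  # (N,)
    H = a[:, None] + b[None, :]  # (G, N)
    out = np.empty(N)
    for n in range(N):
        if sp[n] <= 0 or not np.isfinite(const[n]):
            out[n] = gamma_prev[n]
            continue
        out[n] = _root_from_grid(grid, H[:, n], const[n], gamma_prev[n], dim)
    return out
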