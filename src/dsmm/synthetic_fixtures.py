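"""Synthetic point-set pairs with known ground truth.

The generators emulate the experimental regimes the registration method
is meant for, without any external data:

* 2-D contour-like sets (default 63 points) shaped like an elongated
  corpus-callosum bean, a fish silhouette, or a circle;
* 3-D cloud-like sets (default 300 points) sampled from three anisotropic
  Gaussian blobs confined to a lung-sized ellipsoid (semi-axes
  50 x 70 x 100 mm), so distances read in familiar millimetre magnitudes;
* smooth coherent deformations from a Gaussian-RBF field with 5 random
  control points (amplitude expressed as mean displacement over the
  bounding-box diagonal);
* uniform outliers appended to either set inside the 1.2x-expanded
  bounding box (fraction measured against the original clean count);
* occlusion by random deletion of points, with DISJOINT deletion sets in
  the two sets so that removing r points from each of two n-point sets
  leaves exactly n - 2r surviving correspondences.

Everything is reproducible bit-exactly from (kind, level, seed).
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Optional, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .pointset_io import PointSet

__all__ = [
    "SyntheticScenario",
    "generate_contour",
    "generate_cloud",
    "deform_smooth",
    "add_outliers",
    "occlude",
    "make_scenario",
    "mean_correspondence_error",
    "pre_registration_error",
]

CLOUD_SEMI_AXES = (50.0, 70.0, 100.0)  # mm; lung-like bounding ellipsoid
DEFORM_N_CONTROL = 5
DEFORM_WIDTH_DEFAULT = 0.5  # control-kernel width as a fraction of the bbox diagonal


@dataclasses.dataclass(eq=False)
class SyntheticScenario:
    """A generated registration problem with ground truth.

    ``true_map`` maps each template row index with a surviving genuine
    partner to its target row index (injective).  Outlier masks mark the
    appended clutter rows in each set.
    """

    X: PointSet
    Y: PointSet
    true_map: Dict[int, int]
    outlier_mask_X: np.ndarray
    outlier_mask_Y: np.ndarray
    params: dict

    def __post_init__(self) -> None:
        targets = list(self.true_map.values())
        if len(set(targets)) != len(targets):
            raise ValueError("true_map must be injective")


def _bbox_diag(coords: np.ndarray) -> float:
    return float(np.linalg.norm(coords.max(axis=0) - coords.min(axis=0)))


def generate_contour(n_points: int, shape: str = "cc_like", seed: int = 0) -> PointSet:
    """Ordered 2-D points along a closed smooth parametric curve.

    ``cc_like`` is an elongated two-harmonic Fourier bean; ``fish`` is the
    classic fish curve; ``circle`` is the unit circle.  The seed rotates
    the starting phase and adds a tiny (0.5%) radial jitter so distinct
    seeds give distinct but equally shaped sets.
    """
    if n_points < 8:
        raise ValueError("n_points must be >= 8")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False) + phase
    if shape == "circle":
        # kept exactly on the unit circle (the phase still depends on the seed)
        return PointSet(np.column_stack([np.cos(t), np.sin(t)]))
    if shape == "cc_like":
        x = 1.6 * np.cos(t) + 0.3 * np.cos(2.0 * t)
        y = 0.7 * np.sin(t) + 0.25 * np.sin(2.0 * t)
    elif shape == "fish":
        x = np.cos(t) - np.sin(t) ** 2 / np.sqrt(2.0)
        y = np.cos(t) * np.sin(t)
    else:
        raise ValueError(f"unknown contour shape {shape!r}")
    pts = np.column_stack([x, y])
    pts = pts * (1.0 + rng.normal(0.0, 0.005, size=(n_points, 1)))
    return PointSet(pts)


def generate_cloud(n_points: int, seed: int = 0) -> PointSet:
    """3-D cloud: mixture of 3 anisotropic Gaussian blobs in an ellipsoid.

    All points lie strictly inside the ellipsoid with semi-axes
    ``CLOUD_SEMI_AXES`` (rejection sampling); coordinates are in mm.
    """
    if n_points < 10:
        raise ValueError("n_points must be >= 10")
    rng = np.random.default_rng(seed)
    axes = np.asarray(CLOUD_SEMI_AXES)
    centers = rng.uniform(-0.45, 0.45, size=(3, 3)) * axes  # blob centers, well inside
    covs = []
    for _ in range(3):
        # random rotation times anisotropic spread (8-28 mm std per axis)
        A = rng.normal(size=(3, 3))
        Q, _ = np.linalg.qr(A)
        spread = rng.uniform(8.0, 28.0, size=3)
        covs.append(Q @ np.diag(spread**2) @ Q.T)
    counts = np.full(3, n_points // 3)
    counts[: n_points - counts.sum()] += 1
    pts = []
    for c in range(3):
        need = counts[c]
        got = []
        while len(got) < need:
            cand = rng.multivariate_normal(centers[c], covs[c], size=need, method="cholesky")
            inside = np.sum((cand / axes) ** 2, axis=1) < 1.0
            got.extend(cand[inside])
        pts.append(np.asarray(got[:need]))
    return PointSet(np.vstack(pts))


def deform_smooth(
    ps: PointSet,
    amplitude: float,
    width: float = DEFORM_WIDTH_DEFAULT,
    seed: int = 0,
) -> Tuple[PointSet, np.ndarray]:
    """Displace every point by a smooth Gaussian-RBF field.

    The field is a sum of ``DEFORM_N_CONTROL`` Gaussian bumps at random
    control points inside the bounding box, rescaled so the mean
    displacement norm equals ``amplitude`` times the bounding-box
    diagonal.  ``width`` is the bump width as a fraction of the diagonal.
    Returns the deformed set and the (n, D) displacement field.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if not width > 0:
        raise ValueError("width must be positive")
    coords = ps.coords
    if amplitude == 0.0:
        return PointSet(coords.copy()), np.zeros_like(coords)
    rng = np.random.default_rng(seed)
    lo, hi = coords.min(axis=0), coords.max(axis=0)
    diag = _bbox_diag(coords)
    ctrl = rng.uniform(lo, hi, size=(DEFORM_N_CONTROL, ps.dim))
    coef = rng.normal(size=(DEFORM_N_CONTROL, ps.dim))
    K = np.exp(-cdist(coords, ctrl, "sqeuclidean") / (2.0 * (width * diag) ** 2))
    raw = K @ coef
    mean_norm = float(np.mean(np.linalg.norm(raw, axis=1)))
    if mean_norm == 0.0:
        return PointSet(coords.copy()), np.zeros_like(coords)
    disp = raw * (amplitude * diag / mean_norm)
    return PointSet(coords + disp), disp


def add_outliers(
    ps: PointSet, fraction: float, seed: int = 0
) -> Tuple[PointSet, np.ndarray]:
    """Append round(fraction * n) uniform outliers in the expanded bbox.

    The fraction is measured against the ORIGINAL clean count; outliers
    are drawn uniformly in the bounding box expanded by 1.2x about its
    center.  The returned boolean mask marks the appended rows.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    n = ps.n_points
    n_add = int(round(fraction * n))
    if n_add == 0:
        return PointSet(ps.coords.copy()), np.zeros(n, dtype=bool)
    rng = np.random.default_rng(seed)
    lo, hi = ps.coords.min(axis=0), ps.coords.max(axis=0)
    center = 0.5 * (lo + hi)
    half = 0.5 * (hi - lo) * 1.2
    extra = rng.uniform(center - half, center + half, size=(n_add, ps.dim))
    mask = np.zeros(n + n_add, dtype=bool)
    mask[n:] = True
    return PointSet(np.vstack([ps.coords, extra])), mask


def occlude(ps: PointSet, n_remove: int, seed: int = 0) -> Tuple[PointSet, np.ndarray]:
    """Uniformly delete ``n_remove`` rows; returns survivors + removed indices."""
    if not 0 <= n_remove < ps.n_points:
        raise ValueError(
            f"n_remove must lie in [0, {ps.n_points - 1}], got {n_remove}"
        )
    if n_remove == 0:
        return PointSet(ps.coords.copy()), np.empty(0, dtype=int)
    rng = np.random.default_rng(seed)
    removed = np.sort(rng.choice(ps.n_points, size=n_remove, replace=False))
    keep = np.setdiff1d(np.arange(ps.n_points), removed)
    return PointSet(ps.coords[keep]), removed


def _apply_removal(n: int, removed: np.ndarray) -> Dict[int, int]:
    """Old-index -> new-index map after deleting ``removed`` rows."""
    keep = np.setdiff1d(np.arange(n), removed)
    return {int(old): new for new, old in enumerate(keep)}


def make_scenario(kind: str, level: float, seed: int = 0) -> SyntheticScenario:
    """Compose generate -> deform -> degrade into a full test scenario.

    kind / level:
      * ``contour_deform`` — 63-point bean contour; level = deformation
        amplitude (fraction of bbox diagonal).
      * ``cloud_deform`` — 300-point lung-like cloud; level = amplitude.
      * ``outliers`` — deformed contour pair (amplitude 0.05) with
        level * n uniform outliers appended to BOTH sets.
      * ``occlusion`` — deformed cloud pair (amplitude 0.10) with
        round(level) points deleted from each set (disjoint index sets).
    """
    seed = int(seed)
    params = {"kind": kind, "level": float(level), "seed": seed,
              "deform_width": DEFORM_WIDTH_DEFAULT, "noise_sd": 0.0}
    if kind in ("contour_deform", "outliers"):
        n = 63
        amplitude = float(level) if kind == "contour_deform" else 0.05
        Y0 = generate_contour(n, "cc_like", seed)
    elif kind in ("cloud_deform", "occlusion"):
        n = 300
        amplitude = float(level) if kind == "cloud_deform" else 0.10
        Y0 = generate_cloud(n, seed)
    else:
        raise ValueError(f"unknown scenario kind {kind!r}")
    params.update({"n_points": n, "deform_amplitude": amplitude,
                   "shape": "cc_like" if n == 63 else "cloud"})
    X0, _ = deform_smooth(Y0, amplitude, DEFORM_WIDTH_DEFAULT, seed + 1)

    if kind in ("contour_deform", "cloud_deform"):
        true_map = {i: i for i in range(n)}
        return SyntheticScenario(
            X=X0, Y=Y0, true_map=true_map,
            outlier_mask_X=np.zeros(n, dtype=bool),
            outlier_mask_Y=np.zeros(n, dtype=bool),
            params={**params, "outlier_fraction": 0.0, "occlusion_count": 0},
        )
    if kind == "outliers":
        X, mask_X = add_outliers(X0, level, seed + 2)
        Y, mask_Y = add_outliers(Y0, level, seed + 3)
        true_map = {i: i for i in range(n)}  # originals keep their indices
        return SyntheticScenario(
            X=X, Y=Y, true_map=true_map,
            outlier_mask_X=mask_X, outlier_mask_Y=mask_Y,
            params={**params, "outlier_fraction": float(level), "occlusion_count": 0},
        )
    # occlusion: disjoint removal sets so survivors pair up exactly
    n_remove = int(round(level))
    if not 0 <= 2 * n_remove <= n:
        raise ValueError(f"cannot remove {n_remove} points twice from {n}")
    rng = np.random.default_rng(seed + 2)
    perm = rng.permutation(n)
    rem_X = np.sort(perm[:n_remove])
    rem_Y = np.sort(perm[n_remove : 2 * n_remove])
    keep_X = np.setdiff1d(np.arange(n), rem_X)
    keep_Y = np.setdiff1d(np.arange(n), rem_Y)
    X = PointSet(X0.coords[keep_X])
    Y = PointSet(Y0.coords[keep_Y])
    old2new_X = _apply_removal(n, rem_X)
    old2new_Y = _apply_removal(n, rem_Y)
    true_map = {
        old2new_Y[i]: old2new_X[i]
        for i in range(n)
        if i in old2new_Y and i in old2new_X
    }
    # survivors whose partner was deleted in the OTHER set act as outliers
    mask_X = np.array([keep_X[j] in set(rem_Y) for j in range(len(keep_X))])
    mask_Y = np.array([keep_Y[j] in set(rem_X) for j in range(len(keep_Y))])
    return SyntheticScenario(
        X=X, Y=Y, true_map=true_map,
        outlier_mask_X=mask_X, outlier_mask_Y=mask_Y,
        params={**params, "outlier_fraction": 0.0, "occlusion_count": n_remove},
    )


def _final_positions(result_or_coords) -> np.ndarray:
    if hasattr(result_or_coords, "Y_final"):
        return result_or_coords.Y_final.coords
    if hasattr(result_or_coords, "coords"):
        return result_or_coords.coords
    return np.asarray(result_or_coords, dtype=float)


def mean_correspondence_error(
    result, scenario: SyntheticScenario
) -> Tuple[float, float]:
    """Mean and SD of Euclidean distances over ground-truth pairs.

    ``result`` may be a RegistrationResult or template positions directly;
    distances are measured in the scenario's original units.
    """
    if not scenario.true_map:
        raise ValueError("scenario has an empty true_map")
    Yf = _final_positions(result)
    Xc = scenario.X.coords
    dists = np.array(
        [np.linalg.norm(Yf[n] - Xc[m]) for n, m in scenario.true_map.items()]
    )
    return float(dists.mean()), float(dists.std())


def pre_registration_error(scenario: SyntheticScenario) -> Tuple[float, float]:
    """Correspondence error of the undeformed template (the starting point)."""
    return mean_correspondence_error(scenario.Y.coords, scenario)
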