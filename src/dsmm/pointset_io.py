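"""Point-set containers, text/PLY I/O and scale normalization.

Registration operates on two point sets: a fixed *target* set ``X`` (M×D)
and a moving *template* set ``Y`` (N×D), with D in {2, 3}.  Before the EM
iterations both sets are normalized to zero mean and unit mean-squared
point norm so that kernel widths and tolerances are comparable across
fixtures; the transform is inverted afterwards to report results in the
original (e.g. millimetre) coordinates.

Supported on-disk formats:

* delimited text — one point per row, 2 or 3 numeric columns separated by
  whitespace and/or commas; ``#`` starts a comment line.
* ASCII PLY — a ``vertex`` element with ``x``, ``y``, ``z`` properties
  (2-D sets are written with z = 0 and collapse back to 2-D on read when
  the z column is identically zero).
"""

from __future__ import annotations

import dataclasses
import os
from typing import Tuple

import numpy as np

__all__ = [
    "PointSet",
    "NormalizationParams",
    "read_pointset",
    "write_pointset",
    "normalize_pair",
    "denormalize",
]


@dataclasses.dataclass(frozen=True, eq=False)
class PointSet:
    """An ordered set of D-dimensional points (rows of ``coords``).

    Row order is meaningful for evaluation fixtures (row i of the target
    corresponds to row i of the template); the registration algorithm
    itself never consults it.
    """

    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2:
            raise ValueError("coords must be a 2-D array (points x dims)")
        if coords.shape[0] < 1:
            raise ValueError("a point set must contain at least one point")
        if coords.shape[1] not in (2, 3):
            raise ValueError(f"dimension must be 2 or 3, got {coords.shape[1]}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("all coordinates must be finite")
        object.__setattr__(self, "coords", coords)

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]


@dataclasses.dataclass(frozen=True)
class NormalizationParams:
    """Isotropic affine normalization: x_norm = (x - center) / scale."""

    center: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float).ravel()
        if not self.scale > 0:
            raise ValueError("scale must be positive")
        object.__setattr__(self, "center", center)


def _parse_delimited(path: str) -> np.ndarray:
    rows = []
    ncols = None
    with open(path, "r") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            fields = line.replace(",", " ").split()
            try:
                values = [float(f) for f in fields]
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: malformed row: {exc}") from None
            if ncols is None:
                ncols = len(values)
                if ncols not in (2, 3):
                    raise ValueError(
                        f"{path}: line {lineno}: expected 2 or 3 columns, got {ncols}"
                    )
            elif len(values) != ncols:
                raise ValueError(
                    f"{path}: line {lineno}: expected {ncols} columns, got {len(values)}"
                )
            rows.append(values)
    if not rows:
        raise ValueError(f"{path}: no data rows found")
    return np.asarray(rows, dtype=float)


def _parse_ply(path: str) -> np.ndarray:
    with open(path, "r") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines or lines[0].strip() != "ply":
        raise ValueError(f"{path}: line 1: not a PLY file (missing 'ply' magic)")
    n_vertex = None
    props: list = []
    body_start = None
    in_vertex_element = False
    for i, line in enumerate(lines[1:], start=2):
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            if tok[1] != "ascii":
                raise ValueError(f"{path}: line {i}: only ASCII PLY is supported")
        elif tok[0] == "element":
            in_vertex_element = tok[1] == "vertex"
            if in_vertex_element:
                n_vertex = int(tok[2])
        elif tok[0] == "property" and in_vertex_element:
            props.append(tok[-1])
        elif tok[0] == "end_header":
            body_start = i  # 0-based index into `lines` is i (header line i is lines[i-1])
            break
    if n_vertex is None or body_start is None:
        raise ValueError(f"{path}: malformed PLY header (no vertex element/end_header)")
    for axis in ("x", "y"):
        if axis not in props:
            raise ValueError(f"{path}: vertex element lacks property '{axis}'")
    cols = [props.index(a) for a in ("x", "y", "z") if a in props]
    body = lines[body_start : body_start + n_vertex]
    if len(body) < n_vertex:
        raise ValueError(f"{path}: expected {n_vertex} vertex rows, found {len(body)}")
    data = []
    for j, line in enumerate(body):
        fields = line.split()
        if len(fields) < len(props):
            raise ValueError(
                f"{path}: line {body_start + 1 + j}: expected {len(props)} fields"
            )
        data.append([float(fields[c]) for c in cols])
    arr = np.asarray(data, dtype=float)
    if arr.shape[1] == 3 and np.all(arr[:, 2] == 0.0):
        arr = arr[:, :2]  # 2-D sets round-trip through z = 0
    return arr


def read_pointset(path: str, format: str | None = None) -> PointSet:
    """Read a point set from a delimited text file or an ASCII PLY file.

    ``format`` is ``"delimited"`` or ``"ply"``; if omitted it is inferred
    from the file extension (``.ply`` -> PLY, anything else delimited).
    Row order is preserved.
    """
    if format is None:
        format = "ply" if os.path.splitext(path)[1].lower() == ".ply" else "delimited"
    if format == "delimited":
        return PointSet(_parse_delimited(path))
    if format == "ply":
        return PointSet(_parse_ply(path))
    raise ValueError(f"unknown format {format!r}")


def write_pointset(ps: PointSet, path: str, format: str | None = None) -> None:
    """Write a point set; delimited mode keeps full double precision."""
    if format is None:
        format = "ply" if os.path.splitext(path)[1].lower() == ".ply" else "delimited"
    if format == "delimited":
        with open(path, "w") as fh:
            for row in ps.coords:
                fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")
    elif format == "ply":
        coords = ps.coords
        if ps.dim == 2:
            coords = np.column_stack([coords, np.zeros(ps.n_points)])
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {ps.n_points}\n")
            fh.write("property float x\nproperty float y\nproperty float z\n")
            fh.write("end_header\n")
            for row in coords:
                fh.write(" ".join(f"{v:.10g}" for v in row) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def _normalize_one(coords: np.ndarray) -> Tuple[np.ndarray, NormalizationParams]:
    center = coords.mean(axis=0)
    centered = coords - center
    scale = float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))
    if scale <= 0.0 or not np.isfinite(scale):
        raise ValueError("degenerate point set: all points identical (scale 0)")
    return centered / scale, NormalizationParams(center=center, scale=scale)


def normalize_pair(
    X: PointSet, Y: PointSet, joint: bool = False
) -> Tuple[PointSet, PointSet, NormalizationParams, NormalizationParams]:
    """Normalize target and template to zero mean, unit mean-squared norm.

    By default each set is centered and scaled independently.  With
    ``joint=True`` both sets share one center and one scale computed from
    their concatenation (useful when the two sets must keep their relative
    offset).
    """
    if X.dim != Y.dim:
        raise ValueError(f"dimension mismatch: target D={X.dim}, template D={Y.dim}")
    if joint:
        stacked = np.vstack([X.coords, Y.coords])
        center = stacked.mean(axis=0)
        centered = stacked - center
        scale = float(np.sqrt(np.mean(np.sum(centered**2, axis=1))))
        if scale <= 0.0:
            raise ValueError("degenerate point sets: zero joint scale")
        params = NormalizationParams(center=center, scale=scale)
        Xn = PointSet((X.coords - center) / scale)
        Yn = PointSet((Y.coords - center) / scale)
        return Xn, Yn, params, params
    xcoords, px = _normalize_one(X.coords)
    ycoords, py = _normalize_one(Y.coords)
    return PointSet(xcoords), PointSet(ycoords), px, py


def denormalize(ps: PointSet, params: NormalizationParams) -> PointSet:
    """Map normalized coordinates back: x -> x * scale + center."""
    if params.center.shape[0] != ps.dim:
        raise ValueError(
            f"dimension mismatch: points are {ps.dim}-D, params are "
            f"{params.center.shape[0]}-D"
        )
    return PointSet(ps.coords * params.scale + params.center)
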