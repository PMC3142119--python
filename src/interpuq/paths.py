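"""Piecewise-linear path geometry and the no-new-inflexion plausibility rule.

The central object is a polyline through ordered ``(x, y)`` points — a
candidate interpolation of a sparse quantitative series. Its *inflexion
count* is the number of sign alternations in the sequence of gradient
changes (second differences of the polyline), after gradient changes of
(numerically) zero magnitude are dropped. A candidate path is *plausible*
when its inflexion count does not exceed that of a reference path, usually
the path through the measured points alone: the biological reading is that
no unobserved regulatory event is postulated between measurements.

Everything downstream (envelope bounds, the Monte Carlo sampler, the direct
dynamic-programming method) reduces to evaluating this predicate on large
batches of candidate paths, so a vectorised counter over stacked y-rows is
provided alongside the scalar one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: gradient changes with magnitude at or below this are treated as flat
#: (neither a positive nor a negative curvature event) and skipped.
DEFAULT_ZERO_TOL = 1e-12


class InvalidPathError(ValueError):
    """Path has fewer than two points or non-increasing x values."""


@dataclass(frozen=True)
class Path:
    """An ordered polyline with strictly increasing x.

    Parameters
    ----------
    x, y : array-like
        Coordinates of the vertices; ``x`` must be strictly increasing and
        contain at least two points.
    """

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 1 or y.shape != x.shape:
            raise InvalidPathError("x and y must be 1-d arrays of equal length")
        if x.size < 2:
            raise InvalidPathError("a path needs at least two points")
        if not np.all(np.diff(x) > 0):
            raise InvalidPathError("x must be strictly increasing (no duplicates)")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return int(self.x.size)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.x[0]), float(self.x[-1])

    def value_at(self, x):
        """Linear interpolation of the polyline at ``x`` (scalar or array)."""
        return np.interp(x, self.x, self.y)

    def insert(self, xs, ys) -> "Path":
        """Return a new path with extra vertices merged in x-order."""
        xs = np.atleast_1d(np.asarray(xs, dtype=float))
        ys = np.atleast_1d(np.asarray(ys, dtype=float))
        x_new = np.concatenate([self.x, xs])
        y_new = np.concatenate([self.y, ys])
        order = np.argsort(x_new, kind="stable")
        return Path(x_new[order], y_new[order])

    def mirrored(self) -> "Path":
        """The path reflected in x (reverses the direction of time)."""
        return Path(-self.x[::-1], self.y[::-1].copy())


def count_inflexions_many(x, Y, zero_tol: float = DEFAULT_ZERO_TOL) -> np.ndarray:
    """Inflexion counts for a batch of paths sharing one x grid.

    Parameters
    ----------
    x : (L,) array
        Strictly increasing abscissae shared by every row.
    Y : (..., L) array
        Stacked y-rows; one count is returned per leading index.

    Returns
    -------
    ndarray of int
        Number of adjacent sign alternations among the nonzero second
        differences of each row.
    """
    x = np.asarray(x, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InvalidPathError("a path needs at least two points")
    dx = np.diff(x)
    if np.any(dx <= 0):
        raise InvalidPathError("x must be strictly increasing (no duplicates)")
    if Y.shape[-1] != x.size:
        raise InvalidPathError("Y rows must match the length of x")
    grad = np.diff(Y, axis=-1) / dx
    d2 = np.diff(grad, axis=-1)
    m = d2.shape[-1]
    counts = np.zeros(Y.shape[:-1], dtype=np.int64)
    if m < 2:
        return counts
    sign = (d2 > zero_tol).astype(np.int8) - (d2 < -zero_tol).astype(np.int8)
    idx = np.arange(m)
    # index of the most recent nonzero sign at or before each position
    last_nz = np.maximum.accumulate(np.where(sign != 0, idx, -1), axis=-1)
    prev = last_nz[..., :-1]
    cur = sign[..., 1:]
    prev_sign = np.take_along_axis(sign, np.maximum(prev, 0), axis=-1)
    alt = (cur != 0) & (prev >= 0) & (prev_sign == -cur)
    np.sum(alt, axis=-1, out=counts)
    return counts


def count_inflexions(path: Path, zero_tol: float = DEFAULT_ZERO_TOL) -> int:
    """Inflexion count of a single path (see :func:`count_inflexions_many`)."""
    return int(count_inflexions_many(path.x, path.y[None, :], zero_tol)[0])


def plausible_many(
    x,
    Y,
    reference_count: int,
    acceptance: str = "le",
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> np.ndarray:
    """Vectorised plausibility predicate over stacked y-rows."""
    counts = count_inflexions_many(x, Y, zero_tol)
    if acceptance == "le":
        return counts <= reference_count
    if acceptance == "eq":
        return counts == reference_count
    raise ValueError(f"acceptance must be 'le' or 'eq', got {acceptance!r}")


def is_plausible(
    path: Path,
    reference_count: int,
    acceptance: str = "le",
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> bool:
    """True iff the path introduces no inflexions beyond the reference count."""
    return bool(
        plausible_many(path.x, path.y[None, :], reference_count, acceptance, zero_tol)[0]
    )


def guide_positions(x_measured) -> np.ndarray:
    """Guide abscissae: two per measured interval, at the trisection points."""
    x = np.asarray(x_measured, dtype=float)
    if x.size < 2:
        raise InvalidPathError("need at least two measured points")
    left = x[:-1]
    width = np.diff(x)
    gx = np.empty(2 * width.size)
    gx[0::2] = left + width / 3.0
    gx[1::2] = left + 2.0 * width / 3.0
    return gx


def merge_with_slots(path: Path, insert_x) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Merge insertion abscissae into a path template for batch evaluation.

    Returns ``(x_full, y_base, slots)`` where ``y_base`` holds the path's
    values with NaN at the inserted positions and ``slots[k]`` is the index
    in ``x_full`` of the k-th inserted abscissa. Callers tile ``y_base`` and
    fill the slots with candidate y values.
    """
    insert_x = np.atleast_1d(np.asarray(insert_x, dtype=float))
    xs = np.concatenate([path.x, insert_x])
    ys = np.concatenate([path.y, np.full(insert_x.size, np.nan)])
    tag = np.concatenate([np.full(len(path), -1), np.arange(insert_x.size)])
    order = np.argsort(xs, kind="stable")
    x_full, y_base, tag = xs[order], ys[order], tag[order]
    if np.any(np.diff(x_full) <= 0):
        raise InvalidPathError("inserted x collides with an existing vertex")
    slots = np.empty(insert_x.size, dtype=np.int64)
    slots[tag[tag >= 0]] = np.nonzero(tag >= 0)[0]
    return x_full, y_base, slots
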