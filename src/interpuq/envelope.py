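"""Plausible-interpolation bounds.

At any abscissa x strictly between measurements, the plausible set is the
interval of y values for which inserting the single point (x, y) into the
measured path keeps the inflexion count within the reference. The zero-error
bounds scan a clipped search window and refine each edge by bisection.
Under measurement error the bounds become the union, over all 2^n
assignments of each measurement to its lower or upper confidence limit
("corners"), of the corner paths' own bounds — plus the all-mean assignment,
so the union always contains the mean path's bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import MeasurementSeries
from .paths import (
    DEFAULT_ZERO_TOL,
    Path,
    count_inflexions,
    guide_positions,
    merge_with_slots,
    plausible_many,
)

DEFAULT_CLIP_FACTOR = 1.0
DEFAULT_CORNER_CAP = 12  # exact enumeration up to 2^12 corners
DEFAULT_CORNER_SAMPLES = 4096


class OutOfRangeError(ValueError):
    """Requested abscissa lies outside the measured range."""


class ConfigurationError(ValueError):
    """A measurement lacks the confidence interval the operation needs."""


@dataclass(frozen=True)
class BoundsFunction:
    """Envelope bounds on a grid of abscissae, linear between grid points."""

    xs: np.ndarray
    lo: np.ndarray
    hi: np.ndarray

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if np.any(x < self.xs[0] - 1e-12) or np.any(x > self.xs[-1] + 1e-12):
            raise OutOfRangeError("x outside the measured range")
        return np.interp(x, self.xs, self.lo), np.interp(x, self.xs, self.hi)

    @property
    def domain(self) -> tuple[float, float]:
        return float(self.xs[0]), float(self.xs[-1])


def _search_window(points: Path, clip_factor: float) -> tuple[float, float]:
    ymin, ymax = float(points.y.min()), float(points.y.max())
    span = ymax - ymin
    return ymin - clip_factor * span, ymax + clip_factor * span


def pointwise_bounds(
    points: Path,
    x: float,
    reference_count: int | None = None,
    clip_factor: float = DEFAULT_CLIP_FACTOR,
    acceptance: str = "le",
    zero_tol: float = DEFAULT_ZERO_TOL,
    scan_grid: int = 64,
    refine_iters: int = 60,
) -> tuple[float, float]:
    """Min and max y whose single insertion at x keeps the path plausible.

    Candidates are scanned on a grid over the clipped window
    ``[ymin - c*R, ymax + c*R]`` (R the measured y-range, c the clip
    factor) and the plausible interval's edges are refined by bisection.
    If every candidate in the window is plausible — as happens when too few
    points surround x to force a curvature sign — the clipped window itself
    is returned.
    """
    x = float(x)
    if not points.x[0] < x < points.x[-1]:
        raise OutOfRangeError(f"x={x:g} outside measured range {points.span}")
    if np.any(points.x == x):
        raise ValueError(f"x={x:g} coincides with a measured point")
    ref = count_inflexions(points, zero_tol) if reference_count is None else reference_count

    x_full, y_base, slots = merge_with_slots(points, [x])
    slot = int(slots[0])

    def plaus(ys: np.ndarray) -> np.ndarray:
        Y = np.broadcast_to(y_base, (ys.size, y_base.size)).copy()
        Y[:, slot] = ys
        return plausible_many(x_full, Y, ref, acceptance, zero_tol)

    w_lo, w_hi = _search_window(points, clip_factor)
    if w_hi <= w_lo:  # constant series: only the line is available
        return w_lo, w_hi
    # the collinear insertion never changes the count, so it anchors the interval
    anchor = float(points.value_at(x))
    grid = np.unique(np.concatenate([np.linspace(w_lo, w_hi, scan_grid), [anchor]]))
    ok = plaus(grid)
    if not ok.any():  # numerically possible only in pathological configs
        grid, ok = np.array([anchor]), np.array([True])
    in_lo = float(grid[ok].min())
    in_hi = float(grid[ok].max())

    below = grid[(~ok) & (grid < in_lo)]
    above = grid[(~ok) & (grid > in_hi)]
    # refine both edges together: y_in is always on the plausible side
    y_out = np.array(
        [below.max() if below.size else w_lo, above.min() if above.size else w_hi]
    )
    y_in = np.array([in_lo, in_hi])
    if below.size or above.size:
        for _ in range(refine_iters):
            mid = 0.5 * (y_out + y_in)
            good = plaus(mid)
            y_in = np.where(good, mid, y_in)
            y_out = np.where(good, y_out, mid)
    lo = w_lo if below.size == 0 else float(y_in[0])
    hi = w_hi if above.size == 0 else float(y_in[1])
    return lo, hi


def corner_paths(
    series: MeasurementSeries,
    corner_cap: int = DEFAULT_CORNER_CAP,
    corner_samples: int = DEFAULT_CORNER_SAMPLES,
    seed: int = 0,
) -> list[Path]:
    """Measurement paths for all CI-corner assignments, plus the mean path.

    Each corner sets every measurement to its lower or upper confidence
    limit. Exact enumeration covers n <= ``corner_cap`` measurements;
    beyond that a seeded random subsample of ``corner_samples`` corners is
    used (logged via a warning), always together with the all-mean
    assignment.
    """
    for meas in series.measurements:
        if meas.ci_lo is None or meas.ci_hi is None:
            raise ConfigurationError(f"measurement at t={meas.t:g} lacks a CI")
    t = series.times
    means = series.means
    hw = np.array([meas.half_width for meas in series.measurements])
    if np.all(hw == 0.0):
        return [Path(t, means)]
    n = len(series)
    if n <= corner_cap:
        signs = np.array(
            [[1 if (i >> k) & 1 else -1 for k in range(n)] for i in range(2**n)]
        )
    else:
        warnings.warn(
            f"{n} measurements imply 2^{n} corners; sampling {corner_samples} "
            "plus the all-mean assignment",
            RuntimeWarning,
            stacklevel=2,
        )
        rng = np.random.default_rng(seed)
        signs = rng.choice([-1, 1], size=(corner_samples, n))
    paths = [Path(t, means + s * hw) for s in signs]
    paths.append(Path(t, means))  # guarantees union >= mean-path bounds
    return paths


def corner_union_bounds(
    series: MeasurementSeries,
    x: float,
    clip_factor: float = DEFAULT_CLIP_FACTOR,
    acceptance: str = "le",
    zero_tol: float = DEFAULT_ZERO_TOL,
    corner_cap: int = DEFAULT_CORNER_CAP,
    corner_samples: int = DEFAULT_CORNER_SAMPLES,
    seed: int = 0,
) -> tuple[float, float]:
    """Union of pointwise bounds over CI-corner assignments at one x.

    Every corner uses its own reference inflexion count, since different
    corner assignments imply different shapes.
    """
    lo, hi = np.inf, -np.inf
    for path in corner_paths(series, corner_cap, corner_samples, seed):
        c_lo, c_hi = pointwise_bounds(
            path, x, clip_factor=clip_factor, acceptance=acceptance, zero_tol=zero_tol
        )
        lo, hi = min(lo, c_lo), max(hi, c_hi)
    return lo, hi


def pointwise_bounds_function(
    points: Path,
    xs=None,
    clip_factor: float = DEFAULT_CLIP_FACTOR,
    acceptance: str = "le",
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> BoundsFunction:
    """Zero-error bounds evaluated on a grid (default: measured + guide x)."""
    if xs is None:
        xs = np.sort(np.concatenate([points.x, guide_positions(points.x)]))
    xs = np.asarray(xs, dtype=float)
    lo = np.empty(xs.size)
    hi = np.empty(xs.size)
    for i, x in enumerate(xs):
        if np.any(points.x == x):
            y = float(points.y[points.x == x][0])
            lo[i] = hi[i] = y
        else:
            lo[i], hi[i] = pointwise_bounds(
                points, x, clip_factor=clip_factor, acceptance=acceptance,
                zero_tol=zero_tol,
            )
    return BoundsFunction(xs=xs, lo=lo, hi=hi)


def union_bounds_function(
    series: MeasurementSeries,
    xs=None,
    clip_factor: float = DEFAULT_CLIP_FACTOR,
    acceptance: str = "le",
    zero_tol: float = DEFAULT_ZERO_TOL,
    corner_cap: int = DEFAULT_CORNER_CAP,
    corner_samples: int = DEFAULT_CORNER_SAMPLES,
    seed: int = 0,
) -> BoundsFunction:
    """Corner-union bounds on a grid (default: measured + guide abscissae).

    At a measured abscissa the interval is the measurement's confidence
    interval, which the union of corner paths attains exactly.
    """
    t = series.times
    if xs is None:
        xs = np.sort(np.concatenate([t, guide_positions(t)]))
    xs = np.asarray(xs, dtype=float)
    paths = corner_paths(series, corner_cap, corner_samples, seed)
    refs = [count_inflexions(p, zero_tol) for p in paths]
    lo = np.full(xs.size, np.inf)
    hi = np.full(xs.size, -np.inf)
    for i, x in enumerate(xs):
        at = np.nonzero(t == x)[0]
        if at.size:
            meas = series.measurements[int(at[0])]
            lo[i], hi[i] = meas.ci_lo, meas.ci_hi
            continue
        for path, ref in zip(paths, refs):
            c_lo, c_hi = pointwise_bounds(
                path, x, reference_count=ref, clip_factor=clip_factor,
                acceptance=acceptance, zero_tol=zero_tol,
            )
            lo[i] = min(lo[i], c_lo)
            hi[i] = max(hi[i], c_hi)
    return BoundsFunction(xs=xs, lo=lo, hi=hi)
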