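"""Direct computation of guide-point likelihood distributions.

Instead of discovering plausible interpolations by trial and error, the
direct method discretises the envelope span at each guide abscissa into V
equal-width intervals (each represented by its midpoint) and propagates
probability vectors along the column sequence:

* a *left* pass starts from a uniform vector on the leftmost guide column
  and sweeps right, weighting each midpoint by the plausibility-masked mass
  of the previous column;
* a *right* pass mirrors this from the rightmost column;
* a *joint* combination sets the end columns to their single directional
  vector and, for interior columns, sums plausibility-masked products of
  the left neighbour's left-conditional mass and the right neighbour's
  right-conditional mass.

Plausibility of every candidate is judged on the full merged path (all
measured points plus the inserted guide points), so the passes are a local
approximation to the exact global-constraint marginals; the exact marginals
are available from :func:`enumerate_joint_oracle` for small problems and
serve as the validation oracle.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .paths import (
    DEFAULT_ZERO_TOL,
    Path,
    count_inflexions,
    guide_positions,
    merge_with_slots,
    plausible_many,
)

DEFAULT_GRID = 40  # V: intervals per guide column


class DegenerateConstraintError(RuntimeError):
    """No midpoint combination satisfies the plausibility constraint."""


@dataclass
class GuideColumn:
    """Discretised y-grid at one guide abscissa.

    ``midpoints`` are the centres of V equal-width intervals of
    ``[lo, hi]``; the probability vectors are filled by the passes.
    """

    x: float
    lo: float
    hi: float
    midpoints: np.ndarray
    p_left: np.ndarray | None = None
    p_right: np.ndarray | None = None
    p_joint: np.ndarray | None = None

    @property
    def n_intervals(self) -> int:
        return int(self.midpoints.size)

    @property
    def bin_width(self) -> float:
        return (self.hi - self.lo) / self.n_intervals


def discretize_column(lo: float, hi: float, x: float, V: int) -> GuideColumn:
    """Split ``[lo, hi]`` into V equal-width intervals represented by midpoints."""
    if V < 1:
        raise ValueError("V must be at least 1")
    if hi < lo:
        raise ValueError("hi must not be below lo")
    mids = lo + (np.arange(V) + 0.5) * (hi - lo) / V
    return GuideColumn(x=float(x), lo=float(lo), hi=float(hi), midpoints=mids)


def make_columns(measured: Path, bounds, V: int = DEFAULT_GRID) -> list[GuideColumn]:
    """Discretised guide columns at the trisection points of a measured path."""
    gx = guide_positions(measured.x)
    lo, hi = bounds(gx)
    lo = np.atleast_1d(lo)
    hi = np.atleast_1d(hi)
    return [discretize_column(lo[j], hi[j], gx[j], V) for j in range(gx.size)]


def _normalize(w: np.ndarray, where: str) -> np.ndarray:
    total = w.sum()
    if total <= 0:
        warnings.warn(
            f"all-zero probability column at {where}; falling back to uniform",
            RuntimeWarning,
            stacklevel=3,
        )
        return np.full(w.size, 1.0 / w.size)
    return w / total


def _pair_matrix(
    measured: Path,
    x_a: float,
    mids_a: np.ndarray,
    x_b: float,
    mids_b: np.ndarray,
    reference_count: int,
    acceptance: str,
    zero_tol: float,
) -> np.ndarray:
    """Boolean matrix M[i, j]: measured + (x_a, mids_a[i]) + (x_b, mids_b[j]) plausible."""
    x_full, y_base, slots = merge_with_slots(measured, [x_a, x_b])
    Y = np.broadcast_to(y_base, (mids_a.size, mids_b.size, y_base.size)).copy()
    Y[..., slots[0]] = mids_a[:, None]
    Y[..., slots[1]] = mids_b[None, :]
    return plausible_many(x_full, Y, reference_count, acceptance, zero_tol)


def _triple_tensor(
    measured: Path,
    xs: tuple[float, float, float],
    mids: tuple[np.ndarray, np.ndarray, np.ndarray],
    reference_count: int,
    acceptance: str,
    zero_tol: float,
) -> np.ndarray:
    """Boolean tensor T[a, b, c] for a triple guide insertion."""
    x_full, y_base, slots = merge_with_slots(measured, list(xs))
    Va, Vb, Vc = (m.size for m in mids)
    Y = np.broadcast_to(y_base, (Va, Vb, Vc, y_base.size)).copy()
    Y[..., slots[0]] = mids[0][:, None, None]
    Y[..., slots[1]] = mids[1][None, :, None]
    Y[..., slots[2]] = mids[2][None, None, :]
    return plausible_many(x_full, Y, reference_count, acceptance, zero_tol)


def directional_pass(
    columns: list[GuideColumn],
    measured: Path,
    direction: str,
    reference_count: int | None = None,
    acceptance: str = "le",
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> list[GuideColumn]:
    """Fill ``p_left`` (direction 'left') or ``p_right`` (direction 'right').

    The boundary column nearest the sweep origin gets the uniform vector;
    each subsequent column's midpoint weights are the plausibility-masked
    sums over the previously processed adjacent column, then normalised.
    Columns are modified in place and returned.
    """
    if direction not in ("left", "right"):
        raise ValueError("direction must be 'left' or 'right'")
    if not columns:
        raise ValueError("no guide columns")
    ref = count_inflexions(measured, zero_tol) if reference_count is None else reference_count
    order = range(len(columns)) if direction == "left" else range(len(columns) - 1, -1, -1)
    order = list(order)
    attr = "p_left" if direction == "left" else "p_right"

    start = columns[order[0]]
    setattr(start, attr, np.full(start.n_intervals, 1.0 / start.n_intervals))
    for prev_i, cur_i in zip(order[:-1], order[1:]):
        prev, cur = columns[prev_i], columns[cur_i]
        M = _pair_matrix(
            measured, cur.x, cur.midpoints, prev.x, prev.midpoints,
            ref, acceptance, zero_tol,
        )
        w = M.astype(float) @ getattr(prev, attr)
        setattr(cur, attr, _normalize(w, f"x={cur.x:g} ({direction} pass)"))
    return columns


def joint_combine(
    columns: list[GuideColumn],
    measured: Path,
    reference_count: int | None = None,
    acceptance: str = "le",
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> list[GuideColumn]:
    """Fill ``p_joint`` from completed left and right passes.

    The first guide column's joint vector is its right-conditional vector
    and the last column's is its left-conditional vector; interior columns
    combine the left neighbour's ``p_left`` and right neighbour's
    ``p_right`` through the triple plausibility constraint.
    """
    if any(c.p_left is None or c.p_right is None for c in columns):
        raise RuntimeError("run both directional passes before joint_combine")
    ref = count_inflexions(measured, zero_tol) if reference_count is None else reference_count
    columns[0].p_joint = columns[0].p_right.copy()
    columns[-1].p_joint = columns[-1].p_left.copy()
    for j in range(1, len(columns) - 1):
        left, cur, right = columns[j - 1], columns[j], columns[j + 1]
        T = _triple_tensor(
            measured,
            (left.x, cur.x, right.x),
            (left.midpoints, cur.midpoints, right.midpoints),
            ref, acceptance, zero_tol,
        )
        w = np.einsum("abc,a,c->b", T.astype(float), left.p_left, right.p_right)
        cur.p_joint = _normalize(w, f"x={cur.x:g} (joint)")
    return columns


def enumerate_joint_oracle(
    columns: list[GuideColumn],
    measured: Path,
    reference_count: int | None = None,
    acceptance: str = "le",
    zero_tol: float = DEFAULT_ZERO_TOL,
    cap: int = 10**6,
    chunk: int = 1 << 16,
) -> list[np.ndarray]:
    """Exact per-column marginals by exhaustive midpoint enumeration.

    Enumerates every combination of one midpoint per guide column, keeps
    those whose fully merged path is plausible, and returns the normalised
    per-column marginals under a uniform prior over combinations. Test
    oracle for the passes and the Monte Carlo sampler; refuses problems
    larger than ``cap`` combinations.
    """
    ref = count_inflexions(measured, zero_tol) if reference_count is None else reference_count
    sizes = [c.n_intervals for c in columns]
    total = math.prod(sizes)
    if total > cap:
        raise ValueError(
            f"enumeration size {total} = {'x'.join(map(str, sizes))} exceeds cap {cap}"
        )
    gx = np.array([c.x for c in columns])
    x_full, y_base, slots = merge_with_slots(measured, gx)

    counts = [np.zeros(V) for V in sizes]
    n_keep = 0
    for lo_i in range(0, total, chunk):
        flat = np.arange(lo_i, min(lo_i + chunk, total))
        idx = np.empty((flat.size, len(sizes)), dtype=np.int64)
        rem = flat
        for j in range(len(sizes) - 1, -1, -1):
            idx[:, j] = rem % sizes[j]
            rem = rem // sizes[j]
        Y = np.broadcast_to(y_base, (flat.size, y_base.size)).copy()
        for j, col in enumerate(columns):
            Y[:, slots[j]] = col.midpoints[idx[:, j]]
        ok = plausible_many(x_full, Y, ref, acceptance, zero_tol)
        n_keep += int(ok.sum())
        for j in range(len(sizes)):
            counts[j] += np.bincount(idx[ok, j], minlength=sizes[j])
    if n_keep == 0:
        raise DegenerateConstraintError("no plausible midpoint combination exists")
    return [c / n_keep for c in counts]


@dataclass
class FieldColumn:
    """One column of a likelihood field: a measured point or a guide column."""

    x: float
    kind: str  # "measured" | "guide"
    lo: float
    hi: float
    midpoints: np.ndarray
    p_joint: np.ndarray
    p_left: np.ndarray | None = None
    p_right: np.ndarray | None = None
    measurement: object | None = None  # errors.Measurement for measured columns


@dataclass
class LikelihoodField:
    """Normalised likelihood distributions over all columns of one series."""

    series_id: str
    columns: list[FieldColumn]
    reference_count: int
    meta: dict = field(default_factory=dict)

    @property
    def guide_columns(self) -> list[FieldColumn]:
        return [c for c in self.columns if c.kind == "guide"]

    @property
    def measured_columns(self) -> list[FieldColumn]:
        return [c for c in self.columns if c.kind == "measured"]


def compute_field(
    measured: Path,
    bounds,
    V: int = DEFAULT_GRID,
    reference_count: int | None = None,
    acceptance: str = "le",
    zero_tol: float = DEFAULT_ZERO_TOL,
    series_id: str = "series",
    measurements: list | None = None,
) -> LikelihoodField:
    """Zero-error direct-method field for one representative measured path.

    ``measurements``, when given, must parallel the measured vertices and is
    attached to the measured columns (used downstream for t-based intervals).
    """
    ref = count_inflexions(measured, zero_tol) if reference_count is None else reference_count
    cols = make_columns(measured, bounds, V)
    directional_pass(cols, measured, "left", ref, acceptance, zero_tol)
    directional_pass(cols, measured, "right", ref, acceptance, zero_tol)
    joint_combine(cols, measured, ref, acceptance, zero_tol)

    out: list[FieldColumn] = []
    for i, (mx, my) in enumerate(zip(measured.x, measured.y)):
        out.append(
            FieldColumn(
                x=float(mx), kind="measured", lo=float(my), hi=float(my),
                midpoints=np.array([my]), p_joint=np.array([1.0]),
                measurement=None if measurements is None else measurements[i],
            )
        )
    for c in cols:
        out.append(
            FieldColumn(
                x=c.x, kind="guide", lo=c.lo, hi=c.hi, midpoints=c.midpoints,
                p_joint=c.p_joint, p_left=c.p_left, p_right=c.p_right,
            )
        )
    out.sort(key=lambda col: col.x)
    return LikelihoodField(
        series_id=series_id,
        columns=out,
        reference_count=ref,
        meta={"V": V, "acceptance": acceptance, "method": "direct"},
    )
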