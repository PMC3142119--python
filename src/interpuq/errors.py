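"""Replicate summarisation and the measurement-error model.

Each measured time point carries a handful of replicate values. These are
summarised by a t-based confidence interval for the mean (99% by default);
the interval is then split into m sub-intervals of *variable width but
equal probability* under the scaled-t sampling distribution of the mean,
each represented by its arithmetic midpoint. Latin Hypercube Sampling over
these equal-mass strata — one independently Fisher-Yates-permuted midpoint
rank per measurement and cycle — yields a small set of measurement
realizations whose likelihood fields are averaged into a single field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .direct import FieldColumn, LikelihoodField
from .paths import DEFAULT_ZERO_TOL, Path, count_inflexions

DEFAULT_CONF = 0.99
DEFAULT_CI_BINS = 20  # m: equal-probability sub-intervals per confidence interval
DEFAULT_LHS_CYCLES = 20


class InsufficientReplicatesError(ValueError):
    """A single replicate without an externally supplied sd has no CI."""


def summarize_replicates(
    values,
    conf_level: float = DEFAULT_CONF,
    sd: float | None = None,
) -> tuple[float, float, int, float]:
    """Mean, sd and t-based CI half-width of a set of replicate values.

    Returns ``(mean, sd, n, half_width)`` with
    ``half_width = t_{(1+conf)/2, n-1} * sd / sqrt(n)``. With a single
    value an external ``sd`` must be supplied; the normal quantile is used
    then, since a t distribution with zero degrees of freedom is undefined.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 1:
        raise ValueError("values must be a non-empty 1-d sequence")
    if not 0.0 <= conf_level < 1.0:
        raise ValueError("conf_level must be in [0, 1)")
    n = int(values.size)
    mean = float(values.mean())
    if n == 1:
        if sd is None:
            raise InsufficientReplicatesError(
                "one replicate and no external sd: confidence interval undefined"
            )
        s = float(sd)
    else:
        if sd is not None:
            raise ValueError("external sd is only accepted for single-replicate points")
        # identical replicates have exactly zero dispersion; np.std can
        # return ~1e-18 on them through mean-subtraction rounding
        s = 0.0 if np.ptp(values) == 0 else float(values.std(ddof=1))
    if conf_level == 0.0 or s == 0.0:
        return mean, s, n, 0.0
    q = (1.0 + conf_level) / 2.0
    t_crit = stats.norm.ppf(q) if n == 1 else stats.t.ppf(q, df=n - 1)
    return mean, s, n, float(t_crit * s / np.sqrt(n))


@dataclass(frozen=True)
class Measurement:
    """One time point: replicate values plus their t-based CI.

    ``sd_external`` feeds single-replicate points whose dispersion is known
    from elsewhere (e.g. a pooled error model).
    """

    t: float
    values: tuple[float, ...]
    conf_level: float = DEFAULT_CONF
    sd_external: float | None = None
    # derived (filled in __post_init__)
    mean: float = field(init=False)
    sd: float = field(init=False)
    n_reps: int = field(init=False)
    ci_lo: float = field(init=False)
    ci_hi: float = field(init=False)

    def __post_init__(self) -> None:
        mean, sd, n, hw = summarize_replicates(
            self.values, self.conf_level, self.sd_external
        )
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", sd)
        object.__setattr__(self, "n_reps", n)
        object.__setattr__(self, "ci_lo", mean - hw)
        object.__setattr__(self, "ci_hi", mean + hw)

    @property
    def half_width(self) -> float:
        return (self.ci_hi - self.ci_lo) / 2.0

    def _mean_dist(self):
        """Sampling distribution of the mean (scaled t, or normal for n=1)."""
        scale = self.sd / np.sqrt(self.n_reps)
        if self.n_reps == 1:
            return stats.norm(loc=self.mean, scale=scale)
        return stats.t(df=self.n_reps - 1, loc=self.mean, scale=scale)


def equal_probability_midpoints(measurement: Measurement, m: int) -> np.ndarray:
    """Midpoints of m equal-probability sub-intervals of the CI.

    Sub-interval boundaries sit at the quantiles of the mean's sampling
    distribution at cumulative probabilities ``(1-conf)/2 + j*conf/m``
    (j = 0..m), so each sub-interval carries mass ``conf/m``; the
    representative value of each is the arithmetic midpoint of its
    boundaries. A degenerate CI collapses every midpoint onto the mean.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    conf = measurement.conf_level
    if conf == 0.0 or measurement.sd == 0.0:
        return np.full(m, measurement.mean)
    levels = (1.0 - conf) / 2.0 + conf * np.arange(m + 1) / m
    bounds = measurement._mean_dist().ppf(levels)
    return (bounds[:-1] + bounds[1:]) / 2.0


@dataclass
class MeasurementSeries:
    """Ordered measurements of one series (a gene, or a PC score)."""

    series_id: str
    measurements: list[Measurement]

    def __post_init__(self) -> None:
        self.measurements = sorted(self.measurements, key=lambda meas: meas.t)
        t = self.times
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("series needs at least two distinct, ordered time points")

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def times(self) -> np.ndarray:
        return np.array([meas.t for meas in self.measurements])

    @property
    def means(self) -> np.ndarray:
        return np.array([meas.mean for meas in self.measurements])

    def mean_path(self) -> Path:
        return Path(self.times, self.means)

    @classmethod
    def from_arrays(
        cls,
        series_id: str,
        times,
        replicate_values,
        conf_level: float = DEFAULT_CONF,
    ) -> "MeasurementSeries":
        """Build a series from times and per-time replicate value lists."""
        measurements = [
            Measurement(t=float(t), values=tuple(vals), conf_level=conf_level)
            for t, vals in zip(times, replicate_values)
        ]
        return cls(series_id=series_id, measurements=measurements)


@dataclass(frozen=True)
class Realization:
    """One LHS draw: a rank-selected midpoint per measurement."""

    values: np.ndarray
    reference_count: int
    path: Path


def fisher_yates_shuffle(rng: np.random.Generator, n: int) -> np.ndarray:
    """Index permutation of range(n) by the classic Fisher-Yates walk."""
    idx = np.arange(n)
    for i in range(n - 1, 0, -1):
        j = int(rng.integers(0, i + 1))
        idx[i], idx[j] = idx[j], idx[i]
    return idx


def lhs_realizations(
    series: MeasurementSeries,
    cycles: int = DEFAULT_LHS_CYCLES,
    m: int = DEFAULT_CI_BINS,
    seed: int = 0,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> list[Realization]:
    """Latin Hypercube draws over each measurement's equal-mass strata.

    Each measurement's m midpoints are permuted independently by a seeded
    Fisher-Yates shuffle; realization k collects every measurement's k-th
    ranked permuted midpoint. Each realization records the inflexion count
    of its own representative path.
    """
    if cycles < 1:
        raise ValueError("cycles must be at least 1")
    if cycles > m:
        raise ValueError(f"cycles ({cycles}) cannot exceed m ({m})")
    rng = np.random.default_rng(seed)
    mids = np.stack([equal_probability_midpoints(meas, m) for meas in series.measurements])
    perms = np.stack([fisher_yates_shuffle(rng, m) for _ in series.measurements])
    t = series.times
    out: list[Realization] = []
    for k in range(cycles):
        vals = mids[np.arange(len(series)), perms[:, k]]
        path = Path(t, vals)
        out.append(
            Realization(
                values=vals,
                reference_count=count_inflexions(path, zero_tol),
                path=path,
            )
        )
    return out


def aggregate_fields(fields: list[LikelihoodField]) -> LikelihoodField:
    """Equal-weight mixture of per-realization likelihood fields.

    Guide columns average their joint vectors (then renormalise); measured
    columns pool the realizations' representative values with uniform
    weights. All fields must share column abscissae and guide grids.
    """
    if not fields:
        raise ValueError("no fields to aggregate")
    first = fields[0]
    for other in fields[1:]:
        if len(other.columns) != len(first.columns):
            raise ValueError("fields have mismatched column counts")
        for a, b in zip(first.columns, other.columns):
            if a.kind != b.kind or not np.isclose(a.x, b.x):
                raise ValueError("fields have mismatched column abscissae")
            if a.kind == "guide" and not np.allclose(a.midpoints, b.midpoints):
                raise ValueError("fields have mismatched guide grids")

    columns: list[FieldColumn] = []
    for j, col in enumerate(first.columns):
        if col.kind == "guide":
            p = np.mean([f.columns[j].p_joint for f in fields], axis=0)
            p = p / p.sum()
            columns.append(
                FieldColumn(
                    x=col.x, kind="guide", lo=col.lo, hi=col.hi,
                    midpoints=col.midpoints.copy(), p_joint=p,
                )
            )
        else:
            pooled = np.unique(
                np.concatenate([f.columns[j].midpoints for f in fields])
            )
            columns.append(
                FieldColumn(
                    x=col.x, kind="measured",
                    lo=float(pooled.min()), hi=float(pooled.max()),
                    midpoints=pooled,
                    p_joint=np.full(pooled.size, 1.0 / pooled.size),
                    measurement=col.measurement,
                )
            )
    meta = dict(first.meta)
    meta["aggregated"] = len(fields)
    return LikelihoodField(
        series_id=first.series_id,
        columns=columns,
        reference_count=first.reference_count,
        meta=meta,
    )
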