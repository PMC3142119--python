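"""Estimation pipeline and its evaluation: withholding, quantile envelopes,
coverage, PC1 summarisation and the synthetic calibration experiment.

``estimate_field`` runs the whole chain for one series: corner-union
envelope bounds, guide-column discretisation, the direct passes (or Monte
Carlo sampling), and — when measurements carry error — the Latin Hypercube
loop over measurement realizations. ``build_envelope_set`` turns a field
into nested central likelihood bands (20/75/95% by default) whose vertices
at guide and measured columns are connected by straight lines, and
``coverage`` scores withheld measurement means against those bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA

from . import direct as _direct
from . import errors as _errors
from . import montecarlo as _mc
from .envelope import OutOfRangeError, union_bounds_function
from .errors import Measurement, MeasurementSeries
from .paths import DEFAULT_ZERO_TOL, count_inflexions

DEFAULT_LEVELS = (0.20, 0.75, 0.95)


# ---------------------------------------------------------------------------
# withholding


def withhold(
    series: MeasurementSeries, pattern
) -> tuple[MeasurementSeries, list[Measurement]]:
    """Split a series into retained and withheld measurements.

    ``pattern`` is ``"every-other"`` (keep indices 0, 2, 4, ...),
    ``"every-third"`` (keep 0, 3, 6, ...) or an explicit sequence of
    indices to keep. The first and last time points must be retained —
    the estimator does not extrapolate.
    """
    n = len(series)
    if isinstance(pattern, str):
        step = {"every-other": 2, "every-third": 3}.get(pattern)
        if step is None:
            raise ValueError(f"unknown withholding pattern {pattern!r}")
        keep = set(range(0, n, step))
    else:
        keep = {int(i) for i in pattern}
        if not keep <= set(range(n)):
            raise ValueError("explicit indices out of range")
    if 0 not in keep or (n - 1) not in keep:
        raise ValueError("withholding must retain the first and last time points")
    retained = MeasurementSeries(
        series.series_id, [series.measurements[i] for i in sorted(keep)]
    )
    withheld = [series.measurements[i] for i in range(n) if i not in keep]
    return retained, withheld


# ---------------------------------------------------------------------------
# estimation pipeline


def estimate_field(
    series: MeasurementSeries,
    method: str = "direct",
    V: int = _direct.DEFAULT_GRID,
    m: int = _errors.DEFAULT_CI_BINS,
    cycles: int = _errors.DEFAULT_LHS_CYCLES,
    clip_factor: float = 1.0,
    acceptance: str = "le",
    zero_tol: float = DEFAULT_ZERO_TOL,
    seed: int = 0,
    error_model: str = "auto",
    mc_accept: int = 10000,
    bounds=None,
) -> _direct.LikelihoodField:
    """Likelihood field for one series.

    ``error_model`` is ``"auto"`` (use the LHS loop whenever any
    measurement has a nonzero CI), ``"on"`` or ``"off"``. The Monte Carlo
    route always works on the mean path; its histograms share the direct
    method's column grid. All randomness derives from ``seed``.
    """
    if method not in ("direct", "mc"):
        raise ValueError("method must be 'direct' or 'mc'")
    if error_model not in ("auto", "on", "off"):
        raise ValueError("error_model must be 'auto', 'on' or 'off'")
    ss = np.random.SeedSequence(seed)
    seed_bounds, seed_run = (int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2))
    if bounds is None:
        bounds = union_bounds_function(
            series, clip_factor=clip_factor, acceptance=acceptance,
            zero_tol=zero_tol, seed=seed_bounds,
        )
    mean_path = series.mean_path()

    if method == "mc":
        samples = _mc.sample_plausible_paths(
            mean_path, bounds, mc_accept, seed_run,
            acceptance=acceptance, zero_tol=zero_tol,
        )
        probs = _mc.mc_column_distributions(samples, V, bounds)
        cols = _direct.make_columns(mean_path, bounds, V)
        out = []
        for i, meas in enumerate(series.measurements):
            out.append(
                _direct.FieldColumn(
                    x=float(mean_path.x[i]), kind="measured",
                    lo=float(mean_path.y[i]), hi=float(mean_path.y[i]),
                    midpoints=np.array([mean_path.y[i]]),
                    p_joint=np.array([1.0]), measurement=meas,
                )
            )
        for j, c in enumerate(cols):
            out.append(
                _direct.FieldColumn(
                    x=c.x, kind="guide", lo=c.lo, hi=c.hi,
                    midpoints=c.midpoints, p_joint=probs[j],
                )
            )
        out.sort(key=lambda col: col.x)
        return _direct.LikelihoodField(
            series_id=series.series_id, columns=out,
            reference_count=count_inflexions(mean_path, zero_tol),
            meta={"V": V, "acceptance": acceptance, "method": "mc",
                  "mc_accept": mc_accept, "attempts": samples.attempts},
        )

    use_error = error_model == "on" or (
        error_model == "auto"
        and any(meas.half_width > 0 for meas in series.measurements)
    )
    if not use_error:
        return _direct.compute_field(
            mean_path, bounds, V, acceptance=acceptance, zero_tol=zero_tol,
            series_id=series.series_id, measurements=series.measurements,
        )

    realizations = _errors.lhs_realizations(
        series, cycles=cycles, m=m, seed=seed_run, zero_tol=zero_tol
    )
    fields = [
        _direct.compute_field(
            r.path, bounds, V, reference_count=r.reference_count,
            acceptance=acceptance, zero_tol=zero_tol,
            series_id=series.series_id, measurements=series.measurements,
        )
        for r in realizations
    ]
    agg = _errors.aggregate_fields(fields)
    agg.meta.update({"m": m, "cycles": cycles})
    return agg


# ---------------------------------------------------------------------------
# quantile envelopes


def _pwc_quantile(lo: float, hi: float, probs: np.ndarray, q: float) -> float:
    """Inverse CDF of a piecewise-constant density over equal-width bins."""
    if hi - lo <= 0:
        return lo
    V = probs.size
    bw = (hi - lo) / V
    cum = np.cumsum(probs)
    cum[-1] = 1.0
    q = min(max(q, 0.0), 1.0)
    j = int(np.searchsorted(cum, q, side="left"))
    j = min(j, V - 1)
    while probs[j] <= 0 and j < V - 1:  # land on a mass-carrying bin
        j += 1
    c_prev = cum[j - 1] if j > 0 else 0.0
    frac = 0.0 if probs[j] <= 0 else (q - c_prev) / probs[j]
    return lo + (j + min(max(frac, 0.0), 1.0)) * bw


def _central_interval(col: _direct.FieldColumn, level: float) -> tuple[float, float]:
    q_lo, q_hi = (1.0 - level) / 2.0, (1.0 + level) / 2.0
    return (
        _pwc_quantile(col.lo, col.hi, col.p_joint, q_lo),
        _pwc_quantile(col.lo, col.hi, col.p_joint, q_hi),
    )


def _hd_interval(col: _direct.FieldColumn, level: float, n_scan: int = 201) -> tuple[float, float]:
    """Smallest interval of the piecewise-constant density holding ``level`` mass."""
    best = (np.inf, col.lo, col.hi)
    for u in np.linspace(0.0, 1.0 - level, n_scan):
        a = _pwc_quantile(col.lo, col.hi, col.p_joint, u)
        b = _pwc_quantile(col.lo, col.hi, col.p_joint, u + level)
        if b - a < best[0]:
            best = (b - a, a, b)
    return best[1], best[2]


def _measured_interval(col: _direct.FieldColumn, level: float) -> tuple[float, float]:
    meas = col.measurement
    if meas is None or meas.sd == 0.0 or level == 0.0:
        center = meas.mean if meas is not None else float(col.midpoints.mean())
        return center, center
    q = (1.0 + level) / 2.0
    scale = meas.sd / np.sqrt(meas.n_reps)
    crit = stats.norm.ppf(q) if meas.n_reps == 1 else stats.t.ppf(q, df=meas.n_reps - 1)
    return meas.mean - crit * scale, meas.mean + crit * scale


@dataclass(frozen=True)
class QuantileEnvelopeSet:
    """Nested per-level (x, lo, hi) polylines; linear between vertices."""

    levels: tuple[float, ...]
    xs: np.ndarray
    lo: dict  # level -> ndarray over xs
    hi: dict

    def interval(self, level: float, x):
        """The (lo, hi) band at ``x`` (scalar or array), linearly interpolated."""
        x = np.asarray(x, dtype=float)
        if np.any(x < self.xs[0] - 1e-12) or np.any(x > self.xs[-1] + 1e-12):
            raise OutOfRangeError("x outside the envelope domain")
        return (
            np.interp(x, self.xs, self.lo[level]),
            np.interp(x, self.xs, self.hi[level]),
        )


def build_envelope_set(
    field: _direct.LikelihoodField,
    levels=DEFAULT_LEVELS,
    hdi: bool = False,
) -> QuantileEnvelopeSet:
    """Likelihood envelopes at the requested levels.

    At guide columns the level-q interval is the central (equal-tailed)
    interval of the discrete joint distribution, linearly interpolated
    inside midpoint bins (or the highest-density interval with ``hdi``).
    At measured columns it is the t-based central confidence interval at
    level q. Vertices are connected by straight lines.
    """
    levels = tuple(sorted(float(q) for q in levels))
    if any(not 0.0 <= q < 1.0 for q in levels):
        raise ValueError("levels must lie in [0, 1)")
    for col in field.guide_columns:
        if abs(col.p_joint.sum() - 1.0) > 1e-6:
            raise ValueError(f"unnormalised joint vector at x={col.x:g}")
    xs = np.array([c.x for c in field.columns])
    lo = {q: np.empty(xs.size) for q in levels}
    hi = {q: np.empty(xs.size) for q in levels}
    for i, col in enumerate(field.columns):
        for q in levels:
            if col.kind == "measured":
                a, b = _measured_interval(col, q)
            elif hdi:
                a, b = _hd_interval(col, q)
            else:
                a, b = _central_interval(col, q)
            lo[q][i], hi[q][i] = a, b
    return QuantileEnvelopeSet(levels=levels, xs=xs, lo=lo, hi=hi)


# ---------------------------------------------------------------------------
# coverage


@dataclass(frozen=True)
class CoverageReport:
    """Per-level counts of withheld means falling inside the envelopes."""

    levels: tuple[float, ...]
    n_withheld: int
    n_inside: dict  # level -> int

    def fraction(self, level: float) -> float:
        return self.n_inside[level] / self.n_withheld if self.n_withheld else float("nan")


def coverage(
    withheld,
    envelopes: QuantileEnvelopeSet,
    tol: float = 1e-9,
) -> CoverageReport:
    """Fraction of withheld means inside each likelihood envelope.

    ``withheld`` is a list of :class:`Measurement` or an ``(xs, ys)`` pair.
    Only the withheld means are scored; their own error is ignored, as in
    the evaluation the envelopes are meant for. The ``tol`` slack admits
    points sitting exactly on a (possibly zero-width) boundary.
    """
    if isinstance(withheld, tuple):
        xs, ys = (np.asarray(a, dtype=float) for a in withheld)
    else:
        xs = np.array([meas.t for meas in withheld])
        ys = np.array([meas.mean for meas in withheld])
    n_inside = {}
    for q in envelopes.levels:
        lo, hi = envelopes.interval(q, xs)
        slack = tol * (1.0 + np.maximum(np.abs(lo), np.abs(hi)))
        inside = (ys >= lo - slack) & (ys <= hi + slack)
        n_inside[q] = int(inside.sum())
    return CoverageReport(levels=envelopes.levels, n_withheld=int(xs.size), n_inside=n_inside)


# ---------------------------------------------------------------------------
# PC1 summarisation


def pc1_series(
    frame,
    conf_level: float = _errors.DEFAULT_CONF,
    series_id: str = "PC1",
) -> tuple[MeasurementSeries, float]:
    """First-principal-component series of a genes x (time, replicate) matrix.

    Columns must be a (time, replicate) MultiIndex or ``time_rep`` strings.
    Samples (columns) are projected onto the first component of the
    gene-centred data; the PC1 sign is fixed so the loading with the
    largest magnitude is positive. Returns the replicate series of PC1
    scores and the fraction of total variance the component carries.
    """
    if frame.isna().any().any():
        raise ValueError("matrix contains missing values; imputation is out of scope")
    cols = frame.columns
    if getattr(cols, "nlevels", 1) == 2:
        keys = [(float(t), str(r)) for t, r in cols]
    else:
        try:
            keys = [
                (float(str(c).rsplit("_", 1)[0]), str(c).rsplit("_", 1)[1])
                for c in cols
            ]
        except (IndexError, ValueError) as exc:
            raise ValueError(
                "wide columns must be 'time_rep' pairs, e.g. '0_1'"
            ) from exc
    X = frame.to_numpy(dtype=float).T  # samples x genes
    pca = PCA(n_components=1)
    scores = pca.fit_transform(X)[:, 0]
    loading = pca.components_[0]
    if loading[np.argmax(np.abs(loading))] < 0:
        scores = -scores
    frac = float(pca.explained_variance_ratio_[0])

    by_time: dict[float, list[float]] = {}
    for (t, _rep), s in zip(keys, scores):
        by_time.setdefault(t, []).append(float(s))
    times = sorted(by_time)
    series = MeasurementSeries.from_arrays(
        series_id, times, [by_time[t] for t in times], conf_level=conf_level
    )
    return series, frac


# ---------------------------------------------------------------------------
# calibration experiment


def calibration_experiment(
    n_series: int = 200,
    seed: int = 0,
    n_points: int = 7,
    V: int = _direct.DEFAULT_GRID,
    levels=DEFAULT_LEVELS,
    method: str = "direct",
) -> CoverageReport:
    """Pooled coverage of truths drawn from the plausible set itself.

    For each synthetic series (zero measurement noise — the setting in
    which the likelihood construction is exactly defined), every other
    time point is withheld, a truth path is drawn uniformly from the
    retained points' plausible set, envelopes are estimated from the
    retained points, and the truth's values at the withheld times are
    scored. Curve families and their shape parameters vary across series.
    """
    from .simulate import simulate_series, simulate_truth_from_plausible_set

    levels = tuple(sorted(float(q) for q in levels))
    families = ("logistic", "peak", "damped_osc")
    master = np.random.SeedSequence(seed)
    totals = {q: 0 for q in levels}
    n_total = 0
    for i, child in enumerate(master.spawn(n_series)):
        s_sim, s_truth, s_est = (
            int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(3)
        )
        rng = np.random.default_rng(s_sim)
        curve = families[i % len(families)]
        params = {"mid": float(rng.uniform(2.0, 6.0))}
        if curve == "damped_osc":
            params["period"] = float(rng.uniform(4.0, 8.0))
        sim = simulate_series(
            n_points=n_points, curve=curve, noise_sd=0.0, n_reps=3,
            seed=s_sim, curve_params=params, series_id=f"cal_{i}",
        )
        retained, withheld_meas = withhold(sim.series, "every-other")
        bounds = union_bounds_function(retained, seed=s_est)
        truth = simulate_truth_from_plausible_set(retained, seed=s_truth, bounds=bounds)
        field = estimate_field(retained, method=method, V=V, seed=s_est, bounds=bounds)
        env = build_envelope_set(field, levels)
        xs_w = np.array([meas.t for meas in withheld_meas])
        rep = coverage((xs_w, truth.value_at(xs_w)), env)
        for q in levels:
            totals[q] += rep.n_inside[q]
        n_total += rep.n_withheld
    return CoverageReport(levels=levels, n_withheld=n_total, n_inside=totals)
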