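"""Synthetic series with known truth.

The generator emulates the kind of data the estimator is meant for: smooth,
low-inflexion response curves (sigmoidal rises and falls, single peaks,
damped oscillations) sampled at a handful of time points with a few noisy
replicates each — the shape vocabulary of transcript-abundance time courses.
Replicate noise is normal by default so the t-based interval machinery
applies exactly; a heavy-tailed option exists for robustness checks. A
second generator draws a "truth" path uniformly from the plausible set of a
retained series, which is the reference distribution for calibration tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .envelope import union_bounds_function
from .errors import DEFAULT_CONF, MeasurementSeries
from .montecarlo import sample_plausible_paths
from .paths import Path, count_inflexions


@dataclass(frozen=True)
class SimulatedSeries:
    """A generated series plus its densely sampled generating curve."""

    series: MeasurementSeries
    truth_x: np.ndarray
    truth_y: np.ndarray
    true_inflexions: int  # inflexion count of the true curve at the sampled times
    curve: str
    params: dict


def _curve_function(curve: str, t_span: tuple[float, float], params: dict):
    t0, t1 = t_span
    span = t1 - t0
    mid = params.get("mid", t0 + span / 2.0)
    if curve == "logistic":
        k = params.get("rate", 8.0 / span)
        direction = params.get("direction", "rise")
        sgn = 1.0 if direction == "rise" else -1.0
        return lambda t: 1.0 / (1.0 + np.exp(-sgn * k * (t - mid)))
    if curve == "peak":
        width = params.get("width", span / 6.0)
        return lambda t: np.exp(-0.5 * ((t - mid) / width) ** 2)
    if curve == "damped_osc":
        period = params.get("period", span / 1.5)
        tau = params.get("tau", span / 2.0)
        return lambda t: np.exp(-(t - t0) / tau) * np.cos(2.0 * np.pi * (t - t0) / period)
    raise ValueError(f"unknown curve family {curve!r}")


def simulate_series(
    n_points: int = 9,
    curve: str = "logistic",
    noise_sd: float = 0.1,
    n_reps: int = 3,
    seed: int = 0,
    t_span: tuple[float, float] = (0.0, 8.0),
    curve_params: dict | None = None,
    conf_level: float = DEFAULT_CONF,
    series_id: str | None = None,
    heavy_tails: bool = False,
) -> SimulatedSeries:
    """Sample a smooth low-inflexion curve at n_points with noisy replicates.

    Replicate values are the true curve values plus independent
    ``N(0, noise_sd^2)`` noise (or scaled Student-t with 3 df when
    ``heavy_tails`` is set). Fully seeded and reproducible.
    """
    if n_points < 3:
        raise ValueError("n_points must be at least 3")
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    params = dict(curve_params or {})
    f = _curve_function(curve, t_span, params)
    t = np.linspace(t_span[0], t_span[1], n_points)
    truth_at_t = f(t)
    rng = np.random.default_rng(seed)
    if noise_sd == 0.0:
        noise = np.zeros((n_points, n_reps))
    elif heavy_tails:
        noise = noise_sd * rng.standard_t(df=3, size=(n_points, n_reps))
    else:
        noise = rng.normal(0.0, noise_sd, size=(n_points, n_reps))
    values = truth_at_t[:, None] + noise

    sid = series_id or f"sim_{curve}_{seed}"
    if n_reps == 1:
        # single replicate: the generator knows the true noise sd
        from .errors import Measurement

        series = MeasurementSeries(
            sid,
            [
                Measurement(
                    t=float(tt), values=(float(v),), conf_level=conf_level,
                    sd_external=noise_sd,
                )
                for tt, v in zip(t, values[:, 0])
            ],
        )
    else:
        series = MeasurementSeries.from_arrays(sid, t, values, conf_level=conf_level)
    dense = np.linspace(t_span[0], t_span[1], 400)
    return SimulatedSeries(
        series=series,
        truth_x=dense,
        truth_y=f(dense),
        true_inflexions=count_inflexions(Path(t, truth_at_t)),
        curve=curve,
        params=params,
    )


def simulate_truth_from_plausible_set(
    retained: MeasurementSeries,
    seed: int,
    bounds=None,
    clip_factor: float = 1.0,
    acceptance: str = "le",
) -> Path:
    """One path drawn uniformly from the retained series' plausible set.

    Samples a single accepted guide configuration through the mean path
    (within corner-union bounds unless ``bounds`` is supplied) and returns
    the merged measured+guide polyline; linear interpolation of that
    polyline serves as the unknown "truth" in calibration experiments.
    """
    mean_path = retained.mean_path()
    if bounds is None:
        bounds = union_bounds_function(
            retained, clip_factor=clip_factor, acceptance=acceptance, seed=seed
        )
    samples = sample_plausible_paths(
        mean_path, bounds, n_accept=1, seed=seed, acceptance=acceptance
    )
    return mean_path.insert(samples.guide_x, samples.y[0])
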