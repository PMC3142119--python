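"""Acceptance-rejection sampling of plausible guide-point configurations.

Two guide points per measured interval sit at fixed trisection abscissae;
their y values are drawn independently and uniformly within the envelope
bounds at each guide column, and a draw is accepted iff the merged path
(measured points plus all guides) stays within the reference inflexion
count. The accepted configurations' per-column histograms approximate the
likelihood distribution of plausible interpolations. The method is retained
as the sampling-based validation route for the direct method: acceptance
rates fall quickly as measured points accumulate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .paths import (
    DEFAULT_ZERO_TOL,
    Path,
    count_inflexions,
    guide_positions,
    merge_with_slots,
    plausible_many,
)

DEFAULT_ATTEMPT_CAP = 10**7
_DEGENERATE_SPAN = 1e-12


class SamplingExhaustedError(RuntimeError):
    """The attempt cap was hit before enough draws were accepted."""


@dataclass(frozen=True)
class GuideSamples:
    """Accepted guide configurations: one row of y values per acceptance."""

    guide_x: np.ndarray
    y: np.ndarray  # shape (n_accept, n_guides)
    attempts: int

    @property
    def n_accept(self) -> int:
        return int(self.y.shape[0])

    @property
    def acceptance_rate(self) -> float:
        return self.n_accept / self.attempts if self.attempts else float("nan")


def sample_plausible_paths(
    measured: Path,
    bounds,
    n_accept: int,
    seed: int,
    reference_count: int | None = None,
    acceptance: str = "le",
    zero_tol: float = DEFAULT_ZERO_TOL,
    attempt_cap: int = DEFAULT_ATTEMPT_CAP,
    batch_size: int = 4096,
) -> GuideSamples:
    """Draw exactly ``n_accept`` plausible guide configurations.

    Guide y values are sampled independently per column, uniform within
    ``bounds`` at that column, and accepted jointly. A fixed seed gives a
    bit-identical result; exceeding ``attempt_cap`` raises
    :class:`SamplingExhaustedError` with diagnostics.
    """
    if n_accept < 1:
        raise ValueError("n_accept must be at least 1")
    ref = count_inflexions(measured, zero_tol) if reference_count is None else reference_count
    gx = guide_positions(measured.x)
    lo, hi = bounds(gx)
    lo = np.atleast_1d(np.asarray(lo, dtype=float))
    hi = np.atleast_1d(np.asarray(hi, dtype=float))
    x_full, y_base, slots = merge_with_slots(measured, gx)

    rng = np.random.default_rng(seed)
    accepted: list[np.ndarray] = []
    n_found = 0
    attempts = 0
    while n_found < n_accept:
        if attempts >= attempt_cap:
            raise SamplingExhaustedError(
                f"accepted {n_found}/{n_accept} after {attempts} attempts "
                f"(rate {n_found / attempts:.2e}); bounds may be pathological"
            )
        b = int(min(batch_size, attempt_cap - attempts))
        ys = rng.uniform(lo, hi, size=(b, gx.size))
        attempts += b
        Y = np.broadcast_to(y_base, (b, y_base.size)).copy()
        Y[:, slots] = ys
        ok = plausible_many(x_full, Y, ref, acceptance, zero_tol)
        if ok.any():
            accepted.append(ys[ok])
            n_found += int(ok.sum())
    y = np.concatenate(accepted, axis=0)[:n_accept]
    return GuideSamples(guide_x=gx, y=y, attempts=attempts)


def mc_column_distributions(
    samples: GuideSamples,
    bins: int,
    bounds=None,
) -> np.ndarray:
    """Normalised per-column histograms of accepted guide y values.

    Bins are ``bins`` equal-width intervals of the envelope span at each
    column (so histograms align with the direct method's grid); without a
    ``bounds`` argument the span of the accepted values is used. A
    degenerate span yields the uniform vector, matching the direct
    method's handling of collapsed columns.
    """
    if samples.n_accept == 0:
        raise ValueError("no accepted configurations")
    if bins < 1:
        raise ValueError("bins must be at least 1")
    gx = samples.guide_x
    if bounds is not None:
        lo, hi = bounds(gx)
        lo = np.atleast_1d(np.asarray(lo, dtype=float))
        hi = np.atleast_1d(np.asarray(hi, dtype=float))
    else:
        lo = samples.y.min(axis=0)
        hi = samples.y.max(axis=0)
    out = np.empty((gx.size, bins))
    for j in range(gx.size):
        if hi[j] - lo[j] <= _DEGENERATE_SPAN:
            out[j] = 1.0 / bins
            continue
        counts, _ = np.histogram(samples.y[:, j], bins=bins, range=(lo[j], hi[j]))
        total = counts.sum()
        out[j] = counts / total if total else 1.0 / bins
    return out
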