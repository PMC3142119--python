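"""Withholding, quantile envelopes, coverage and PC1 summarisation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from interpuq.analysis import (
    QuantileEnvelopeSet,
    build_envelope_set,
    coverage,
    estimate_field,
    pc1_series,
    withhold,
)
from interpuq.direct import FieldColumn, LikelihoodField
from interpuq.errors import Measurement, MeasurementSeries

# local conditional chains legitimately hit all-zero columns on some fixtures
pytestmark = pytest.mark.filterwarnings("ignore:all-zero")


def make_series(n, seed=0):
    rng = np.random.default_rng(seed)
    values = [tuple(rng.normal(i * 0.3, 0.1, 3)) for i in range(n)]
    return MeasurementSeries.from_arrays("s", np.arange(n, dtype=float), values)


class TestWithhold:
    def test_every_other_on_seven_points(self):
        retained, withheld = withhold(make_series(7), "every-other")
        assert [m.t for m in retained.measurements] == [0, 2, 4, 6]
        assert [m.t for m in withheld] == [1, 3, 5]

    def test_every_third_keeps_six_of_sixteen(self):
        retained, withheld = withhold(make_series(16), "every-third")
        assert len(retained) == 6
        assert [m.t for m in retained.measurements] == [0, 3, 6, 9, 12, 15]
        assert len(withheld) == 10

    def test_explicit_full_list_withholds_nothing(self):
        series = make_series(5)
        retained, withheld = withhold(series, range(5))
        assert len(retained) == 5
        assert withheld == []

    def test_dropping_an_endpoint_is_rejected(self):
        with pytest.raises(ValueError, match="first and last"):
            withhold(make_series(6), "every-other")  # index 5 lost
        with pytest.raises(ValueError, match="first and last"):
            withhold(make_series(5), [0, 1, 2, 3])

    def test_unknown_pattern_rejected(self):
        with pytest.raises(ValueError):
            withhold(make_series(5), "every-fourth")


def uniform_field(V=20):
    guide = FieldColumn(
        x=0.5, kind="guide", lo=0.0, hi=1.0,
        midpoints=(np.arange(V) + 0.5) / V, p_joint=np.full(V, 1.0 / V),
    )
    ends = [
        FieldColumn(
            x=float(x), kind="measured", lo=0.0, hi=0.0,
            midpoints=np.array([0.0]), p_joint=np.array([1.0]),
        )
        for x in (0.0, 1.0)
    ]
    return LikelihoodField("s", [ends[0], guide, ends[1]], reference_count=0)


class TestEnvelopeSet:
    def test_uniform_column_gives_exact_central_quantiles(self):
        env = build_envelope_set(uniform_field(), levels=(0.95,))
        lo, hi = env.interval(0.95, 0.5)
        assert lo == pytest.approx(0.025, abs=1e-12)
        assert hi == pytest.approx(0.975, abs=1e-12)

    def test_levels_are_nested_at_every_vertex(self):
        field = estimate_field(make_series(4, seed=3), V=16, seed=0)
        env = build_envelope_set(field, levels=(0.20, 0.75, 0.95))
        for x in env.xs:
            lo20, hi20 = env.interval(0.20, x)
            lo75, hi75 = env.interval(0.75, x)
            lo95, hi95 = env.interval(0.95, x)
            assert lo95 <= lo75 <= lo20 <= hi20 <= hi75 <= hi95

    def test_spike_column_collapses_to_bin_width(self):
        field = uniform_field(V=10)
        p = np.zeros(10)
        p[4] = 1.0
        field.columns[1].p_joint = p
        env = build_envelope_set(field, levels=(0.20, 0.95))
        bin_width = 0.1
        for level in (0.20, 0.95):
            lo, hi = env.interval(level, 0.5)
            assert hi - lo <= bin_width + 1e-12
            assert abs((lo + hi) / 2 - 0.45) <= bin_width

    def test_measured_columns_use_t_confidence_intervals(self):
        series = make_series(4, seed=1)
        field = estimate_field(series, V=8, seed=0)
        env = build_envelope_set(field, levels=(0.95,))
        meas = series.measurements[0]
        lo, hi = env.interval(0.95, meas.t)
        crit = stats.t.ppf(0.975, df=meas.n_reps - 1)
        half = crit * meas.sd / np.sqrt(meas.n_reps)
        assert lo == pytest.approx(meas.mean - half)
        assert hi == pytest.approx(meas.mean + half)

    def test_unnormalised_field_rejected(self):
        field = uniform_field()
        field.columns[1].p_joint = field.columns[1].p_joint * 0.5
        with pytest.raises(ValueError, match="unnormalised"):
            build_envelope_set(field)

    def test_hdi_never_wider_than_central(self):
        field = estimate_field(make_series(4, seed=5), V=16, seed=0)
        central = build_envelope_set(field, levels=(0.75,))
        hdi = build_envelope_set(field, levels=(0.75,), hdi=True)
        for i, x in enumerate(central.xs):
            w_c = central.hi[0.75][i] - central.lo[0.75][i]
            w_h = hdi.hi[0.75][i] - hdi.lo[0.75][i]
            assert w_h <= w_c + 1e-9

    def test_envelopes_stay_inside_plausible_bounds(self):
        from interpuq.envelope import union_bounds_function

        series = make_series(4, seed=9)
        bounds = union_bounds_function(series, seed=0)
        field = estimate_field(series, V=16, seed=0, bounds=bounds)
        env = build_envelope_set(field, levels=(0.95,))
        for x in env.xs:
            b_lo, b_hi = bounds(x)
            e_lo, e_hi = env.interval(0.95, x)
            assert e_lo >= b_lo - 1e-9
            assert e_hi <= b_hi + 1e-9


class TestCoverage:
    @staticmethod
    def flat_envelopes():
        xs = np.array([0.0, 1.0, 2.0])
        return QuantileEnvelopeSet(
            levels=(0.2, 0.95),
            xs=xs,
            lo={0.2: np.full(3, -0.5), 0.95: np.full(3, -2.0)},
            hi={0.2: np.full(3, 0.5), 0.95: np.full(3, 2.0)},
        )

    def test_central_point_inside_all_levels(self):
        rep = coverage((np.array([0.5]), np.array([0.0])), self.flat_envelopes())
        assert rep.n_inside == {0.2: 1, 0.95: 1}

    def test_extreme_point_inside_no_level(self):
        rep = coverage((np.array([1.5]), np.array([5.0])), self.flat_envelopes())
        assert rep.n_inside == {0.2: 0, 0.95: 0}

    def test_point_between_levels(self):
        rep = coverage((np.array([1.0]), np.array([1.0])), self.flat_envelopes())
        assert rep.n_inside == {0.2: 0, 0.95: 1}
        assert rep.fraction(0.95) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(Exception):
            coverage((np.array([9.0]), np.array([0.0])), self.flat_envelopes())


class TestPC1:
    @staticmethod
    def wide_frame(noise=0.0, seed=0, n_genes=30, times=(0, 2, 4), reps=2):
        rng = np.random.default_rng(seed)
        loading = rng.normal(size=n_genes)
        profile = {t: np.sin(t) + 1.0 for t in times}
        cols = {}
        for t in times:
            for r in range(1, reps + 1):
                cols[f"{t}_{r}"] = loading * profile[t] + rng.normal(
                    0, noise, n_genes
                )
        return pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])

    def test_rank_one_matrix_has_unit_variance_fraction(self):
        series, frac = pc1_series(self.wide_frame(noise=0.0))
        assert frac == pytest.approx(1.0, abs=1e-9)
        assert len(series) == 3
        assert all(m.n_reps == 2 for m in series.measurements)

    def test_gene_permutation_leaves_scores_unchanged_up_to_sign(self):
        frame = self.wide_frame(noise=0.05)
        series_a, _ = pc1_series(frame)
        shuffled = frame.sample(frac=1.0, random_state=1)
        series_b, _ = pc1_series(shuffled)
        a = np.concatenate([m.values for m in series_a.measurements])
        b = np.concatenate([m.values for m in series_b.measurements])
        assert np.allclose(a, b, atol=1e-9) or np.allclose(a, -b, atol=1e-9)

    def test_missing_values_rejected(self):
        frame = self.wide_frame()
        frame.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            pc1_series(frame)


def test_pipeline_is_deterministic():
    """Same seed, same configuration: identical envelopes end to end."""
    series = make_series(4, seed=2)
    envs = []
    for _ in range(2):
        field = estimate_field(series, V=12, seed=42)
        envs.append(build_envelope_set(field))
    for level in envs[0].levels:
        np.testing.assert_array_equal(envs[0].lo[level], envs[1].lo[level])
        np.testing.assert_array_equal(envs[0].hi[level], envs[1].hi[level])
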