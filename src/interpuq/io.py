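"""Readers and writers for the tabular interchange formats.

Tidy series files have columns ``series_id, time, replicate, value``
(tab- or comma-delimited, header required). Wide expression matrices have
a gene identifier in the first column and one column per (time, replicate)
sample named ``time_rep``. Output tables are TSV: the per-midpoint field
table, the per-level envelope table and the coverage report, plus a JSON
run manifest recording the configuration and library versions.
"""

from __future__ import annotations

import json
from pathlib import Path as FsPath

import numpy as np
import pandas as pd

from .analysis import CoverageReport, QuantileEnvelopeSet
from .direct import LikelihoodField
from .errors import DEFAULT_CONF, MeasurementSeries

TIDY_COLUMNS = ["series_id", "time", "replicate", "value"]


class FormatError(ValueError):
    """Input file violates the tidy or wide format contract."""


def _read_table(path) -> pd.DataFrame:
    with open(path, encoding="utf-8") as handle:
        header = handle.readline()
    sep = "\t" if "\t" in header else ","
    # the default fast float parser loses the last couple of bits
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def read_series(
    path,
    format: str = "tidy",
    conf_level: float = DEFAULT_CONF,
) -> list[MeasurementSeries]:
    """Read one or more measurement series from a tidy or wide file."""
    if format == "tidy":
        return _read_tidy(path, conf_level)
    if format == "wide":
        frame = read_wide_matrix(path)
        return [
            _series_from_wide_row(str(gene), row, conf_level)
            for gene, row in frame.iterrows()
        ]
    raise ValueError("format must be 'tidy' or 'wide'")


def _read_tidy(path, conf_level: float) -> list[MeasurementSeries]:
    df = _read_table(path)
    missing = [c for c in TIDY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"tidy file lacks column(s): {', '.join(missing)}")
    values = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[values.isna() & df["value"].notna()]
    if len(bad):
        # +2: one for the header line, one for 1-based numbering
        raise FormatError(f"non-numeric value on line {int(bad[0]) + 2}")
    df = df.assign(value=values)
    dup = df.duplicated(subset=["series_id", "time", "replicate"], keep=False)
    if dup.any():
        lines = ", ".join(str(int(i) + 2) for i in df.index[dup][:5])
        raise FormatError(f"duplicate (series_id, time, replicate) keys on line(s) {lines}")

    out: list[MeasurementSeries] = []
    for sid, group in df.groupby("series_id", sort=True):
        times = sorted(group["time"].unique())
        reps = [
            group.loc[group["time"] == t]
            .sort_values("replicate")["value"]
            .to_numpy()
            for t in times
        ]
        out.append(
            MeasurementSeries.from_arrays(str(sid), times, reps, conf_level=conf_level)
        )
    return out


def read_wide_matrix(path) -> pd.DataFrame:
    """Genes x (time, replicate) matrix; columns become a (time, rep) MultiIndex."""
    df = _read_table(path)
    gene_col = df.columns[0]
    df = df.set_index(gene_col)
    try:
        pairs = [
            (float(str(c).rsplit("_", 1)[0]), str(c).rsplit("_", 1)[1])
            for c in df.columns
        ]
    except (IndexError, ValueError) as exc:
        raise FormatError("wide columns must be named 'time_rep', e.g. '0_1'") from exc
    df.columns = pd.MultiIndex.from_tuples(pairs, names=["time", "replicate"])
    df = df.apply(pd.to_numeric)
    return df


def _series_from_wide_row(gene: str, row: pd.Series, conf_level: float) -> MeasurementSeries:
    by_time: dict[float, list[float]] = {}
    for (t, _rep), v in row.items():
        by_time.setdefault(float(t), []).append(float(v))
    times = sorted(by_time)
    return MeasurementSeries.from_arrays(
        gene, times, [by_time[t] for t in times], conf_level=conf_level
    )


def series_to_frame(series_list) -> pd.DataFrame:
    """Tidy DataFrame for a list of series (round-trips with read_series)."""
    rows = []
    for series in series_list:
        for meas in series.measurements:
            for r, v in enumerate(meas.values, start=1):
                rows.append((series.series_id, meas.t, r, v))
    return pd.DataFrame(rows, columns=TIDY_COLUMNS)


def write_series(series_list, path) -> None:
    series_to_frame(series_list).to_csv(path, sep="\t", index=False)


def write_field_table(fields, path) -> None:
    """Per-midpoint field table: one row per (column, midpoint)."""
    rows = []
    for field in fields:
        for col in field.columns:
            for i, mid in enumerate(col.midpoints):
                rows.append(
                    (
                        field.series_id,
                        col.x,
                        col.kind,
                        mid,
                        col.p_left[i] if col.p_left is not None else np.nan,
                        col.p_right[i] if col.p_right is not None else np.nan,
                        col.p_joint[i],
                    )
                )
    pd.DataFrame(
        rows,
        columns=[
            "series_id", "column_x", "column_kind",
            "midpoint_y", "p_left", "p_right", "p_joint",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_envelope_table(envelopes: dict[str, QuantileEnvelopeSet], path) -> None:
    rows = []
    for sid, env in envelopes.items():
        for level in env.levels:
            for x, lo, hi in zip(env.xs, env.lo[level], env.hi[level]):
                rows.append((sid, level, x, lo, hi))
    pd.DataFrame(
        rows, columns=["series_id", "level", "x", "y_lo", "y_hi"]
    ).to_csv(path, sep="\t", index=False)


def write_coverage_table(reports: dict[str, CoverageReport], path) -> None:
    rows = []
    for sid, rep in reports.items():
        for level in rep.levels:
            rows.append(
                (sid, level, rep.n_withheld, rep.n_inside[level], rep.fraction(level))
            )
    pd.DataFrame(
        rows, columns=["series_id", "level", "n_withheld", "n_inside", "fraction"]
    ).to_csv(path, sep="\t", index=False)


def write_manifest(config: dict, path) -> None:
    import scipy
    import sklearn

    from . import __version__

    manifest = {
        "config": config,
        "versions": {
            "interpuq": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    FsPath(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
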