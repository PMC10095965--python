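"""Readers and writers for the package's plain-text exchange formats.

All tables carry mandatory header rows with unit-suffixed column names; the
readers validate column names and basic monotonicity and report the offending
row on malformed input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from gravirod.centerline import CenterlineSample, CenterlineSeries, MorphospacePoint

__all__ = [
    "SERIES_COLUMNS",
    "write_series_csv",
    "read_series_csv",
    "write_morphospace_csv",
    "read_morphospace_csv",
    "write_grid_tsv",
    "write_map_tsv",
]

SERIES_COLUMNS = ["individual_id", "genotype", "time_min", "point_index", "x_mm", "y_mm"]


class ParseError(ValueError):
    """Malformed input table (bad columns or row-level inconsistency)."""


def write_series_csv(series_list, path) -> None:
    """Write one or more CenterlineSeries to a single CSV."""
    if isinstance(series_list, CenterlineSeries):
        series_list = [series_list]
    rows = []
    for series in series_list:
        for sample in series.samples:
            for idx, (x, y) in enumerate(sample.points):
                rows.append(
                    (series.individual_id, series.genotype, sample.time, idx, x, y)
                )
    df = pd.DataFrame(rows, columns=SERIES_COLUMNS)
    df.to_csv(path, index=False)


def read_series_csv(path) -> list[CenterlineSeries]:
    """Read CenterlineSeries from CSV, validating columns and time ordering.

    Raises
    ------
    ParseError
        On wrong columns, or non-monotone time / point indices (the message
        names the first offending row).
    """
    df = pd.read_csv(path)
    if list(df.columns) != SERIES_COLUMNS:
        raise ParseError(
            f"bad columns {list(df.columns)}; expected {SERIES_COLUMNS}"
        )
    out = []
    for ind_id, sub in df.groupby("individual_id", sort=False):
        genotypes = sub["genotype"].unique()
        if len(genotypes) != 1:
            raise ParseError(f"individual {ind_id!r} has multiple genotypes")
        samples = []
        prev_t = -np.inf
        for t, frame in sub.groupby("time_min", sort=True):
            idx = frame["point_index"].to_numpy()
            if not np.array_equal(idx, np.arange(len(idx))):
                row = int(frame.index[0])
                raise ParseError(
                    f"non-contiguous point_index for {ind_id!r} at "
                    f"t={t} (first row {row})"
                )
            if t <= prev_t:
                row = int(frame.index[0])
                raise ParseError(f"non-monotone time at row {row}")
            prev_t = t
            samples.append(
                CenterlineSample(time=float(t), points=frame[["x_mm", "y_mm"]].to_numpy())
            )
        out.append(CenterlineSeries(str(ind_id), str(genotypes[0]), samples))
    return out


def write_morphospace_csv(records, path) -> None:
    """Write per-individual morphospace points.

    ``records``: iterable of (individual_id, genotype, MorphospacePoint).
    """
    rows = [
        {
            "individual_id": ind,
            "genotype": gen,
            "extension_ratio": p.extension_ratio,
            "max_curvature_per_mm": p.max_curvature,
            "length_start_mm": p.length_start,
            "length_end_mm": p.length_end,
        }
        for ind, gen, p in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_morphospace_csv(path) -> list[tuple[str, str, MorphospacePoint]]:
    df = pd.read_csv(path)
    needed = {"individual_id", "genotype", "extension_ratio", "max_curvature_per_mm"}
    if not needed.issubset(df.columns):
        raise ParseError(f"morphospace CSV missing columns {needed - set(df.columns)}")
    out = []
    for _, r in df.iterrows():
        out.append(
            (
                str(r["individual_id"]),
                str(r["genotype"]),
                MorphospacePoint(
                    extension_ratio=float(r["extension_ratio"]),
                    max_curvature=float(r["max_curvature_per_mm"]),
                    length_start=float(r.get("length_start_mm", np.nan)),
                    length_end=float(r.get("length_end_mm", np.nan)),
                ),
            )
        )
    return out


def write_grid_tsv(s_grid, g_grid, d_grid, path) -> None:
    """Deviation landscape: rows = S values, columns = G values."""
    df = pd.DataFrame(d_grid, index=s_grid, columns=g_grid)
    df.index.name = "S\\G"
    df.to_csv(path, sep="\t")


def write_map_tsv(times, values, path, s_grid=None) -> None:
    """Generic (time x space) map with a time_min first column."""
    values = np.asarray(values)
    cols = (
        [f"{s:.6g}" for s in s_grid]
        if s_grid is not None
        else [str(i) for i in range(values.shape[1])]
    )
    df = pd.DataFrame(values, columns=cols)
    df.insert(0, "time_min", np.asarray(times))
    df.to_csv(path, sep="\t", index=False)
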