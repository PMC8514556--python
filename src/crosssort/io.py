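"""Delimited-text I/O for time series and score tables.

CSV is the canonical exchange format: a header row of channel names, one row
per sample, one column per channel.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .timeseries import TimeSeries

__all__ = ["read_timeseries_csv", "write_timeseries_csv"]


def read_timeseries_csv(path, dt: float = 1.0, sep: str | None = None) -> TimeSeries:
    """Read a delimited text file into a TimeSeries.

    The delimiter is sniffed (comma/tab/semicolon/whitespace) unless given.
    Non-numeric cells and ragged rows raise a parse error naming the
    location; rows containing NaN are rejected with their (1-based, after the
    header) row numbers.
    """
    path = Path(path)
    if sep is None:
        import csv

        sample = path.read_text()[:4096]
        try:
            sep = csv.Sniffer().sniff(sample, delimiters=",;\t ").delimiter
        except csv.Error:
            sep = ","
    try:
        # round_trip parsing so write/read preserves doubles bit-for-bit
        df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - message passthrough
        raise ValueError(f"could not parse {path}: {exc}") from exc
    bad_cols = [c for c in df.columns if not np.issubdtype(df[c].dtype, np.number)]
    if bad_cols:
        for c in bad_cols:
            coerced = pd.to_numeric(df[c], errors="coerce")
            bad_rows = df.index[coerced.isna() & df[c].notna()].tolist()
            if bad_rows:
                raise ValueError(
                    f"non-numeric cell(s) in column {c!r} of {path} at data row(s) "
                    f"{[r + 1 for r in bad_rows[:5]]}"
                )
        df = df.apply(pd.to_numeric)
    nan_rows = df.index[df.isna().any(axis=1)].tolist()
    if nan_rows:
        raise ValueError(
            f"missing values in {path} at data row(s) {[r + 1 for r in nan_rows[:10]]}"
        )
    values = df.to_numpy(dtype=float)
    if values.shape[1] == 1:
        values = values[:, 0]
    return TimeSeries(values, dt=dt, labels=[str(c) for c in df.columns])


def write_timeseries_csv(series: TimeSeries, path) -> None:
    """Write a TimeSeries to CSV at full precision (round-trip safe)."""
    values = series.values
    if values.ndim == 1:
        values = values[:, None]
    df = pd.DataFrame(values, columns=series.labels)
    df.to_csv(path, index=False, float_format="%.17g")
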