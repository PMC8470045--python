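"""CSV reading/writing for concentration and amount series.

The on-disk format is a plain UTF-8 comma-separated file with a header
row containing ``time_h`` and one value column (``amount_mg`` or
``concentration_mg_per_ml`` by convention, but any single extra column
is accepted).  Parse errors report the offending line number.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .series import UNITS_AMOUNT, UNITS_CONCENTRATION, Series

__all__ = ["read_series", "write_series"]

_VALUE_COLUMN = {UNITS_AMOUNT: "amount_mg", UNITS_CONCENTRATION: "concentration_mg_per_ml"}


class SeriesParseError(ValueError):
    """A CSV series file could not be parsed; message carries the location."""


def read_series(path, units: str, column: str | None = None) -> Series:
    """Read a time series from CSV.

    Parameters
    ----------
    path : path-like
        CSV file with header ``time_h,<value column>``.
    units : {"mg", "mg/mL"}
        Unit tag to attach to the values.
    column : str, optional
        Name of the value column; defaults to the single non-time column
        (ambiguous files must name it explicitly).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise SeriesParseError(f"{path}: file is empty") from None
    if "time_h" not in frame.columns:
        raise SeriesParseError(f"{path}: missing required column 'time_h'")
    if column is None:
        candidates = [c for c in frame.columns if c != "time_h"]
        conventional = _VALUE_COLUMN.get(units)
        if len(candidates) == 1:
            column = candidates[0]
        elif conventional in candidates:
            column = conventional
        else:
            raise SeriesParseError(
                f"{path}: expected one value column beside 'time_h' "
                f"(or a {conventional!r} column), found {candidates}; "
                "pass column= explicitly"
            )
    elif column not in frame.columns:
        raise SeriesParseError(f"{path}: missing column {column!r}")

    times, values = [], []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        cells = {}
        for col in ("time_h", column):
            raw = row[col]
            try:
                cells[col] = float(raw)
            except (TypeError, ValueError):
                raise SeriesParseError(
                    f"{path}: non-numeric value {raw!r} in column {col!r} at line {line}"
                ) from None
        if cells["time_h"] < 0:
            raise SeriesParseError(f"{path}: negative time at line {line}")
        times.append(cells["time_h"])
        values.append(cells[column])
    if not times:
        raise SeriesParseError(f"{path}: no data rows")

    try:
        return Series(times=times, values=values, units=units)
    except ValueError as exc:
        raise SeriesParseError(f"{path}: {exc}") from None


def write_series(series: Series, path) -> None:
    """Write a series to CSV with the conventional column name for its units."""
    pd.DataFrame(
        {"time_h": series.times, _VALUE_COLUMN[series.units]: series.values}
    ).to_csv(path, index=False)
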