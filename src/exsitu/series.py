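"""Year-indexed annual series.

Every trend analysis in the package exchanges values as a pandas Series with a
contiguous integer year index (one entry per calendar year, explicit zeros, no
gaps). ``annual_series`` builds and validates that shape; downstream modules
assume it.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
import pandas as pd

Window = Tuple[int, int]

#: The study window: a century of records.
DEFAULT_WINDOW: Window = (1921, 2021)


def annual_series(
    values: Sequence[float] | np.ndarray,
    start_year: int,
    name: str | None = None,
) -> pd.Series:
    """Build a validated annual series from consecutive per-year values."""
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("annual series values must be one-dimensional")
    index = pd.RangeIndex(start_year, start_year + len(arr), name="year")
    return pd.Series(arr, index=index, name=name)


def empty_series(window: Window, name: str | None = None) -> pd.Series:
    start, end = validate_window(window)
    return annual_series(np.zeros(end - start + 1), start, name=name)


def validate_window(window: Window) -> Window:
    start, end = int(window[0]), int(window[1])
    if start > end:
        raise ValueError(f"window start {start} after end {end}")
    return start, end


def check_annual(series: pd.Series) -> pd.Series:
    """Validate that ``series`` is a well-formed annual series."""
    idx = series.index
    if len(series) == 0:
        raise ValueError("annual series is empty")
    if not np.issubdtype(np.asarray(idx).dtype, np.integer):
        raise ValueError("annual series index must be integer years")
    if not np.all(np.diff(np.asarray(idx)) == 1):
        raise ValueError("annual series index must be consecutive years")
    if series.isna().any():
        raise ValueError("annual series may not contain missing entries")
    return series


def series_to_frame(named: dict[str, pd.Series]) -> pd.DataFrame:
    """Combine same-window annual series into a year-indexed frame."""
    frame = pd.DataFrame(named)
    frame.index.name = "year"
    return frame


def years(window: Window) -> np.ndarray:
    start, end = validate_window(window)
    return np.arange(start, end + 1)
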