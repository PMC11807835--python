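"""Annual reconstruction of collection state, turnover and trajectories.

Accession records carry only an accession date and a most-recent status
update, so the historic state of a collection is reconstructed by treating
each accession as a presence interval: from its accession year through the
year of its last status update, with a terminal event when every planting of
the accession is dead. Census convention is inclusive at both ends (an
accession whose last individual died in year *d* was part of that year's
collection), which gives the shifted accounting identity

    count(y) - count(y-1) = gains(y) - losses(y-1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from exsitu.records import EnrichedRecord
from exsitu.series import DEFAULT_WINDOW, Window, annual_series, check_annual, validate_window

#: Columns of the interval frame produced by :func:`accession_intervals`.
INTERVAL_COLUMNS = [
    "collection_id", "accession_id", "start_year", "end_year",
    "terminal_event", "provenance", "species", "genus", "family",
    "is_tree", "endemism", "iucn_current_category", "name_class",
    "matched", "n_plantings",
]


@dataclass
class ClipReport:
    total_accessions: int = 0
    clipped_start: int = 0
    clipped_end: int = 0
    dropped_outside_window: int = 0


def accession_intervals(
    records: Sequence[EnrichedRecord],
    snapshot_year: int | None = None,
    window: Window = DEFAULT_WINDOW,
    extend_alive_to_snapshot: bool = False,
) -> tuple[pd.DataFrame, ClipReport]:
    """Collapse plantings into one presence interval per accession.

    The interval starts at the accession year and ends at the latest status
    year over the accession's plantings; the terminal event is set when every
    planting's last status is dead. With ``extend_alive_to_snapshot`` the end
    year of accessions alive at their last update is extended to
    ``snapshot_year`` (the alternative census convention); by default they
    contribute through their last observed year only, consistent with
    right-censoring in the survival analyses.

    Returns a DataFrame with one row per accession (:data:`INTERVAL_COLUMNS`)
    plus a clipping report for the window.
    """
    start_w, end_w = validate_window(window)
    report = ClipReport()
    rows: dict[tuple[str, str], dict] = {}
    for rec in records:
        key = (rec.collection_id, rec.accession_id)
        start = rec.accession_date.year
        end = rec.last_status_date.year
        alive = rec.status_alive
        row = rows.get(key)
        if row is None:
            rows[key] = {
                "collection_id": rec.collection_id,
                "accession_id": rec.accession_id,
                "start_year": start,
                "end_year": end,
                "any_alive": alive,
                "provenance": rec.provenance.value,
                "species": rec.species,
                "genus": rec.genus,
                "family": rec.family,
                "is_tree": bool(rec.backbone.is_tree) if rec.backbone else False,
                "endemism": _endemism(rec),
                "iucn_current_category": rec.iucn_current_category,
                "name_class": rec.name_class.value,
                "matched": rec.backbone is not None,
                "n_plantings": 1,
            }
        else:
            row["start_year"] = min(row["start_year"], start)
            row["end_year"] = max(row["end_year"], end)
            row["any_alive"] = row["any_alive"] or alive
            row["n_plantings"] += 1
    report.total_accessions = len(rows)
    out = []
    for row in rows.values():
        row["terminal_event"] = not row.pop("any_alive")
        if not row["terminal_event"] and extend_alive_to_snapshot:
            if snapshot_year is None:
                raise ValueError("extend_alive_to_snapshot requires snapshot_year")
            row["end_year"] = max(row["end_year"], snapshot_year)
        if row["end_year"] < start_w or row["start_year"] > end_w:
            report.dropped_outside_window += 1
            continue
        if row["start_year"] < start_w:
            row["start_year"] = start_w
            report.clipped_start += 1
        if row["end_year"] > end_w:
            row["end_year"] = end_w
            # clipping the end removes the terminal event from the window
            row["terminal_event"] = False
            report.clipped_end += 1
        out.append(row)
    frame = pd.DataFrame(out, columns=INTERVAL_COLUMNS)
    return frame, report


def _endemism(rec: EnrichedRecord) -> str:
    from exsitu.records import is_endemic

    return is_endemic(rec.distribution)


def annual_counts(intervals: pd.DataFrame, window: Window = DEFAULT_WINDOW) -> pd.Series:
    """Number of accessions existing in each year of the window."""
    start_w, end_w = validate_window(window)
    n_years = end_w - start_w + 1
    delta = np.zeros(n_years + 1)
    if len(intervals):
        s = np.clip(intervals["start_year"].to_numpy() - start_w, 0, None)
        e = np.clip(intervals["end_year"].to_numpy() - start_w, None, n_years - 1)
        keep = (intervals["start_year"].to_numpy() <= end_w) & \
               (intervals["end_year"].to_numpy() >= start_w)
        np.add.at(delta, s[keep], 1)
        np.add.at(delta, e[keep] + 1, -1)
    return annual_series(np.cumsum(delta[:-1]), start_w, name="accessions")


def turnover(
    intervals: pd.DataFrame, window: Window = DEFAULT_WINDOW
) -> tuple[pd.Series, pd.Series, pd.Series]:
    """Annual gains (new accessions), losses (last individual died) and net.

    Losses only count terminal events: an accession merely censored at its
    last status update is not a loss.
    """
    start_w, end_w = validate_window(window)
    n_years = end_w - start_w + 1
    gains = np.zeros(n_years)
    losses = np.zeros(n_years)
    if len(intervals):
        s = intervals["start_year"].to_numpy()
        e = intervals["end_year"].to_numpy()
        ev = intervals["terminal_event"].to_numpy().astype(bool)
        in_s = (s >= start_w) & (s <= end_w)
        np.add.at(gains, s[in_s] - start_w, 1)
        sel = ev & (e >= start_w) & (e <= end_w)
        np.add.at(losses, e[sel] - start_w, 1)
    g = annual_series(gains, start_w, name="gains")
    l = annual_series(losses, start_w, name="losses")
    return g, l, (g - l).rename("net")


def rolling_mean(series: pd.Series, window_width: int = 5) -> pd.Series:
    """Centered moving average; edges average over the available overlap."""
    check_annual(series)
    if window_width < 1 or window_width % 2 == 0:
        raise ValueError("window_width must be odd and >= 1")
    return series.rolling(window_width, center=True, min_periods=1).mean()


def classify_trajectory(series: pd.Series, tail_years: int = 10,
                        flat_frac_per_year: float = 0.005) -> str:
    """Classify a collection-size curve as increasing/plateauing/decreasing.

    Declared rule (a reproducible surrogate for visual categorization): fit an
    ordinary least-squares line to the final ``tail_years`` values; if the
    absolute slope is below ``flat_frac_per_year`` of the series peak per
    year the curve is PLATEAUING, otherwise the slope sign decides.
    """
    check_annual(series)
    if len(series) < max(tail_years, 10):
        raise ValueError(f"series too short to classify (need >= {max(tail_years, 10)})")
    tail = series.iloc[-tail_years:]
    x = np.asarray(tail.index, dtype=float)
    slope = np.polyfit(x, tail.to_numpy(dtype=float), 1)[0]
    peak = float(series.max())
    if peak <= 0 or abs(slope) < flat_frac_per_year * peak:
        return "PLATEAUING"
    return "INCREASING" if slope > 0 else "DECREASING"
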