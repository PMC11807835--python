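"""Provenance composition, native/non-native sourcing, and breakpoint effects.

Provenance distinguishes wild-origin, wild-derived, garden-origin and
unknown-origin accessions. Native/non-native status compares a taxon's TDWG
level-3 distribution against the *native region* of the holding collection:
the minimal set of botanical countries covering the collection's political
country (shipped as a curated mapping table). The policy-breakpoint statistic
``relative_change`` compares mean annual acquisition in the decade after a
breakpoint year against the decade before it, as a percentage of the
pre-breakpoint mean.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from exsitu.records import Provenance
from exsitu.series import DEFAULT_WINDOW, Window, annual_series, check_annual, validate_window

PROVENANCE_ORDER = [p.value for p in Provenance]


@dataclass(frozen=True)
class NativeRegion:
    """The minimal TDWG level-3 cover of a collection's political country."""

    collection_id: str
    political_country: str
    l3_codes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.l3_codes:
            raise ValueError("native region must have at least one L3 code")


def _per_year_table(intervals: pd.DataFrame, window: Window,
                    by_start_only: bool) -> pd.DataFrame:
    start_w, end_w = validate_window(window)
    if not len(intervals):
        return pd.DataFrame({"year": [], "provenance": []})
    if by_start_only:
        df = intervals[(intervals["start_year"] >= start_w)
                       & (intervals["start_year"] <= end_w)]
        return pd.DataFrame({"year": df["start_year"].to_numpy(),
                             "provenance": df["provenance"].to_numpy()})
    s = intervals["start_year"].clip(lower=start_w).to_numpy()
    e = intervals["end_year"].clip(upper=end_w).to_numpy()
    keep = s <= e
    s, e = s[keep], e[keep]
    prov = intervals["provenance"].to_numpy()[keep]
    reps = (e - s + 1).astype(int)
    years = np.concatenate([np.arange(a, b + 1) for a, b in zip(s, e)]) \
        if len(s) else np.array([], dtype=int)
    return pd.DataFrame({"year": years, "provenance": np.repeat(prov, reps)})


def _counts_frame(table: pd.DataFrame, window: Window) -> pd.DataFrame:
    start_w, end_w = validate_window(window)
    idx = pd.RangeIndex(start_w, end_w + 1, name="year")
    frame = pd.DataFrame(0.0, index=idx, columns=PROVENANCE_ORDER)
    if len(table):
        counts = table.groupby(["year", "provenance"]).size().unstack(fill_value=0)
        for col in counts.columns:
            frame.loc[counts.index, col] = counts[col].to_numpy(dtype=float)
    return frame


def provenance_series(
    intervals: pd.DataFrame, window: Window = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Per-year proportions of existing accessions by provenance category.

    Rows with no existing accessions are all-zero; otherwise the four
    proportions sum to 1.
    """
    counts = _counts_frame(_per_year_table(intervals, window, False), window)
    totals = counts.sum(axis=1)
    props = counts.div(totals.where(totals > 0, 1.0), axis=0)
    props[totals == 0] = 0.0
    return props


def incoming_by_provenance(
    intervals: pd.DataFrame, window: Window = DEFAULT_WINDOW
) -> pd.DataFrame:
    """Per-year counts of newly accessioned material by provenance.

    Columns partition the turnover gains: their row sum equals gains(y).
    """
    return _counts_frame(_per_year_table(intervals, window, True), window)


# ---------------------------------------------------------------------------
# Native regions (TDWG level 3)
# ---------------------------------------------------------------------------

def load_country_l3_mapping(path: str | Path | None = None) -> dict[str, frozenset[str]]:
    """Load the country -> TDWG level-3 minimal-cover table.

    Defaults to the packaged table covering the study's 19 collection
    countries.
    """
    if path is None:
        source = resources.files("exsitu.data").joinpath("country_tdwg_l3.csv")
        text = source.read_text(encoding="utf-8")
        rows = list(csv.DictReader(text.splitlines()))
    else:
        with open(path, "r", encoding="utf-8", newline="") as fh:
            rows = list(csv.DictReader(fh))
    mapping: dict[str, set[str]] = {}
    for row in rows:
        mapping.setdefault(row["country"], set()).add(row["l3_code"])
    return {k: frozenset(v) for k, v in mapping.items()}


def packaged_l3_codes() -> frozenset[str]:
    """All TDWG level-3 codes known to the packaged tables."""
    source = resources.files("exsitu.data").joinpath("tdwg_l3_codes.csv")
    rows = csv.DictReader(source.read_text(encoding="utf-8").splitlines())
    return frozenset(row["l3_code"] for row in rows)


def native_region(
    political_country: str,
    mapping: Mapping[str, frozenset[str]] | None = None,
    collection_id: str = "",
) -> NativeRegion:
    """Resolve a collection's political country to its native region."""
    table = mapping if mapping is not None else load_country_l3_mapping()
    if political_country not in table:
        raise KeyError(
            f"country {political_country!r} not in the TDWG level-3 mapping table")
    return NativeRegion(collection_id=collection_id,
                        political_country=political_country,
                        l3_codes=frozenset(table[political_country]))


def is_native(distribution: Iterable[str], region: NativeRegion) -> str:
    """native / non_native / unknown by distribution overlap with the region."""
    dist = set(distribution)
    if not dist:
        return "unknown"
    return "native" if dist & region.l3_codes else "non_native"


def native_status_map(
    records, regions: Mapping[str, NativeRegion]
) -> dict[tuple[str, str], str]:
    """Resolve native/non_native/unknown per (collection, accession).

    A record resolves via its collection's native region and its taxon's
    distribution; collections without a region, and taxa without a
    distribution, give "unknown".
    """
    out: dict[tuple[str, str], str] = {}
    for rec in records:
        key = (rec.collection_id, rec.accession_id)
        region = regions.get(rec.collection_id)
        if region is None:
            out[key] = "unknown"
            continue
        status = is_native(rec.distribution, region)
        prev = out.get(key)
        if prev in (None, "unknown"):
            out[key] = status
    return out


def native_series(
    intervals: pd.DataFrame,
    regions: Mapping[str, NativeRegion],
    window: Window = DEFAULT_WINDOW,
) -> tuple[pd.Series, pd.Series]:
    """Proportions of native vs non-native among classified new accessions.

    ``intervals`` must carry a ``native_status`` column (native / non_native /
    unknown) or a ``distribution`` resolvable via ``regions`` keyed by
    collection id; unknowns are excluded from the denominator.
    """
    start_w, end_w = validate_window(window)
    df = intervals
    if "native_status" not in df.columns:
        raise ValueError("intervals need a 'native_status' column "
                         "(use pipeline.attach_native_status)")
    df = df[(df["start_year"] >= start_w) & (df["start_year"] <= end_w)]
    df = df[df["native_status"].isin(["native", "non_native"])]
    idx = pd.RangeIndex(start_w, end_w + 1, name="year")
    counts = df.groupby(["start_year", "native_status"]).size().unstack(fill_value=0)
    counts = counts.reindex(index=idx, fill_value=0)
    for col in ("native", "non_native"):
        if col not in counts.columns:
            counts[col] = 0
    totals = counts["native"] + counts["non_native"]
    denom = totals.where(totals > 0, 1)
    native = (counts["native"] / denom).rename("native")
    non_native = (counts["non_native"] / denom).rename("non_native")
    return annual_series(native.to_numpy(float), start_w, "native"), \
        annual_series(non_native.to_numpy(float), start_w, "non_native")


def relative_change(
    series: pd.Series,
    breakpoint_year: int,
    pre_window_years: int = 10,
    post_window_years: int = 10,
) -> float:
    """Percentage change of the post-breakpoint mean vs the pre-breakpoint mean.

    Windows are ``[breakpoint - pre, breakpoint)`` and
    ``(breakpoint, breakpoint + post]``; the breakpoint year itself belongs to
    neither. Returns e.g. -44.0 for a drop from 100 to 56.
    """
    check_annual(series)
    first, last = int(series.index[0]), int(series.index[-1])
    if breakpoint_year - pre_window_years < first or breakpoint_year + post_window_years > last:
        raise ValueError("comparison windows fall outside the series")
    pre = series.loc[breakpoint_year - pre_window_years: breakpoint_year - 1]
    post = series.loc[breakpoint_year + 1: breakpoint_year + post_window_years]
    pre_mean = float(pre.mean())
    if pre_mean == 0:
        raise ZeroDivisionError("pre-breakpoint mean is zero; relative change undefined")
    return 100.0 * (float(post.mean()) - pre_mean) / pre_mean
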