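"""Right-censored survival analysis of accessions and species.

An accession's duration runs from its accessioning date to either its death
(all individuals dead: an event) or its most recent status update (still
alive: right-censored). The product-limit (Kaplan-Meier) estimator, Greenwood
variance and Brookmeyer-Crowley median confidence intervals are implemented
here directly; they are the statistic the whole analysis turns on.

Species-level survival uses *survival windows*: the maximal date intervals
during which at least one accession of the species was alive in a collection.
A species that dies out and is later reintroduced contributes each window as
a separate survival time.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from exsitu.records import EnrichedRecord, is_endemic

DAYS_PER_YEAR = 365.25

THREATENED_CURRENT = frozenset({"VU", "EN", "CR", "EW"})


@dataclass
class KMCurve:
    """Product-limit survival estimate over the distinct event times."""

    event_times: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray
    greenwood_variance: np.ndarray
    n_total: int
    n_events: int

    def survival_at(self, t: float) -> float:
        """Step-function value S(t) (right-continuous)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.event_times,
            "at_risk": self.at_risk,
            "events": self.events,
            "survival": self.survival,
            "greenwood_variance": self.greenwood_variance,
        })


def accession_survival_inputs(
    records: Sequence[EnrichedRecord],
    accession_window: tuple[int, int] | None = None,
) -> tuple[pd.DataFrame, int]:
    """Build accession-level durations and event flags.

    Plantings are collapsed to one row per (collection, accession): duration
    from the accession date to the latest status date in years (days/365.25);
    the event fires only when every planting is dead. ``accession_window``
    optionally restricts to accessions accessioned in [lo, hi] (used for the
    threatened-accession analyses). Returns the frame plus the number of
    records excluded for invalid dates.
    """
    rows: dict[tuple[str, str], dict] = {}
    excluded = 0
    for rec in records:
        if rec.last_status_date < rec.accession_date:  # defensive; parser rejects
            excluded += 1
            continue
        key = (rec.collection_id, rec.accession_id)
        row = rows.get(key)
        if row is None:
            rows[key] = {
                "collection_id": rec.collection_id,
                "accession_id": rec.accession_id,
                "accession_date": rec.accession_date,
                "last_status_date": rec.last_status_date,
                "any_alive": rec.status_alive,
                "species": rec.species,
                "matched": rec.backbone is not None,
                "is_tree": bool(rec.backbone.is_tree) if rec.backbone else False,
                "endemism": is_endemic(rec.distribution),
                "threatened": rec.iucn_current_category in THREATENED_CURRENT,
                "name_class": rec.name_class.value,
                "provenance": rec.provenance.value,
            }
        else:
            row["accession_date"] = min(row["accession_date"], rec.accession_date)
            row["last_status_date"] = max(row["last_status_date"], rec.last_status_date)
            row["any_alive"] = row["any_alive"] or rec.status_alive
    frame = pd.DataFrame(rows.values())
    if len(frame):
        if accession_window is not None:
            lo, hi = accession_window
            years = frame["accession_date"].map(lambda d: d.year)
            frame = frame[(years >= lo) & (years <= hi)].reset_index(drop=True)
        frame["duration"] = [
            (b - a).days / DAYS_PER_YEAR
            for a, b in zip(frame["accession_date"], frame["last_status_date"])
        ]
        frame["event"] = ~frame["any_alive"]
        frame = frame.drop(columns=["any_alive"])
    return frame, excluded


def km_fit(durations: Sequence[float] | pd.DataFrame,
           events: Sequence[bool] | None = None) -> KMCurve:
    """Kaplan-Meier product-limit fit.

    Accepts either (durations, events) arrays or a frame with ``duration``
    and ``event`` columns. At tied times deaths are counted before
    censorings (censored subjects at time t are still at risk for events at
    t), the standard product-limit convention.
    """
    if isinstance(durations, pd.DataFrame):
        frame = durations
        t = np.asarray(frame["duration"], dtype=float)
        e = np.asarray(frame["event"], dtype=bool)
    else:
        t = np.asarray(durations, dtype=float)
        e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("km_fit needs at least one observation")
    if (t < 0).any():
        raise ValueError("durations must be nonnegative")
    n = t.size
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])
    if event_times.size == 0:
        return KMCurve(np.array([]), np.array([]), np.array([]),
                       np.array([]), np.array([]), n_total=n, n_events=0)
    # at risk just before each event time; events at each time
    at_risk = n - np.searchsorted(t, event_times, side="left")
    d = np.array([np.count_nonzero((t == et) & e) for et in event_times])
    frac = 1.0 - d / at_risk
    surv = np.cumprod(frac)
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = d / (at_risk * (at_risk - d).astype(float))
        gw_terms[~np.isfinite(gw_terms)] = np.inf
        greenwood = surv**2 * np.cumsum(gw_terms)  # 0 * inf -> nan where S hit 0
    greenwood[~np.isfinite(greenwood)] = np.nan
    return KMCurve(event_times, at_risk, d, surv, greenwood,
                   n_total=n, n_events=int(d.sum()))


def km_median(curve: KMCurve, with_ci: bool = False
              ) -> float | None | tuple[float | None, tuple[float | None, float | None]]:
    """Median survival: the smallest event time t with S(t) <= 0.5.

    Returns None when S never reaches 0.5 ("not reached"). With ``with_ci``
    the Brookmeyer-Crowley 95% interval is returned: the first crossing times
    of 0.5 by the log(-log) transformed pointwise confidence band (either
    bound may itself be None when the band never reaches 0.5).
    """
    median = _first_time_below(curve.event_times, curve.survival, 0.5)
    if not with_ci:
        return median
    lo_band, hi_band = _loglog_band(curve)
    # the band that is *above* S crosses 0.5 later -> upper CI limit
    ci_low = _first_time_below(curve.event_times, hi_band, 0.5)
    ci_high = _first_time_below(curve.event_times, lo_band, 0.5)
    if ci_low is not None and ci_high is not None and ci_low > ci_high:
        ci_low, ci_high = ci_high, ci_low
    return median, (ci_low, ci_high)


def _first_time_below(times: np.ndarray, values: np.ndarray,
                      level: float) -> float | None:
    if times.size == 0:
        return None
    hit = np.nonzero(values <= level + 1e-12)[0]
    return float(times[hit[0]]) if hit.size else None


def _loglog_band(curve: KMCurve, z: float = 1.959963984540054
                 ) -> tuple[np.ndarray, np.ndarray]:
    s = curve.survival
    var = curve.greenwood_variance
    lo = np.full_like(s, np.nan)
    hi = np.full_like(s, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        inner = s > 0
        logs = np.log(s[inner])
        se = np.sqrt(var[inner]) / (s[inner] * np.abs(logs))
        theta = np.log(-logs)
        lo[inner] = np.exp(-np.exp(theta + z * se))
        hi[inner] = np.exp(-np.exp(theta - z * se))
    lo[~np.isfinite(lo)] = 0.0
    hi[~np.isfinite(hi)] = 1.0 if curve.survival.size else 1.0
    # where S hit exactly 0 the band collapses
    zero = s <= 0
    lo[zero] = 0.0
    hi[zero] = 0.0 if curve.survival.size and zero.all() else hi[zero]
    return lo, hi


# ---------------------------------------------------------------------------
# Species survival windows
# ---------------------------------------------------------------------------

def species_survival_windows(
    records: Sequence[EnrichedRecord],
    snapshot_date: date,
) -> pd.DataFrame:
    """Maximal per-(collection, species) intervals with >=1 accession alive.

    Accession presence intervals (accession date -> last status date) are
    unioned; overlapping or touching intervals merge, any positive gap splits
    windows (a reintroduction). A window closing before ``snapshot_date`` is
    an event (the species died out of the collection); otherwise censored.
    """
    acc: dict[tuple[str, str, str], list] = {}
    for rec in records:
        key = (rec.collection_id, rec.accession_id, rec.species)
        cur = acc.get(key)
        if cur is None:
            acc[key] = [rec.accession_date, rec.last_status_date, rec.status_alive,
                        rec.iucn_current_category in THREATENED_CURRENT]
        else:
            cur[0] = min(cur[0], rec.accession_date)
            cur[1] = max(cur[1], rec.last_status_date)
            cur[2] = cur[2] or rec.status_alive
    groups: dict[tuple[str, str], list] = {}
    for (coll, _aid, species), (start, end, alive, threat) in acc.items():
        groups.setdefault((coll, species), []).append((start, end, alive, threat))
    rows = []
    for (coll, species), ivals in groups.items():
        ivals.sort(key=lambda x: (x[0], x[1]))
        cur_start, cur_end, cur_alive = ivals[0][0], ivals[0][1], ivals[0][2]
        threat = ivals[0][3]
        merged = []
        for start, end, alive, _t in ivals[1:]:
            if start <= cur_end:  # overlap or touching
                cur_end = max(cur_end, end)
                cur_alive = cur_alive or alive
            else:
                merged.append((cur_start, cur_end, cur_alive))
                cur_start, cur_end, cur_alive = start, end, alive
        merged.append((cur_start, cur_end, cur_alive))
        for start, end, alive in merged:
            # censored only when some accession in the window is still alive
            # at its last update; otherwise the window closed before snapshot
            event = not alive
            rows.append({
                "collection_id": coll, "species": species,
                "start_date": start, "end_date": end,
                "duration": (end - start).days / DAYS_PER_YEAR,
                "event": event, "threatened": threat,
            })
    return pd.DataFrame(rows, columns=["collection_id", "species", "start_date",
                                       "end_date", "duration", "event",
                                       "threatened"])


# ---------------------------------------------------------------------------
# Stratified fits
# ---------------------------------------------------------------------------

class Stratifier(str, enum.Enum):
    TREE = "TREE"
    ENDEMIC = "ENDEMIC"
    THREATENED_ACCESSIONS = "THREATENED_ACCESSIONS"
    THREATENED_SPECIES = "THREATENED_SPECIES"
    NATIVE = "NATIVE"
    NAME_CLASS = "NAME_CLASS"


@dataclass
class StratumResult:
    curve: KMCurve
    median: Optional[float]
    ci95: tuple[Optional[float], Optional[float]]
    n: int


def stratified_km(
    records: Sequence[EnrichedRecord],
    stratifier: Stratifier | str,
    native_status: Mapping[tuple[str, str], str] | None = None,
    accession_window: tuple[int, int] | None = None,
    snapshot_date: date | None = None,
) -> dict[str, StratumResult]:
    """Kaplan-Meier fits per stratum with medians and 95% CIs.

    THREATENED_ACCESSIONS applies the accession-window restriction (default
    1980-2021 when no window is given); THREATENED_SPECIES stratifies
    species survival windows instead of accessions and requires
    ``snapshot_date``. NATIVE requires ``native_status`` mapping
    (collection_id, accession_id) -> native/non_native/unknown. Unresolvable
    rows (unknown endemism or native status, unmatched taxonomy where the
    stratifier needs it) are excluded; empty strata are omitted.
    """
    strat = Stratifier(stratifier)
    if strat is Stratifier.THREATENED_SPECIES:
        if snapshot_date is None:
            raise ValueError("THREATENED_SPECIES stratification needs snapshot_date")
        window = accession_window or (1980, 2021)
        subset = [r for r in records if window[0] <= r.accession_date.year <= window[1]]
        frame = species_survival_windows(subset, snapshot_date)
        if not len(frame):
            return {}
        frame["stratum"] = np.where(frame["threatened"], "threatened", "non_threatened")
    else:
        if strat is Stratifier.THREATENED_ACCESSIONS:
            accession_window = accession_window or (1980, 2021)
        frame, _ = accession_survival_inputs(records, accession_window=accession_window)
        if not len(frame):
            return {}
        if strat is Stratifier.TREE:
            frame = frame[frame["matched"]]
            frame["stratum"] = np.where(frame["is_tree"], "tree", "non_tree")
        elif strat is Stratifier.ENDEMIC:
            frame = frame[frame["endemism"].isin(["endemic", "widespread"])]
            frame["stratum"] = frame["endemism"]
        elif strat is Stratifier.THREATENED_ACCESSIONS:
            frame["stratum"] = np.where(frame["threatened"],
                                        "threatened", "non_threatened")
        elif strat is Stratifier.NAME_CLASS:
            frame["stratum"] = frame["name_class"].str.lower()
        elif strat is Stratifier.NATIVE:
            if native_status is None:
                raise ValueError("NATIVE stratification needs native_status mapping")
            keys = list(zip(frame["collection_id"], frame["accession_id"]))
            frame["stratum"] = [native_status.get(k, "unknown") for k in keys]
            frame = frame[frame["stratum"].isin(["native", "non_native"])]
    out: dict[str, StratumResult] = {}
    for name, group in frame.groupby("stratum"):
        if not len(group):
            continue
        curve = km_fit(group)
        median, ci = km_median(curve, with_ci=True)
        out[str(name)] = StratumResult(curve=curve, median=median, ci95=ci,
                                       n=len(group))
    return out
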