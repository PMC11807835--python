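"""Threatened-species dynamics, designation responsiveness and cohort contrasts.

Two distinct procedures coexist here, mirroring how Red List information is
used. Retrospective analyses map a *current* category snapshot onto the
historic reconstructions (threat accumulation, new-accession proportions,
individuals per species). Designation-timeline analyses use the *assessment
history* (year, category) per taxon, under a scheme that also recognises the
defunct categories E (endangered/extinct) and R (rare), to locate the first
year a species was designated threatened and to test whether collections
respond to designation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from exsitu.records import EnrichedRecord
from exsitu.series import DEFAULT_WINDOW, Window, annual_series, check_annual, validate_window
from exsitu.survival import THREATENED_CURRENT

#: Categories counting as threatened under the current scheme.
THREATENED = THREATENED_CURRENT
NON_THREATENED = frozenset({"NE", "DD", "LC", "NT"})
#: Defunct categories additionally counting as threatened in history analyses.
HISTORICAL_THREATENED = THREATENED | {"E", "R"}
HISTORICAL_NON_THREATENED = NON_THREATENED | {"EX", "I", "K", "NR", "O"}


@dataclass(frozen=True)
class AssessmentEvent:
    """One IUCN assessment of a taxon (assessment year, not publication)."""

    taxon: str
    year: int
    category: str


def read_assessment_history_csv(path: str | Path) -> dict[str, list[AssessmentEvent]]:
    """Read (taxon, year, category) rows into per-taxon sorted histories."""
    histories: dict[str, list[AssessmentEvent]] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            ev = AssessmentEvent(row["taxon"], int(row["year"]), row["category"].strip())
            histories.setdefault(ev.taxon, []).append(ev)
    for events in histories.values():
        events.sort(key=lambda e: e.year)
    return histories


def write_assessment_history_csv(histories: Mapping[str, Sequence[AssessmentEvent]],
                                 path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["taxon", "year", "category"])
        for taxon in sorted(histories):
            for ev in histories[taxon]:
                w.writerow([taxon, ev.year, ev.category])


def classify_threat(category: str, scheme: str = "CURRENT") -> bool:
    """Whether a Red List category counts as threatened under the scheme.

    CURRENT: VU/EN/CR/EW are threatened; NE/DD/LC/NT are not. HISTORICAL
    additionally treats the defunct codes E (endangered/extinct), R (rare)
    and V (vulnerable, old scheme) as threatened.
    """
    cat = category.strip().upper()
    scheme = scheme.upper()
    if scheme == "CURRENT":
        if cat in THREATENED:
            return True
        if cat in NON_THREATENED or cat == "EX":
            return False
    elif scheme == "HISTORICAL":
        if cat in HISTORICAL_THREATENED:
            return True
        if cat in HISTORICAL_NON_THREATENED:
            return False
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    raise ValueError(f"unrecognized Red List category {category!r} under {scheme}")


def designation_year(history: Sequence[AssessmentEvent]) -> int | None:
    """Earliest assessment year classified threatened (HISTORICAL scheme)."""
    for ev in sorted(history, key=lambda e: e.year):
        if classify_threat(ev.category, "HISTORICAL"):
            return ev.year
    return None


def threat_accumulation(
    intervals: pd.DataFrame, window: Window = DEFAULT_WINDOW
) -> tuple[pd.Series, pd.Series]:
    """Distinct species counts per year, split by retrospective threat status.

    Uses the snapshot category attached to the intervals
    (``iucn_current_category``); only records matched to the backbone carry a
    meaningful species identity and category.
    """
    start_w, end_w = validate_window(window)
    n_years = end_w - start_w + 1
    threatened = np.zeros(n_years)
    non_threatened = np.zeros(n_years)
    df = intervals[intervals["matched"]] if "matched" in intervals.columns else intervals
    if len(df):
        is_threat = df["iucn_current_category"].isin(sorted(THREATENED))
        for flag, target in ((True, threatened), (False, non_threatened)):
            sub = df[is_threat == flag]
            if not len(sub):
                continue
            s = sub["start_year"].clip(lower=start_w).to_numpy()
            e = sub["end_year"].clip(upper=end_w).to_numpy()
            keep = s <= e
            reps = (e[keep] - s[keep] + 1).astype(int)
            years = np.concatenate(
                [np.arange(a, b + 1) for a, b in zip(s[keep], e[keep])]
            ) if keep.any() else np.array([], dtype=int)
            species = np.repeat(sub["species"].to_numpy()[keep], reps)
            counts = pd.DataFrame({"year": years, "species": species}) \
                .groupby("year")["species"].nunique()
            target[counts.index.to_numpy(dtype=int) - start_w] = counts.to_numpy()
    return (annual_series(threatened, start_w, "threatened_species"),
            annual_series(non_threatened, start_w, "non_threatened_species"))


def select_responsive_cohort(
    histories: Mapping[str, Sequence[AssessmentEvent]],
    first_window: tuple[int, int] = (2000, 2009),
) -> set[str]:
    """Taxa first designated threatened within the window that stay threatened.

    A taxon qualifies when its first threatened designation year falls in
    ``first_window`` (inclusive) and every later assessment also classifies
    as threatened.
    """
    lo, hi = first_window
    cohort = set()
    for taxon, events in histories.items():
        year = designation_year(events)
        if year is None or not (lo <= year <= hi):
            continue
        later = [ev for ev in events if ev.year > year]
        if all(classify_threat(ev.category, "HISTORICAL") for ev in later):
            cohort.add(taxon)
    return cohort


def net_year_counts(
    gains_by_taxon_year: Mapping[tuple[str, int], int] | pd.DataFrame,
    cohort: Iterable[str],
    designation_years: Mapping[str, int],
    radius: int = 10,
) -> np.ndarray:
    """Accessions of cohort taxa summed by year relative to designation.

    Entry k (for k in -radius..+radius, returned as a vector of length
    2*radius+1) is the total number of new accessions of cohort taxa in
    calendar year designation_year(taxon) + k.
    """
    cohort = set(cohort)
    if not cohort:
        raise ValueError("cohort must be nonempty")
    if isinstance(gains_by_taxon_year, pd.DataFrame):
        table: dict[tuple[str, int], int] = {}
        grouped = gains_by_taxon_year.groupby(["species", "start_year"]).size()
        for (taxon, year), count in grouped.items():
            table[(taxon, int(year))] = int(count)
    else:
        table = {(t, int(y)): int(c) for (t, y), c in gains_by_taxon_year.items()}
    counts = np.zeros(2 * radius + 1)
    for (taxon, year), c in table.items():
        if taxon not in cohort or taxon not in designation_years:
            continue
        k = year - designation_years[taxon]
        if -radius <= k <= radius:
            counts[k + radius] += c
    return counts


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    ci95: tuple[float, float]
    cohens_d: float
    group_summaries: tuple[tuple[int, float, float], tuple[int, float, float]]


def welch_t_from_stats(n1: int, mean1: float, sd1: float,
                       n2: int, mean2: float, sd2: float) -> WelchResult:
    """Welch two-sample t-test from group summaries (two-sided).

    t = (m1 - m2)/sqrt(s1^2/n1 + s2^2/n2) with Welch-Satterthwaite degrees of
    freedom; 95% CI for the mean difference; Cohen's d with the equal-weight
    pooled sd sqrt((s1^2 + s2^2)/2) for equal n (n-weighted pooled sd
    otherwise).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    v1, v2 = sd1**2, sd2**2
    if v1 == 0 and v2 == 0:
        # precondition: nonzero variance in at least one group
        raise ZeroDivisionError("degenerate groups: zero variance in both")
    se2 = v1 / n1 + v2 / n2
    diff = mean1 - mean2
    t = diff / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    half = sps.t.ppf(0.975, df) * np.sqrt(se2)
    if n1 == n2:
        pooled = np.sqrt((v1 + v2) / 2.0)
    else:
        pooled = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2))
    d = diff / pooled if pooled > 0 else np.nan
    return WelchResult(
        t_statistic=float(t), degrees_of_freedom=float(df), p_value=float(p),
        ci95=(float(diff - half), float(diff + half)), cohens_d=float(d),
        group_summaries=((n1, float(mean1), float(sd1)),
                         (n2, float(mean2), float(sd2))),
    )


def welch_t(group_before: Sequence[float], group_after: Sequence[float]) -> WelchResult:
    """Welch two-sample t-test on raw observations (two-sided)."""
    a = np.asarray(group_before, dtype=float)
    b = np.asarray(group_after, dtype=float)
    return welch_t_from_stats(len(a), a.mean(), a.std(ddof=1),
                              len(b), b.mean(), b.std(ddof=1))


def responsiveness_test(counts: np.ndarray) -> WelchResult:
    """Welch test of accession rates before vs after threat designation.

    ``counts`` is the net-year vector from :func:`net_year_counts`; the two
    groups are the yearly sums at net years -radius..-1 and +1..+radius (net
    year 0, the designation year itself, belongs to neither).
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 5 or counts.size % 2 == 0:
        raise ValueError("counts must have odd length 2*radius+1 with radius >= 2")
    radius = counts.size // 2
    return welch_t(counts[:radius], counts[radius + 1:])


def new_threat_proportion_series(
    intervals: pd.DataFrame,
    window: Window = (1978, 2021),
) -> tuple[pd.Series, float, float]:
    """Proportion of newly acquired accessions that are threatened, per year.

    Returns the annual proportion series (NaN-free; years with zero gains are
    excluded from the regression) plus the OLS slope (per year) and
    intercept of the linear trend.
    """
    start_w, end_w = validate_window(window)
    df = intervals[(intervals["start_year"] >= start_w)
                   & (intervals["start_year"] <= end_w)]
    years = np.arange(start_w, end_w + 1)
    gains = np.zeros(len(years))
    threat = np.zeros(len(years))
    if len(df):
        g = df.groupby("start_year").size()
        gains[g.index.to_numpy(dtype=int) - start_w] = g.to_numpy()
        t = df[df["iucn_current_category"].isin(sorted(THREATENED))] \
            .groupby("start_year").size()
        if len(t):
            threat[t.index.to_numpy(dtype=int) - start_w] = t.to_numpy()
    valid = gains > 0
    props = np.zeros(len(years))
    props[valid] = threat[valid] / gains[valid]
    if valid.sum() < 2:
        raise ValueError("need at least two years with gains for the trend")
    slope, intercept = np.polyfit(years[valid], props[valid], 1)
    return annual_series(props, start_w, "threatened_proportion"), \
        float(slope), float(intercept)


def individuals_per_species_distribution(
    records: Sequence[EnrichedRecord],
    cap: int = 20,
    since: int = 1978,
) -> pd.DataFrame:
    """Distribution of individuals per species, split by threat status.

    Counts individual plantings accessioned since ``since`` per species;
    species with ``cap`` or more individuals are pooled into one open-ended
    bin. Returns a frame indexed by bin (1..cap-1 and "20+") with columns
    ``threatened`` / ``non_threatened`` holding proportions of species.
    """
    per_species: dict[str, int] = {}
    threat_of: dict[str, bool] = {}
    for rec in records:
        if rec.accession_date.year < since:
            continue
        per_species[rec.species] = per_species.get(rec.species, 0) + 1
        threat_of[rec.species] = rec.iucn_current_category in THREATENED
    bins = [str(i) for i in range(1, cap)] + [f"{cap}+"]
    out = pd.DataFrame(0.0, index=pd.Index(bins, name="individuals"),
                       columns=["threatened", "non_threatened"])
    totals = {"threatened": 0, "non_threatened": 0}
    for species, count in per_species.items():
        group = "threatened" if threat_of[species] else "non_threatened"
        key = f"{cap}+" if count >= cap else str(count)
        out.loc[key, group] += 1
        totals[group] += 1
    for group, total in totals.items():
        if total:
            out[group] /= total
    return out


def mean_individuals_series(
    records: Sequence[EnrichedRecord],
    restrict: str = "ALL",
    window: Window = DEFAULT_WINDOW,
) -> pd.Series:
    """Mean number of individual plants per (optionally threatened) species.

    Per year: existing individual plantings divided by distinct species
    existing, with presence taken planting-by-planting from accession date to
    last status year. ``restrict`` is ALL or THREATENED.
    """
    start_w, end_w = validate_window(window)
    restrict = restrict.upper()
    if restrict not in ("ALL", "THREATENED"):
        raise ValueError("restrict must be ALL or THREATENED")
    rows = []
    for rec in records:
        if restrict == "THREATENED" and rec.iucn_current_category not in THREATENED:
            continue
        s = max(rec.accession_date.year, start_w)
        e = min(rec.last_status_date.year, end_w)
        if s <= e:
            rows.append((s, e, rec.species))
    n_years = end_w - start_w + 1
    plantings = np.zeros(n_years)
    values = np.zeros(n_years)
    if rows:
        s = np.array([r[0] for r in rows]) - start_w
        e = np.array([r[1] for r in rows]) - start_w
        delta = np.zeros(n_years + 1)
        np.add.at(delta, s, 1)
        np.add.at(delta, e + 1, -1)
        plantings = np.cumsum(delta[:-1])
        reps = (e - s + 1).astype(int)
        years = np.concatenate([np.arange(a, b + 1) for a, b in zip(s, e)])
        species = np.repeat(np.array([r[2] for r in rows], dtype=object), reps)
        nunique = pd.DataFrame({"y": years, "sp": species}).groupby("y")["sp"].nunique()
        n_species = np.zeros(n_years)
        n_species[nunique.index.to_numpy(dtype=int)] = nunique.to_numpy()
        nonzero = n_species > 0
        values[nonzero] = plantings[nonzero] / n_species[nonzero]
    return annual_series(values, start_w, "mean_individuals_per_species")


# ---------------------------------------------------------------------------
# Cohort comparison (conservation programme vs meta-collection)
# ---------------------------------------------------------------------------

def _quantiles(values: Sequence[float], qs=(0.0, 0.25, 0.5, 0.75, 1.0)) -> dict[float, float]:
    arr = np.asarray(values, dtype=float)
    # linear interpolation between order statistics
    return {float(q): float(np.quantile(arr, q, method="linear")) for q in qs}


def _cohort_summary(records: Sequence[EnrichedRecord]) -> dict:
    taxa_threat: dict[str, bool] = {}
    taxa_wild: dict[str, bool] = {}
    per_prov_taxon: dict[str, dict[str, int]] = {}
    holdings_threatened: list[int] = []
    seen_holdings: set[str] = set()
    for rec in records:
        sp = rec.species
        threatened = rec.iucn_current_category in THREATENED
        taxa_threat[sp] = taxa_threat.get(sp, False) or threatened
        taxa_wild[sp] = taxa_wild.get(sp, False) or rec.provenance.value == "WILD"
        per_prov_taxon.setdefault(rec.provenance.value, {})
        per_prov_taxon[rec.provenance.value][sp] = \
            per_prov_taxon[rec.provenance.value].get(sp, 0) + 1
        if threatened and rec.backbone is not None and sp not in seen_holdings:
            seen_holdings.add(sp)
            holdings_threatened.append(rec.backbone.n_global_collections)
    n_taxa = len(taxa_threat)
    n_threatened = sum(taxa_threat.values())
    prov_summaries = {}
    for prov, table in sorted(per_prov_taxon.items()):
        counts = np.array(sorted(table.values()), dtype=float)
        prov_summaries[prov] = {
            "n_taxa": int(len(counts)),
            "median": float(np.median(counts)),
            "mean": float(counts.mean()),
            "q25": float(np.quantile(counts, 0.25, method="linear")),
            "q75": float(np.quantile(counts, 0.75, method="linear")),
        }
    return {
        "n_taxa": n_taxa,
        "n_threatened_taxa": n_threatened,
        "threatened_taxon_proportion": n_threatened / n_taxa if n_taxa else np.nan,
        "wild_taxon_proportion": (sum(taxa_wild.values()) / n_taxa) if n_taxa else np.nan,
        "individuals_per_taxon_by_provenance": prov_summaries,
        "threatened_holdings_quantiles": _quantiles(holdings_threatened)
        if holdings_threatened else {},
    }


def compare_cohorts(subset_a: Sequence[EnrichedRecord],
                    subset_b: Sequence[EnrichedRecord]) -> dict:
    """Summaries of two cohorts of currently existing plantings.

    Reports per cohort: the proportion of threatened taxa, the proportion of
    wild-origin taxa, individuals-per-taxon summaries by provenance, and
    linear-interpolation sample quantiles of global holdings for threatened
    taxa. Ratios are left to the caller.
    """
    if not subset_a or not subset_b:
        raise ValueError("both cohorts must be nonempty")
    return {"cohort_a": _cohort_summary(subset_a),
            "cohort_b": _cohort_summary(subset_b)}


def smooth_trend(series: pd.Series, span: float = 0.5) -> pd.Series:
    """Local (loess-style) linear regression with tricube weights.

    For each year, the nearest ``ceil(span * n)`` points get tricube weights
    scaled by the furthest neighbour's distance and a weighted straight line
    is evaluated at that year. Exactly reproduces linear series.
    """
    check_annual(series)
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    n = len(series)
    if n < 5:
        raise ValueError("series too short to smooth (need >= 5)")
    k = max(3, int(np.ceil(span * n)))
    x = np.asarray(series.index, dtype=float)
    y = series.to_numpy(dtype=float)
    out = np.empty(n)
    for i in range(n):
        dist = np.abs(x - x[i])
        idx = np.argsort(dist, kind="stable")[:k]
        h = dist[idx].max()
        if h == 0:
            out[i] = y[i]
            continue
        w = (1 - (dist[idx] / h) ** 3) ** 3
        w = np.clip(w, 0, None)
        xi, yi = x[idx], y[idx]
        sw = w.sum()
        xbar = (w * xi).sum() / sw
        ybar = (w * yi).sum() / sw
        sxx = (w * (xi - xbar) ** 2).sum()
        slope = (w * (xi - xbar) * (yi - ybar)).sum() / sxx if sxx > 0 else 0.0
        out[i] = ybar + slope * (x[i] - xbar)
    return annual_series(out, int(series.index[0]),
                         name=f"{series.name or 'series'}_trend")
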