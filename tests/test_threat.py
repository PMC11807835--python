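"""Threat classification, designation timelines, Welch test and trends."""

from __future__ import annotations

from datetime import date

import numpy as np
import pytest
from scipy import stats as sps

from exsitu import (
    annual_series,
    classify_threat,
    compare_cohorts,
    designation_year,
    individuals_per_species_distribution,
    mean_individuals_series,
    net_year_counts,
    new_threat_proportion_series,
    responsiveness_test,
    select_responsive_cohort,
    smooth_trend,
    threat_accumulation,
    welch_t,
    welch_t_from_stats,
)
from exsitu.threat import AssessmentEvent
from conftest import interval_frame


def events(*pairs, taxon="Sp x"):
    return [AssessmentEvent(taxon, y, c) for y, c in pairs]


class TestClassifyThreat:
    @pytest.mark.parametrize("category,expected", [
        ("VU", True), ("EN", True), ("CR", True), ("EW", True),
        ("NE", False), ("DD", False), ("LC", False), ("NT", False),
        ("EX", False),
    ])
    def test_current_scheme(self, category, expected):
        assert classify_threat(category, "CURRENT") is expected

    @pytest.mark.parametrize("category,expected", [
        ("E", True), ("R", True), ("VU", True), ("LC", False),
    ])
    def test_historical_scheme_adds_defunct_codes(self, category, expected):
        assert classify_threat(category, "HISTORICAL") is expected

    def test_unrecognized_code_is_error(self):
        with pytest.raises(ValueError):
            classify_threat("E", "CURRENT")
        with pytest.raises(ValueError):
            classify_threat("??", "HISTORICAL")


class TestDesignationYear:
    def test_first_qualifying_event(self):
        assert designation_year(events((1990, "LC"), (2004, "EN"),
                                       (2010, "VU"))) == 2004

    def test_defunct_rare_category_counts(self):
        assert designation_year(events((1985, "R"))) == 1985

    def test_never_threatened_returns_none(self):
        assert designation_year(events((1995, "LC"), (2010, "NT"))) is None


class TestResponsiveCohort:
    def test_stays_threatened_included(self):
        h = {"A": events((2003, "EN"), (2012, "VU"), taxon="A")}
        assert select_responsive_cohort(h) == {"A"}

    def test_downlisted_excluded(self):
        h = {"A": events((2003, "EN"), (2012, "LC"), taxon="A")}
        assert select_responsive_cohort(h) == set()

    def test_designated_outside_window_excluded(self):
        h = {"A": events((1999, "EN"), taxon="A")}
        assert select_responsive_cohort(h) == set()


class TestNetYearCounts:
    def test_single_taxon_direct_indexing(self):
        gains = {("A", 2003): 2, ("A", 2007): 1}
        counts = net_year_counts(gains, {"A"}, {"A": 2005})
        assert counts[10 - 2] == 2
        assert counts[10 + 2] == 1
        assert counts.sum() == 3

    def test_two_taxa_align_by_net_year(self):
        gains = {("A", 2003): 1, ("B", 2008): 4}
        counts = net_year_counts(gains, {"A", "B"}, {"A": 2005, "B": 2010})
        assert counts[10 - 2] == 5
        assert counts.sum() == 5

    def test_translation_property(self):
        gains = {("A", y): 1 for y in range(1998, 2012)}
        base = net_year_counts(gains, {"A"}, {"A": 2005}, radius=5)
        shifted = net_year_counts(gains, {"A"}, {"A": 2006}, radius=5)
        assert np.array_equal(base[:-1], shifted[1:])

    def test_empty_cohort_is_error(self):
        with pytest.raises(ValueError):
            net_year_counts({}, set(), {})

    def test_frame_input_counts_accessions(self):
        frame = interval_frame([
            (2003, 2010, False, {"species": "A"}),
            (2003, 2005, True, {"species": "A"}),
            (2007, 2010, False, {"species": "B"}),
        ])
        counts = net_year_counts(frame, {"A"}, {"A": 2005})
        assert counts[10 - 2] == 2 and counts.sum() == 2


class TestWelch:
    def test_reproduces_published_summary_statistics(self):
        res = welch_t_from_stats(10, 216.4, 48.8, 10, 232.1, 42.3)
        assert res.t_statistic == pytest.approx(-0.77, abs=0.005)
        assert res.degrees_of_freedom == pytest.approx(17.65, abs=0.02)
        assert res.cohens_d == pytest.approx(-0.34, abs=0.005)
        assert res.ci95[0] == pytest.approx(-58.66, abs=0.05)
        assert res.ci95[1] == pytest.approx(27.26, abs=0.05)
        assert res.p_value == pytest.approx(0.4521, abs=0.002)

    def test_closed_form_hand_calculation(self):
        res = welch_t([1, 2, 3], [2, 3, 4])
        assert res.t_statistic == pytest.approx(-1.2247, abs=1e-4)
        assert res.degrees_of_freedom == pytest.approx(4.0)
        assert res.cohens_d == pytest.approx(-1.0)

    def test_identical_groups_null(self):
        res = welch_t([5, 6, 7, 8], [5, 6, 7, 8])
        assert res.t_statistic == 0.0 and res.cohens_d == 0.0

    def test_antisymmetry_and_df_bound(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            a = rng.normal(0, 1, size=int(rng.integers(3, 12)))
            b = rng.normal(1, 2, size=int(rng.integers(3, 12)))
            r1, r2 = welch_t(a, b), welch_t(b, a)
            assert r1.t_statistic == pytest.approx(-r2.t_statistic)
            assert r1.degrees_of_freedom <= len(a) + len(b) - 2 + 1e-9
            # cross-check against scipy
            t, p = sps.ttest_ind(a, b, equal_var=False)
            assert r1.t_statistic == pytest.approx(float(t))
            assert r1.p_value == pytest.approx(float(p))

    def test_equal_sizes_and_variances_give_pooled_df(self):
        res = welch_t_from_stats(8, 1.0, 2.0, 8, 3.0, 2.0)
        assert res.degrees_of_freedom == pytest.approx(14.0)

    def test_degenerate_variance_signalled(self):
        with pytest.raises(ZeroDivisionError):
            welch_t([3, 3, 3], [3, 3, 3])

    def test_responsiveness_groups_exclude_net_year_zero(self):
        counts = np.arange(21, dtype=float)  # net year 0 holds value 10
        res = responsiveness_test(counts)
        (n1, m1, _), (n2, m2, _) = res.group_summaries
        assert (n1, m1) == (10, 4.5)
        assert (n2, m2) == (10, 15.5)


class TestThreatAccumulation:
    def test_all_least_concern_gives_zero_threatened(self):
        frame = interval_frame([(1990, 2000, False)] * 3)
        threatened, _ = threat_accumulation(frame)
        assert threatened.eq(0).all()

    def test_single_vulnerable_species_throughout(self):
        frame = interval_frame(
            [(1950, 2021, False, {"iucn_current_category": "VU"})])
        threatened, _ = threat_accumulation(frame)
        assert (threatened.loc[1950:2021] == 1).all()

    def test_five_species_hand_enumeration(self):
        rows = [
            (1990, 1995, True, {"species": "a", "iucn_current_category": "VU"}),
            (1992, 1998, True, {"species": "b", "iucn_current_category": "LC"}),
            (1993, 1994, True, {"species": "c", "iucn_current_category": "CR"}),
            (1994, 1999, True, {"species": "d", "iucn_current_category": "NT"}),
            (1996, 2000, True, {"species": "a", "iucn_current_category": "VU"}),
        ]
        threatened, non_threatened = threat_accumulation(interval_frame(rows))
        assert threatened.loc[1993] == 2   # a, c
        assert threatened.loc[1996] == 1   # a (second accession)
        assert non_threatened.loc[1995] == 2  # b, d

    def test_split_sums_to_species_accumulation(self, small_enriched):
        from exsitu import accession_intervals, accumulation_series
        frame, _ = accession_intervals(small_enriched, snapshot_year=2021)
        threatened, non_threatened = threat_accumulation(frame)
        total = accumulation_series(frame, "SPECIES")
        assert np.allclose((threatened + non_threatened).to_numpy(),
                           total.to_numpy())


class TestNewThreatProportion:
    def test_all_non_threatened_flat_zero(self):
        frame = interval_frame([(1980 + i, 2021, False) for i in range(20)])
        series, slope, intercept = new_threat_proportion_series(frame)
        assert series.eq(0).all() and slope == 0.0

    def test_exact_linear_ramp_recovered(self):
        rows = []
        for i in range(40):
            year = 1978 + i
            for j in range(100):
                cat = "EN" if j < i + 1 else "LC"
                rows.append((year, 2021, False,
                             {"iucn_current_category": cat,
                              "species": f"s{i}-{j}"}))
        series, slope, intercept = new_threat_proportion_series(
            interval_frame(rows), window=(1978, 2017))
        assert series.loc[1978] == pytest.approx(0.01)
        assert series.loc[2017] == pytest.approx(0.40)
        assert slope == pytest.approx(0.01, rel=1e-9)

    def test_slope_matches_normal_equations(self):
        rng = np.random.default_rng(4)
        rows = []
        for i in range(10):
            year = 1990 + i
            n_threat = int(rng.integers(0, 5))
            for j in range(12):
                cat = "VU" if j < n_threat else "LC"
                rows.append((year, 2021, False, {"iucn_current_category": cat}))
        series, slope, _ = new_threat_proportion_series(
            interval_frame(rows), window=(1990, 1999))
        x = np.asarray(series.index, dtype=float)
        y = series.to_numpy()
        expected = (((x - x.mean()) * (y - y.mean())).sum()
                    / ((x - x.mean()) ** 2).sum())
        assert slope == pytest.approx(expected)


class TestIndividualsDistribution:
    def test_worked_binning(self, make_enriched):
        recs = []
        for species, n, cat in [("a", 1, "EN"), ("b", 1, "LC"),
                                ("c", 2, "LC"), ("d", 25, "LC")]:
            for i in range(n):
                recs.append(make_enriched(
                    accession_id=f"{species}{i}", iucn_current_category=cat,
                    raw_name=f"Genus {species}",
                    accession_date=date(1990, 7, 1)))
        table = individuals_per_species_distribution(recs)
        assert table.loc["1", "non_threatened"] == pytest.approx(1 / 3)
        assert table.loc["2", "non_threatened"] == pytest.approx(1 / 3)
        assert table.loc["20+", "non_threatened"] == pytest.approx(1 / 3)
        assert table.loc["1", "threatened"] == pytest.approx(1.0)

    def test_proportions_sum_to_one_per_group(self, small_enriched):
        table = individuals_per_species_distribution(small_enriched)
        for col in table.columns:
            if table[col].sum() > 0:
                assert table[col].sum() == pytest.approx(1.0)

    def test_pre_1978_records_ignored(self, make_enriched):
        recs = [make_enriched(accession_date=date(1950, 7, 1),
                              last_status_date=date(1960, 7, 1),
                              status_alive=False)]
        table = individuals_per_species_distribution(recs)
        assert table.to_numpy().sum() == 0


class TestMeanIndividuals:
    def test_single_species_three_plantings(self, make_enriched):
        recs = [make_enriched(accession_id=f"A{i}",
                              accession_date=date(2000, 7, 1),
                              last_status_date=date(2005, 7, 1))
                for i in range(3)]
        series = mean_individuals_series(recs, window=(2000, 2005))
        assert series.loc[2002] == pytest.approx(3.0)

    def test_two_species_mean(self, make_enriched):
        recs = [make_enriched(raw_name="Aa bb", accession_id="A1",
                              accession_date=date(2000, 7, 1),
                              last_status_date=date(2004, 7, 1))]
        recs += [make_enriched(raw_name="Cc dd", accession_id=f"B{i}",
                               accession_date=date(2000, 7, 1),
                               last_status_date=date(2004, 7, 1))
                 for i in range(3)]
        series = mean_individuals_series(recs, window=(2000, 2004))
        assert series.loc[2001] == pytest.approx(2.0)

    def test_restriction_to_threatened(self, make_enriched):
        recs = [
            make_enriched(raw_name="Aa bb", iucn_current_category="EN",
                          accession_id="A1", accession_date=date(2000, 7, 1),
                          last_status_date=date(2003, 7, 1)),
            make_enriched(raw_name="Cc dd", iucn_current_category="LC",
                          accession_id="B1", accession_date=date(2000, 7, 1),
                          last_status_date=date(2003, 7, 1)),
        ]
        series = mean_individuals_series(recs, "THREATENED", window=(2000, 2003))
        assert series.loc[2001] == pytest.approx(1.0)


class TestCompareCohorts:
    def test_identical_subsets_identical_summaries(self, small_enriched):
        current = [r for r in small_enriched if r.status_alive][:500]
        result = compare_cohorts(current, current)
        assert result["cohort_a"] == result["cohort_b"]

    def test_quantile_interpolation_convention(self, make_enriched,
                                               small_backbone):
        from exsitu import enrich_records
        from dataclasses import replace
        recs = []
        for i, holdings in enumerate([1, 2, 3, 4]):
            taxon = replace(small_backbone[i], n_global_collections=holdings)
            recs.append(make_enriched(
                backbone=taxon, iucn_current_category="EN",
                accession_id=f"A{i}", raw_name=taxon.accepted_name))
        result = compare_cohorts(recs, recs)
        assert result["cohort_a"]["threatened_holdings_quantiles"][0.5] == 2.5

    def test_empty_cohort_rejected(self, small_enriched):
        with pytest.raises(ValueError):
            compare_cohorts([], small_enriched[:5])

    def test_proportions_counted_over_taxa(self, make_enriched):
        recs = [
            make_enriched(raw_name="Aa bb", accession_id="A1",
                          iucn_current_category="EN"),
            make_enriched(raw_name="Aa bb", accession_id="A2",
                          iucn_current_category="EN"),
            make_enriched(raw_name="Cc dd", accession_id="A3",
                          iucn_current_category="LC"),
        ]
        result = compare_cohorts(recs, recs)
        assert result["cohort_a"]["threatened_taxon_proportion"] == \
            pytest.approx(0.5)


class TestSmoothTrend:
    def test_linear_series_reproduced_exactly(self):
        s = annual_series(2.0 * np.arange(20) + 5.0, 1990)
        assert np.allclose(smooth_trend(s, span=0.5).to_numpy(), s.to_numpy())

    def test_constant_series_unchanged(self):
        s = annual_series(np.full(15, 3.3), 1990)
        assert np.allclose(smooth_trend(s, span=0.7).to_numpy(), 3.3)

    def test_matches_statsmodels_lowess_on_noisy_quadratic(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(8)
        x = np.arange(1960, 2020, dtype=float)
        y = 0.02 * (x - 1990) ** 2 + rng.normal(0, 0.5, size=len(x))
        s = annual_series(y, 1960)
        span = 0.4
        ours = smooth_trend(s, span=span).to_numpy()
        theirs = sm.nonparametric.lowess(y, x, frac=span, it=0,
                                         return_sorted=False)
        # same neighbourhood definition up to one point; near-identical fits
        assert np.allclose(ours, theirs, atol=0.25)

    def test_invalid_span_rejected(self):
        s = annual_series(np.arange(10, dtype=float), 2000)
        with pytest.raises(ValueError):
            smooth_trend(s, span=0.0)
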