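"""Pipeline driver: stage orchestration and figure-ready table outputs.

Runs the full analysis — simulate (or load), standardize, reconstruct,
diversity, provenance, threat, survival — in dependency order and writes
every series as a year-indexed CSV plus a manifest (inputs, parameters, seed,
content hashes). Identical configuration and seed give byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from exsitu import diversity as dv
from exsitu import provenance as pv
from exsitu import reconstruct as rc
from exsitu import survival as sv
from exsitu import threat as th
from exsitu.records import (
    parse_collection_file,
    read_backbone_csv,
    enrich_records,
)
from exsitu.series import DEFAULT_WINDOW
from exsitu.synthetic import SyntheticConfig, generate_meta_collection, write_dataset

logger = logging.getLogger("exsitu")

ALL_STAGES = ("reconstruct", "diversity", "provenance", "threat", "survival")


class PipelineError(ValueError):
    """Configuration problem (e.g. a stage without its required inputs)."""


@dataclass
class PipelineConfig:
    output_dir: str | Path = "exsitu_out"
    seed: int = 0
    window: tuple[int, int] = DEFAULT_WINDOW
    breakpoint_year: int = 1993
    snapshot_year: int = 2021
    stages: Sequence[str] = ALL_STAGES
    # either a synthetic config ...
    synthetic: Optional[SyntheticConfig] = None
    # ... or real input paths
    records_path: Optional[str] = None
    backbone_path: Optional[str] = None
    tree_path: Optional[str] = None
    histories_path: Optional[str] = None
    snapshot_path: Optional[str] = None
    tree_list_path: Optional[str] = None
    holdings_path: Optional[str] = None
    collections_path: Optional[str] = None  # collection_id,country
    write_inputs: bool = False  # also dump the synthetic inputs as CSVs

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        syn = raw.pop("synthetic", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "synthetic"})
        if syn is not None:
            syn = {k: tuple(v) if isinstance(v, list) else v for k, v in syn.items()}
            cfg.synthetic = SyntheticConfig(**syn)
        if isinstance(cfg.window, list):
            cfg.window = tuple(cfg.window)
        return cfg

    def validate(self) -> "PipelineConfig":
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise PipelineError(f"unknown stage(s): {', '.join(sorted(unknown))}")
        if self.synthetic is None and self.records_path is None:
            raise PipelineError(
                "pipeline needs either a synthetic config or a records input "
                "(records_path) for the requested stages")
        return self


def _load_csv_map(path: str, key: str, value: str | None) -> dict:
    frame = pd.read_csv(path)
    if value is None:
        return dict.fromkeys(frame[key].astype(str), True)
    return dict(zip(frame[key].astype(str), frame[value]))


def _prepare(config: PipelineConfig):
    """Load or simulate inputs; return enriched records plus context."""
    if config.synthetic is not None:
        syn = config.synthetic
        if syn.seed != config.seed:
            syn = SyntheticConfig(**{**vars(syn), "seed": config.seed})
        dataset = generate_meta_collection(syn)
        if config.write_inputs:
            write_dataset(dataset, Path(config.output_dir) / "inputs")
        enriched = enrich_records(dataset.records, dataset.backbone,
                                  dataset.iucn_snapshot, dataset.tree_list,
                                  dataset.holdings)
        return enriched, dataset.histories, dataset.tree, dataset.collection_countries
    records, report = parse_collection_file(config.records_path)
    logger.info("parsed %d records (excluded material=%d, failed=%d)",
                report.kept, report.excluded_material,
                report.failed_dates + report.invalid_interval)
    if config.backbone_path is None:
        raise PipelineError("standardize stage needs a backbone input "
                            "(backbone_path)")
    backbone = read_backbone_csv(config.backbone_path)
    snapshot = _load_csv_map(config.snapshot_path, "taxon", "category") \
        if config.snapshot_path else {}
    tree_list = set(_load_csv_map(config.tree_list_path, "taxon", None)) \
        if config.tree_list_path else set()
    holdings = {k: int(v) for k, v in _load_csv_map(
        config.holdings_path, "taxon", "n_global_collections").items()} \
        if config.holdings_path else {}
    enriched = enrich_records(records, backbone, snapshot, tree_list, holdings)
    histories = th.read_assessment_history_csv(config.histories_path) \
        if config.histories_path else {}
    tree = dv.load_tree(config.tree_path) if config.tree_path else None
    countries = {str(k): str(v) for k, v in _load_csv_map(
        config.collections_path, "collection_id", "country").items()} \
        if config.collections_path else {}
    return enriched, histories, tree, countries


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages and return the output manifest."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    window = tuple(config.window)
    stages = list(config.stages)
    outputs: dict[str, Path] = {}
    summary: dict[str, object] = {}

    def save(name: str, frame) -> None:
        path = outdir / f"{name}.csv"
        if isinstance(frame, pd.Series):
            frame = frame.to_frame()
        frame.to_csv(path)
        outputs[name] = path

    t0 = time.perf_counter()
    enriched, histories, tree, countries = _prepare(config)
    logger.info("inputs ready: %d records (%.1fs)", len(enriched),
                time.perf_counter() - t0)

    if tree is None and "diversity" in stages:
        raise PipelineError("diversity stage needs a phylogeny input (tree_path)")
    if not histories and "threat" in stages and config.synthetic is None \
            and config.histories_path is None:
        raise PipelineError("threat stage needs assessment histories "
                            "(histories_path)")

    intervals, clip = rc.accession_intervals(enriched, config.snapshot_year,
                                             window=window)
    regions = {}
    for cid, country in countries.items():
        try:
            regions[cid] = pv.native_region(country, collection_id=cid)
        except KeyError:
            logger.warning("no TDWG mapping for country %r; collection %s "
                           "excluded from native analyses", country, cid)
    status_map = pv.native_status_map(enriched, regions)
    intervals["native_status"] = [
        status_map.get((c, a), "unknown")
        for c, a in zip(intervals["collection_id"], intervals["accession_id"])]

    if "reconstruct" in stages:
        t = time.perf_counter()
        counts = rc.annual_counts(intervals, window)
        gains, losses, net = rc.turnover(intervals, window)
        save("annual_counts", counts)
        save("turnover", pd.DataFrame({"gains": gains, "losses": losses,
                                       "net": net,
                                       "net_5y": rc.rolling_mean(net, 5)}))
        neg = net.index[(net < 0)]
        summary["trajectory"] = rc.classify_trajectory(counts)
        summary["first_net_negative_year"] = int(neg[0]) if len(neg) else None
        summary["peak_year"] = int(counts.idxmax())
        summary["peak_accessions"] = float(counts.max())
        logger.info("reconstruct done (%.1fs)", time.perf_counter() - t)

    if "diversity" in stages:
        t = time.perf_counter()
        genus_tree, dropped = dv.trim_to_genus_tree(tree)
        acc = {rank.lower(): dv.accumulation_series(intervals, rank, window)
               for rank in ("SPECIES", "GENUS", "FAMILY")}
        pd_ser, coverage = dv.pd_series(intervals, genus_tree, window)
        save("diversity_accumulation", pd.DataFrame(acc))
        save("faith_pd", pd_ser)
        summary["pd_coverage"] = {"n_covered": coverage["n_covered"],
                                  "n_missing": coverage["n_missing"],
                                  "tips_dropped_at_trim": len(dropped)}
        logger.info("diversity done (%.1fs)", time.perf_counter() - t)

    if "provenance" in stages:
        t = time.perf_counter()
        props = pv.provenance_series(intervals, window)
        incoming = pv.incoming_by_provenance(intervals, window)
        save("provenance_proportions", props)
        save("incoming_by_provenance", incoming)
        wild_prop_5y = rc.rolling_mean(props["WILD"], 5)
        summary["peak_wild_year"] = int(wild_prop_5y.idxmax())
        summary["peak_wild_pct"] = float(100 * wild_prop_5y.max())
        try:
            summary["wild_acquisition_change_pct"] = pv.relative_change(
                incoming["WILD"], config.breakpoint_year)
        except (ValueError, ZeroDivisionError) as exc:
            summary["wild_acquisition_change_pct"] = None
            logger.warning("wild relative change unavailable: %s", exc)
        native, non_native = pv.native_series(intervals, regions, window)
        save("native_series", pd.DataFrame({"native": native,
                                            "non_native": non_native}))
        classified = intervals[intervals["native_status"]
                               .isin(["native", "non_native"])]
        nn_gain = classified[classified["native_status"] == "non_native"]
        nn_series = rc.turnover(nn_gain, window)[0].rename("non_native_gains")
        save("non_native_gains", nn_series)
        try:
            summary["nonnative_acquisition_change_pct"] = pv.relative_change(
                nn_series, config.breakpoint_year)
        except (ValueError, ZeroDivisionError) as exc:
            summary["nonnative_acquisition_change_pct"] = None
            logger.warning("non-native relative change unavailable: %s", exc)
        logger.info("provenance done (%.1fs)", time.perf_counter() - t)

    if "threat" in stages:
        t = time.perf_counter()
        threat_acc, nonthreat_acc = th.threat_accumulation(intervals, window)
        save("threat_accumulation",
             pd.DataFrame({"threatened": threat_acc,
                           "non_threatened": nonthreat_acc}))
        props, slope, intercept = th.new_threat_proportion_series(
            intervals, (max(1978, window[0]), window[1]))
        save("new_threat_proportion", props)
        summary["new_threat_proportion_slope_per_year"] = slope
        cohort = th.select_responsive_cohort(histories)
        summary["responsive_cohort_size"] = len(cohort)
        if cohort:
            des_years = {t_: th.designation_year(h)
                         for t_, h in histories.items() if t_ in cohort}
            gains_frame = intervals[intervals["matched"]]
            counts = th.net_year_counts(gains_frame, cohort, des_years)
            save("net_year_counts",
                 pd.DataFrame({"net_year": np.arange(-10, 11),
                               "accessions": counts}).set_index("net_year"))
            try:
                welch = th.responsiveness_test(counts)
                summary["responsiveness"] = {
                    "t": welch.t_statistic, "df": welch.degrees_of_freedom,
                    "p": welch.p_value, "cohens_d": welch.cohens_d,
                    "ci95": list(welch.ci95)}
                _write_welch(outdir / "responsiveness_welch.txt", welch)
                outputs["responsiveness_welch"] = outdir / "responsiveness_welch.txt"
            except (ValueError, ZeroDivisionError) as exc:
                logger.warning("responsiveness test unavailable: %s", exc)
        dist = th.individuals_per_species_distribution(enriched)
        save("individuals_per_species", dist)
        save("mean_individuals_threatened",
             th.mean_individuals_series(enriched, "THREATENED", window))
        programme_id = sorted({r.collection_id for r in enriched})[0]
        current = [r for r in enriched if r.status_alive]
        prog = [r for r in current if r.collection_id == programme_id]
        if prog and len(prog) < len(current):
            comparison = th.compare_cohorts(prog, current)
            (outdir / "cohort_comparison.json").write_text(
                json.dumps(comparison, indent=2, sort_keys=True), encoding="utf-8")
            outputs["cohort_comparison"] = outdir / "cohort_comparison.json"
            summary["programme_threat_proportion"] = \
                comparison["cohort_a"]["threatened_taxon_proportion"]
            summary["meta_threat_proportion"] = \
                comparison["cohort_b"]["threatened_taxon_proportion"]
        logger.info("threat done (%.1fs)", time.perf_counter() - t)

    if "survival" in stages:
        t = time.perf_counter()
        inputs, _ = sv.accession_survival_inputs(enriched)
        curve = sv.km_fit(inputs)
        median, ci = sv.km_median(curve, with_ci=True)
        save("km_overall", curve.to_frame().set_index("time"))
        medians = {"all_accessions": {"median": median, "ci95": list(ci),
                                      "n": curve.n_total}}
        snapshot_date = date(config.snapshot_year, 12, 31)
        for strat in ("TREE", "ENDEMIC", "THREATENED_ACCESSIONS",
                      "THREATENED_SPECIES", "NATIVE", "NAME_CLASS"):
            kwargs = {}
            if strat == "THREATENED_SPECIES":
                kwargs["snapshot_date"] = snapshot_date
            if strat == "NATIVE":
                kwargs["native_status"] = status_map
            fits = sv.stratified_km(enriched, strat, **kwargs)
            for name, res in fits.items():
                medians[f"{strat.lower()}:{name}"] = {
                    "median": res.median, "ci95": list(res.ci95), "n": res.n}
        rows = pd.DataFrame([
            {"stratum": k, "median_years": v["median"],
             "ci_low": v["ci95"][0], "ci_high": v["ci95"][1], "n": v["n"]}
            for k, v in medians.items()]).set_index("stratum")
        save("survival_medians", rows)
        summary["median_survival_years"] = {k: v["median"]
                                            for k, v in medians.items()}
        logger.info("survival done (%.1fs)", time.perf_counter() - t)

    manifest = {
        "seed": config.seed,
        "window": list(window),
        "breakpoint_year": config.breakpoint_year,
        "stages": stages,
        "summary": summary,
        "outputs": {name: {"path": str(path.relative_to(outdir)),
                           "sha256": _sha256(path)}
                    for name, path in sorted(outputs.items())},
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return manifest


def _write_welch(path: Path, welch: th.WelchResult) -> None:
    lines = [
        f"t_statistic\t{welch.t_statistic:.6g}",
        f"degrees_of_freedom\t{welch.degrees_of_freedom:.6g}",
        f"p_value\t{welch.p_value:.6g}",
        f"ci95_low\t{welch.ci95[0]:.6g}",
        f"ci95_high\t{welch.ci95[1]:.6g}",
        f"cohens_d\t{welch.cohens_d:.6g}",
    ]
    for label, (n, mean, sd) in zip(("before", "after"), welch.group_summaries):
        lines.append(f"{label}\tn={n}\tmean={mean:.6g}\tsd={sd:.6g}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
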