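"""Synthetic meta-collection generator.

Generates accession records, a taxonomic backbone with TDWG level-3
distributions, an ultrametric genus phylogeny and IUCN-style assessment
histories that jointly carry the statistical structure the downstream
analyses assume:

* arrivals follow an inhomogeneous Poisson process whose cumulative intensity
  is logistic (sigmoidal collection growth with a carrying capacity);
* provenance is a four-category mixture; after the policy breakpoint year the
  WILD acquisition probability is multiplied by ``wild_multiplier`` (the
  remaining categories are rescaled to keep the mixture summing to one), and
  likewise the probability of sourcing non-native material is multiplied by
  ``nonnative_multiplier``;
* lifespans are Weibull (or exponential) with a configurable median, longer
  for trees; alive accessions are right-censored at a per-accession "last
  inventory" date lagging 0-3 years behind the snapshot;
* a configurable fraction of taxa are endemic (single botanical country), and
  assessment histories are produced by an annual designation hazard.

Everything is driven by one ``numpy`` Generator, so a fixed seed fixes every
downstream series bit for bit.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import yaml
from dendropy.simulate import treesim

from exsitu.provenance import load_country_l3_mapping
from exsitu.records import BackboneTaxon, PlantingRecord, Provenance
from exsitu.threat import AssessmentEvent, write_assessment_history_csv
from exsitu.records import write_backbone_csv, write_records_csv

_SYLLABLES = ["ba", "ce", "da", "fe", "go", "hi", "ka", "la", "mi", "no",
              "pa", "qui", "ra", "se", "ti", "ul", "ve", "xa", "yo", "zu"]
_AUTHORS = ["L.", "Mill.", "DC.", "Benth.", "Hook.f.", "Thunb.", "Lam.",
            "Willd.", "Sm.", "R.Br.", "A.Gray", "Baker", "Kunth", "Franch.",
            "Maxim.", "Engl.", "Schltr.", "Standl."]


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic meta-collection.

    Defaults emulate the structure of a century of records from ~20
    institutions reaching carrying capacity: sigmoidal arrival intensity with
    its inflection at the 1993 policy breakpoint, a ~15-year median lifespan
    (20 for trees), and post-breakpoint multipliers on wild and non-native
    acquisition.
    """

    seed: int = 0
    n_collections: int = 20
    window: tuple[int, int] = (1921, 2021)
    # logistic cumulative arrival intensity
    carrying_capacity: float = 21_800.0
    midpoint_year: float = 1993.0
    growth_rate: float = 0.09
    # provenance mixture before the breakpoint (must sum to 1)
    provenance_mix: dict = field(default_factory=lambda: {
        "WILD": 0.35, "WILD_DERIVED": 0.10, "GARDEN": 0.15, "UNKNOWN": 0.40})
    breakpoint_year: int = 1993
    wild_multiplier: float = 0.56
    nonnative_multiplier: float = 0.62
    nonnative_share: float = 0.65  # pre-breakpoint P(new accession is non-native)
    # lifespans
    lifespan_family: str = "weibull"  # or "exponential"
    lifespan_median: float = 15.0
    tree_lifespan_median: float = 20.0
    weibull_shape: float = 1.2
    tree_fraction: float = 0.15
    # taxonomy
    n_families: int = 40
    n_genera: int = 150
    n_species: int = 600
    endemic_fraction: float = 0.15
    infraspecific_fraction: float = 0.08
    hybrid_fraction: float = 0.03
    # record noise
    cultivar_rate: float = 0.12
    typo_rate: float = 0.02
    blank_authority_rate: float = 0.2
    mean_extra_plantings: float = 0.4
    inventory_lag_years: float = 3.0
    # assessments
    assessment_hazard: float = 0.004
    assessment_window: tuple[int, int] = (1980, 2019)
    snapshot_year: int = 2021
    # conservation-programme collection (first collection id)
    programme: bool = True
    programme_wild_share: float = 0.75
    programme_threat_boost: float = 5.0

    def validate(self) -> "SyntheticConfig":
        mix = {Provenance(k): float(v) for k, v in self.provenance_mix.items()}
        if any(not (0 <= v <= 1) for v in mix.values()) or \
                abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("provenance_mix must be probabilities summing to 1")
        for name in ("wild_multiplier", "nonnative_multiplier", "tree_fraction",
                     "endemic_fraction", "nonnative_share"):
            v = getattr(self, name)
            if not (0 <= v <= 1 + 1e-9) and "multiplier" not in name:
                raise ValueError(f"{name} must lie in [0, 1]")
            if v < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.lifespan_median <= 0 or self.tree_lifespan_median <= 0:
            raise ValueError("lifespan medians must be positive")
        start, end = self.window
        if not (start < self.breakpoint_year < end <= self.snapshot_year):
            raise ValueError("need start < breakpoint < end <= snapshot year")
        if self.lifespan_family not in ("weibull", "exponential"):
            raise ValueError("lifespan_family must be weibull or exponential")
        if self.n_genera < 2 or self.n_species < self.n_genera:
            raise ValueError("need >= 2 genera and n_species >= n_genera")
        return self


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, as in-memory objects."""

    records: list[PlantingRecord]
    backbone: list[BackboneTaxon]
    histories: dict[str, list[AssessmentEvent]]
    tree: dendropy.Tree
    iucn_snapshot: dict[str, str]
    tree_list: set[str]
    holdings: dict[str, int]
    collection_countries: dict[str, str]
    config: SyntheticConfig

    def __iter__(self):  # (records, backbone, histories, tree) unpacking
        return iter((self.records, self.backbone, self.histories, self.tree))


# ---------------------------------------------------------------------------
# Names and phylogeny
# ---------------------------------------------------------------------------

def _make_names(rng: np.random.Generator, n: int, n_syll: tuple[int, int],
                suffix: str = "", capitalize: bool = True) -> list[str]:
    names: list[str] = []
    seen: set[str] = set()
    while len(names) < n:
        k = int(rng.integers(n_syll[0], n_syll[1] + 1))
        word = "".join(rng.choice(_SYLLABLES) for _ in range(k)) + suffix
        if capitalize:
            word = word.capitalize()
        if word not in seen:
            seen.add(word)
            names.append(word)
    return names


def generate_phylogeny(n_genera: int, seed: int,
                       labels: Sequence[str] | None = None) -> dendropy.Tree:
    """Ultrametric pure-birth tree with one tip per genus.

    Deterministic given the seed; tip labels default to ``G0001``-style names
    unless ``labels`` provides ``n_genera`` names.
    """
    if n_genera < 2:
        raise ValueError("need at least two genera for a tree")
    tree = treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_genera,
        rng=random.Random(int(seed)))
    if labels is None:
        labels = [f"G{i + 1:04d}" for i in range(n_genera)]
    if len(labels) != n_genera:
        raise ValueError("labels length must equal n_genera")
    leaves = sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label)
    for leaf, label in zip(leaves, labels):
        leaf.taxon.label = label
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0
    # the final speciation pair gets zero-length terminal edges; extend every
    # leaf edge by the same small amount (keeps the tree ultrametric and all
    # branch lengths strictly positive)
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    eps = 0.01 * depth if depth > 0 else 0.01
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += eps
    return tree


# ---------------------------------------------------------------------------
# Backbone and assessments
# ---------------------------------------------------------------------------

def _build_backbone(cfg: SyntheticConfig, rng: np.random.Generator,
                    l3_pool: list[str]) -> tuple[list[BackboneTaxon], list[str]]:
    genera = _make_names(rng, cfg.n_genera, (3, 4))
    families = _make_names(rng, cfg.n_families, (2, 3), suffix="aceae")
    family_of_genus = {g: families[int(rng.integers(cfg.n_families))]
                       for g in genera}
    # every genus gets one species, the rest are distributed at random
    genus_of_species = list(genera)
    genus_of_species += [genera[int(rng.integers(cfg.n_genera))]
                         for _ in range(cfg.n_species - cfg.n_genera)]
    epithets = _make_names(rng, cfg.n_species, (2, 4), capitalize=False)
    infra_epithets = _make_names(rng, cfg.n_species, (2, 3), capitalize=False)
    taxa: list[BackboneTaxon] = []
    for i, (genus, epithet) in enumerate(zip(genus_of_species, epithets)):
        name = f"{genus} {epithet}"
        if rng.random() < cfg.hybrid_fraction:
            name = f"{genus} × {epithet}"
        elif rng.random() < cfg.infraspecific_fraction:
            rank = "var." if rng.random() < 0.5 else "subsp."
            name = f"{genus} {epithet} {rank} {infra_epithets[i]}"
        if rng.random() < cfg.endemic_fraction:
            dist = {l3_pool[int(rng.integers(len(l3_pool)))]}
        else:
            k = int(rng.integers(2, 6))
            dist = set(rng.choice(l3_pool, size=k, replace=False))
        taxa.append(BackboneTaxon(
            accepted_name=name,
            authority=_AUTHORS[int(rng.integers(len(_AUTHORS)))],
            family=family_of_genus[genus],
            distribution=frozenset(dist),
            is_tree=bool(rng.random() < cfg.tree_fraction),
            n_global_collections=int(min(500, rng.geometric(0.02))),
        ))
    return taxa, genera


_THREAT_FIRST = ["VU", "EN", "CR", "E", "R"]
_THREAT_FIRST_P = [0.40, 0.30, 0.10, 0.10, 0.10]
_THREAT_LATER = ["VU", "EN", "CR"]


def _build_histories(cfg: SyntheticConfig, rng: np.random.Generator,
                     taxa: Sequence[BackboneTaxon]
                     ) -> tuple[dict[str, list[AssessmentEvent]], dict[str, str]]:
    lo, hi = cfg.assessment_window
    histories: dict[str, list[AssessmentEvent]] = {}
    snapshot: dict[str, str] = {}
    for taxon in taxa:
        name = taxon.accepted_name
        events: list[AssessmentEvent] = []
        designated = None
        for year in range(lo, hi + 1):
            if rng.random() < cfg.assessment_hazard:
                designated = year
                break
        if designated is not None:
            cat = rng.choice(_THREAT_FIRST, p=_THREAT_FIRST_P)
            events.append(AssessmentEvent(name, designated, str(cat)))
            year = designated
            while True:
                year += int(rng.integers(5, 13))
                if year > cfg.snapshot_year:
                    break
                if rng.random() < 0.9:
                    cat = str(rng.choice(_THREAT_LATER))
                else:
                    cat = "LC" if rng.random() < 0.7 else "NT"
                events.append(AssessmentEvent(name, year, cat))
        elif rng.random() < 0.3:
            year = int(rng.integers(lo, hi + 1))
            events.append(AssessmentEvent(name, year, "LC"))
        if events:
            histories[name] = events
            last = events[-1].category
            snapshot[name] = {"E": "EN", "R": "NT"}.get(last, last)
        else:
            snapshot[name] = "LC" if rng.random() < 0.8 else "DD"
    return histories, snapshot


# ---------------------------------------------------------------------------
# Record generation
# ---------------------------------------------------------------------------

def _logistic_cdf(y: np.ndarray, t0: float, r: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-r * (y - t0)))


def _lifespan_scale(cfg: SyntheticConfig, median: float) -> float:
    if cfg.lifespan_family == "exponential":
        return median / np.log(2.0)
    return median / np.log(2.0) ** (1.0 / cfg.weibull_shape)


def _draw_lifespan(cfg: SyntheticConfig, rng: np.random.Generator,
                   median: float) -> float:
    scale = _lifespan_scale(cfg, median)
    if cfg.lifespan_family == "exponential":
        return float(rng.exponential(scale))
    return float(scale * rng.weibull(cfg.weibull_shape))


def _typo(rng: np.random.Generator, word: str) -> str:
    if len(word) < 4:
        return word
    i = int(rng.integers(1, len(word) - 1))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    repl = alphabet[int(rng.integers(26))]
    if repl == word[i]:
        repl = alphabet[(alphabet.index(repl) + 1) % 26]
    return word[:i] + repl + word[i + 1:]


def generate_meta_collection(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full synthetic meta-collection under the configured conditions."""
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)
    country_map = load_country_l3_mapping()
    countries = sorted(country_map)
    l3_pool = sorted({c for codes in country_map.values() for c in codes})

    taxa, genera = _build_backbone(cfg, rng, l3_pool)
    tree = generate_phylogeny(cfg.n_genera, int(rng.integers(2**31 - 1)),
                              labels=genera)
    histories, snapshot = _build_histories(cfg, rng, taxa)
    threatened_names = {n for n, c in snapshot.items()
                        if c in ("VU", "EN", "CR", "EW")}

    # collections: country assignment round-robin, lognormal size weights
    coll_ids = [f"C{i + 1:03d}" for i in range(cfg.n_collections)]
    coll_country = {cid: countries[i % len(countries)]
                    for i, cid in enumerate(coll_ids)}
    weights = rng.lognormal(mean=0.0, sigma=0.8, size=cfg.n_collections)
    weights /= weights.sum()

    # per-collection native / non-native taxon pools
    native_pool: dict[str, np.ndarray] = {}
    nonnative_pool: dict[str, np.ndarray] = {}
    for cid in coll_ids:
        region = country_map[coll_country[cid]]
        flags = np.array([bool(t.distribution & region) for t in taxa])
        native_pool[cid] = np.nonzero(flags)[0]
        nonnative_pool[cid] = np.nonzero(~flags)[0]

    threat_idx = np.array([t.accepted_name in threatened_names for t in taxa])

    def _pick_taxon(cid: str, native: bool, boost: float) -> int:
        pool = native_pool[cid] if native else nonnative_pool[cid]
        if pool.size == 0:
            pool = np.arange(len(taxa))
        if boost > 1.0:
            w = np.where(threat_idx[pool], boost, 1.0)
            w /= w.sum()
            return int(rng.choice(pool, p=w))
        return int(rng.choice(pool))

    start_y, end_y = cfg.window
    years = np.arange(start_y, end_y + 1)
    cdf = _logistic_cdf(np.append(years, end_y + 1).astype(float),
                        cfg.midpoint_year, cfg.growth_rate)
    lam = cfg.carrying_capacity * np.diff(cdf)

    mix_names = [p.value for p in Provenance]
    base_mix = np.array([cfg.provenance_mix[n] for n in mix_names])

    def _mix_for(year: int, programme: bool) -> np.ndarray:
        mix = base_mix.copy()
        if programme:
            wild = cfg.programme_wild_share
            i_w = mix_names.index("WILD")
            others = np.delete(mix, i_w)
            mix = np.insert(others / others.sum() * (1 - wild), i_w, wild)
        if year > cfg.breakpoint_year:
            i_w = mix_names.index("WILD")
            new_wild = mix[i_w] * cfg.wild_multiplier
            others = np.delete(mix, i_w)
            mix = np.insert(others / others.sum() * (1 - new_wild), i_w, new_wild)
        return mix

    snapshot_date = date(cfg.snapshot_year, 12, 31)
    records: list[PlantingRecord] = []
    total = 0
    acc_serial = 0
    for year, intensity in zip(years, lam):
        n_y = int(rng.poisson(intensity))
        n_y = min(n_y, int(cfg.carrying_capacity) - total)  # cumulative <= K
        total += n_y
        p_nn = cfg.nonnative_share
        if year > cfg.breakpoint_year:
            p_nn *= cfg.nonnative_multiplier
        for _ in range(n_y):
            ci = int(rng.choice(cfg.n_collections, p=weights))
            cid = coll_ids[ci]
            programme = cfg.programme and ci == 0
            prov = Provenance(str(rng.choice(mix_names, p=_mix_for(year, programme))))
            native = rng.random() >= p_nn
            boost = cfg.programme_threat_boost if programme else 1.0
            taxon = taxa[_pick_taxon(cid, native, boost)]

            acc_serial += 1
            accession_id = f"A{acc_serial:06d}"
            acc_date = date(year, 1, 1) + timedelta(days=int(rng.integers(0, 365)))
            median = (cfg.tree_lifespan_median if taxon.is_tree
                      else cfg.lifespan_median)
            lifespan = max(_draw_lifespan(cfg, rng, median), 0.02)
            death_days = min(int(round(lifespan * 365.25)), 500 * 365)
            death_date = acc_date + timedelta(days=death_days)
            inv_lag = rng.uniform(0.0, cfg.inventory_lag_years)
            inv_date = snapshot_date - timedelta(days=int(round(inv_lag * 365.25)))
            inv_date = max(inv_date, acc_date)

            raw_name = taxon.accepted_name
            if rng.random() < cfg.typo_rate:
                parts = raw_name.split(" ")
                j = 1 if len(parts) > 1 else 0
                parts[j] = _typo(rng, parts[j])
                raw_name = " ".join(parts)
            if rng.random() < cfg.cultivar_rate:
                raw_name += f" '{_make_names(rng, 1, (2, 2))[0]}'"
            authority = "" if rng.random() < cfg.blank_authority_rate \
                else taxon.authority

            n_plantings = 1 + int(rng.poisson(cfg.mean_extra_plantings))
            accession_dead = death_date <= inv_date
            for p in range(n_plantings):
                last_planting = p == n_plantings - 1
                if last_planting:
                    p_death = death_date
                else:
                    days = min(int(round(lifespan * rng.uniform(0.3, 1.0)
                                         * 365.25)), death_days)
                    p_death = acc_date + timedelta(days=days)
                if p_death <= inv_date:
                    status_date, alive = p_death, False
                else:
                    status_date, alive = inv_date, True
                records.append(PlantingRecord(
                    collection_id=cid,
                    accession_id=accession_id,
                    planting_id=f"{accession_id}-{p + 1}",
                    raw_name=raw_name,
                    raw_authority=authority,
                    provenance=prov,
                    accession_date=acc_date,
                    last_status_date=max(status_date, acc_date),
                    status_alive=alive,
                ))
            # ensure the accession event flag reflects the intended fate
            assert accession_dead == (death_date <= inv_date)

    tree_list = {t.accepted_name for t in taxa if t.is_tree}
    holdings = {t.accepted_name: t.n_global_collections for t in taxa}
    return SyntheticDataset(
        records=records, backbone=taxa, histories=histories, tree=tree,
        iucn_snapshot=snapshot, tree_list=tree_list, holdings=holdings,
        collection_countries=coll_country, config=cfg,
    )


# ---------------------------------------------------------------------------
# File output (same formats records_io / diversity read)
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Write the dataset as the CSV/newick files the pipeline reads."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "records": out / "records.csv",
        "backbone": out / "backbone.csv",
        "histories": out / "assessment_histories.csv",
        "tree": out / "phylogeny.nwk",
        "snapshot": out / "iucn_snapshot.csv",
        "tree_list": out / "tree_species.csv",
        "holdings": out / "holdings.csv",
        "collections": out / "collections.csv",
        "metadata": out / "metadata.yaml",
    }
    write_records_csv(dataset.records, paths["records"])
    write_backbone_csv(dataset.backbone, paths["backbone"])
    write_assessment_history_csv(dataset.histories, paths["histories"])
    dataset.tree.write(path=str(paths["tree"]), schema="newick")
    _write_two_col(paths["snapshot"], ["taxon", "category"],
                   sorted(dataset.iucn_snapshot.items()))
    _write_two_col(paths["tree_list"], ["taxon"],
                   [(t,) for t in sorted(dataset.tree_list)])
    _write_two_col(paths["holdings"], ["taxon", "n_global_collections"],
                   sorted(dataset.holdings.items()))
    _write_two_col(paths["collections"], ["collection_id", "country"],
                   sorted(dataset.collection_countries.items()))
    meta = {"seed": dataset.config.seed,
            "n_records": len(dataset.records),
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in vars(dataset.config).items()}}
    paths["metadata"].write_text(yaml.safe_dump(meta), encoding="utf-8")
    return paths


def _write_two_col(path: Path, header: list[str], rows) -> None:
    import csv

    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for row in rows:
            w.writerow(list(row))
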