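"""Domain types and I/O for living-collection accession records.

A *planting* is one living individual; an *accession* is the batch it arrived
in; a *collection* is one institution's records. This module parses delimited
exports of planting records into typed rows (keeping only living plantings,
with a parse report of everything excluded), standardizes taxon names against
a backbone of accepted names via a conservative matching cascade, and joins on
the enrichment sources (threat categories, tree list, global holdings).
"""

from __future__ import annotations

import csv
import enum
from collections import Counter
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from exsitu.names import (
    ParsedName,
    author_tokens,
    canonical_name,
    canonical_tokens,
    parse_name,
    rank_normalized_tokens,
    strip_cultivar,
    token_sequence_distance,
)


class Provenance(str, enum.Enum):
    WILD = "WILD"
    WILD_DERIVED = "WILD_DERIVED"
    GARDEN = "GARDEN"
    UNKNOWN = "UNKNOWN"


class MaterialType(str, enum.Enum):
    LIVING_PLANTING = "LIVING_PLANTING"
    SEED = "SEED"
    HERBARIUM = "HERBARIUM"
    PROPAGATION = "PROPAGATION"
    OTHER = "OTHER"


class MatchClass(str, enum.Enum):
    EXACT = "EXACT"
    RANK_NORMALIZED = "RANK_NORMALIZED"
    TYPO = "TYPO"
    AMBIGUOUS = "AMBIGUOUS"
    UNMATCHED = "UNMATCHED"


class AuthorAgreement(str, enum.Enum):
    FULL = "FULL"
    PARTIAL = "PARTIAL"
    NONE = "NONE"
    NO_AUTHOR = "NO_AUTHOR"


class NameClass(str, enum.Enum):
    #: species, subspecies, varieties, forma
    BIOLOGICAL = "BIOLOGICAL"
    #: cultivars and hybrids
    HORTICULTURAL = "HORTICULTURAL"


#: IUCN Red List categories under the current scheme.
IUCN_CATEGORIES = ("NE", "DD", "LC", "NT", "VU", "EN", "CR", "EW", "EX")


@dataclass(frozen=True)
class PlantingRecord:
    """One living planting: the atomic unit of every series in the package."""

    collection_id: str
    accession_id: str
    planting_id: str
    raw_name: str
    raw_authority: str
    provenance: Provenance
    accession_date: date
    last_status_date: date
    status_alive: bool
    material_type: MaterialType = MaterialType.LIVING_PLANTING

    def __post_init__(self) -> None:
        if self.accession_date > self.last_status_date:
            raise ValueError(
                f"accession date {self.accession_date} after last status "
                f"date {self.last_status_date} for planting {self.planting_id}"
            )


@dataclass(frozen=True)
class BackboneTaxon:
    """An accepted name with its authority and enrichment attributes."""

    accepted_name: str
    authority: str = ""
    family: str = ""
    distribution: frozenset[str] = frozenset()
    is_tree: bool = False
    n_global_collections: int = 0

    def __post_init__(self) -> None:
        if not self.accepted_name.strip():
            raise ValueError("backbone taxon needs a nonempty accepted name")
        if self.n_global_collections < 0:
            raise ValueError("n_global_collections must be nonnegative")

    @property
    def parsed(self) -> ParsedName:
        return parse_name(self.accepted_name)

    @property
    def genus(self) -> str:
        return self.parsed.genus.capitalize()


@dataclass(frozen=True)
class MatchResult:
    query_name: str
    matched_taxon: Optional[BackboneTaxon]
    match_class: MatchClass
    author_agreement: AuthorAgreement

    def __post_init__(self) -> None:
        unresolved = self.match_class in (MatchClass.AMBIGUOUS, MatchClass.UNMATCHED)
        if unresolved != (self.matched_taxon is None):
            raise ValueError("matched_taxon must be absent exactly for "
                             "AMBIGUOUS/UNMATCHED results")


@dataclass(frozen=True)
class EnrichedRecord:
    """A planting record after standardization and enrichment joins."""

    record: PlantingRecord
    backbone: Optional[BackboneTaxon]
    match: Optional[MatchResult]
    iucn_current_category: str
    name_class: NameClass

    def __getattr__(self, item):  # delegate plain record fields
        return getattr(self.record, item)

    @property
    def accepted_name(self) -> Optional[str]:
        return self.backbone.accepted_name if self.backbone else None

    @property
    def species(self) -> str:
        """Analysis name: accepted if matched, else the canonical raw name."""
        if self.backbone is not None:
            return self.backbone.accepted_name
        return canonical_name(self.record.raw_name)

    @property
    def genus(self) -> Optional[str]:
        return self.backbone.genus if self.backbone else None

    @property
    def family(self) -> Optional[str]:
        return self.backbone.family if self.backbone else None

    @property
    def distribution(self) -> frozenset[str]:
        return self.backbone.distribution if self.backbone else frozenset()


@dataclass
class ParseReport:
    """Accounting of what a parse kept, excluded and could not read."""

    total_rows: int = 0
    kept: int = 0
    excluded_material: int = 0
    failed_dates: int = 0
    invalid_interval: int = 0
    missing_fields: int = 0
    unknown_provenance: Counter = field(default_factory=Counter)
    failed_rows: list[int] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Dialects: mapping institutional export vocabularies onto the domain types.
# ---------------------------------------------------------------------------

MANDATORY_FIELDS = (
    "collection_id", "accession_id", "planting_id", "raw_name",
    "provenance", "accession_date", "last_status_date", "status",
    "material_type",
)


@dataclass
class Dialect:
    """Column mapping plus code vocabularies for one export format."""

    columns: dict[str, str]
    provenance_map: dict[str, Provenance] = field(default_factory=dict)
    material_map: dict[str, MaterialType] = field(default_factory=dict)
    alive_values: frozenset[str] = frozenset({"ALIVE", "A", "EXISTING", "TRUE", "1"})

    def __post_init__(self) -> None:
        missing = [f for f in MANDATORY_FIELDS if f not in self.columns]
        if missing:
            raise DialectError(f"dialect missing mandatory column mappings: "
                               f"{', '.join(missing)}")
        self.provenance_map = {k.upper(): Provenance(v)
                               for k, v in self.provenance_map.items()}
        self.material_map = {k.upper(): MaterialType(v)
                             for k, v in self.material_map.items()}
        self.alive_values = frozenset(v.upper() for v in self.alive_values)


class DialectError(ValueError):
    """A dialect/configuration problem (e.g. a missing mandatory column)."""


def load_dialect(path: str | Path) -> Dialect:
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return Dialect(
        columns=dict(raw["columns"]),
        provenance_map=dict(raw.get("provenance_map", {})),
        material_map=dict(raw.get("material_map", {})),
        alive_values=frozenset(raw.get("alive_values",
                                       ["ALIVE", "A", "EXISTING", "TRUE", "1"])),
    )


#: Dialect of the package's own canonical CSV output (identity mappings).
CANONICAL_DIALECT = Dialect(
    columns={f: f for f in MANDATORY_FIELDS} | {"raw_authority": "raw_authority"},
    provenance_map={p.value: p for p in Provenance},
    material_map={m.value: m for m in MaterialType},
    alive_values=frozenset({"TRUE", "1", "ALIVE"}),
)


def parse_flexible_date(text: str) -> date:
    """Parse ISO dates at day, month or year resolution.

    Year-only values anchor to 1 July (the unbiased midpoint for duration
    arithmetic); year-month values anchor to the 15th.
    """
    s = (text or "").strip()
    parts = s.split("-")
    try:
        if len(parts) == 3:
            return date(int(parts[0]), int(parts[1]), int(parts[2]))
        if len(parts) == 2:
            return date(int(parts[0]), int(parts[1]), 15)
        if len(parts) == 1 and s:
            return date(int(s), 7, 1)
    except ValueError as exc:
        raise ValueError(f"unparseable date {text!r}") from exc
    raise ValueError(f"unparseable date {text!r}")


def parse_collection_file(
    path: str | Path,
    dialect: Dialect = CANONICAL_DIALECT,
) -> tuple[list[PlantingRecord], ParseReport]:
    """Parse one collection export, keeping only living plantings.

    Rows that fail date parsing or violate the date-order invariant are
    excluded but accounted for in the report, never silently dropped.
    """
    report = ParseReport()
    records: list[PlantingRecord] = []
    try:
        fh = open(path, "r", encoding="utf-8", newline="")
    except OSError as exc:
        raise IOError(f"cannot read collection file {path}: {exc}") from exc
    with fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [col for col in dialect.columns.values() if col not in header]
        if missing:
            raise DialectError(
                f"collection file {path} lacks mapped column(s): "
                f"{', '.join(sorted(set(missing)))}")
        for i, row in enumerate(reader):
            report.total_rows += 1
            get = lambda f: (row.get(dialect.columns[f], "") or "").strip() \
                if f in dialect.columns else ""
            material_code = get("material_type").upper()
            material = dialect.material_map.get(material_code)
            if material is None:
                try:
                    material = MaterialType(material_code)
                except ValueError:
                    material = MaterialType.OTHER
            if material is not MaterialType.LIVING_PLANTING:
                report.excluded_material += 1
                continue
            prov_code = get("provenance").upper()
            prov = dialect.provenance_map.get(prov_code)
            if prov is None:
                try:
                    prov = Provenance(prov_code)
                except ValueError:
                    prov = Provenance.UNKNOWN
                    report.unknown_provenance[prov_code] += 1
            try:
                acc_date = parse_flexible_date(get("accession_date"))
                status_date = parse_flexible_date(get("last_status_date"))
            except ValueError:
                report.failed_dates += 1
                report.failed_rows.append(i)
                continue
            if acc_date > status_date:
                report.invalid_interval += 1
                report.failed_rows.append(i)
                continue
            name = get("raw_name")
            if not name:
                report.missing_fields += 1
                report.failed_rows.append(i)
                continue
            records.append(PlantingRecord(
                collection_id=get("collection_id"),
                accession_id=get("accession_id"),
                planting_id=get("planting_id"),
                raw_name=name,
                raw_authority=get("raw_authority"),
                provenance=prov,
                accession_date=acc_date,
                last_status_date=status_date,
                status_alive=get("status").upper() in dialect.alive_values,
                material_type=material,
            ))
            report.kept += 1
    return records, report


def write_records_csv(records: Iterable[PlantingRecord], path: str | Path) -> None:
    """Write records in the canonical dialect (round-trips through parsing)."""
    cols = list(MANDATORY_FIELDS) + ["raw_authority"]
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(cols)
        for r in records:
            writer.writerow([
                r.collection_id, r.accession_id, r.planting_id, r.raw_name,
                r.provenance.value, r.accession_date.isoformat(),
                r.last_status_date.isoformat(),
                "TRUE" if r.status_alive else "FALSE",
                r.material_type.value, r.raw_authority,
            ])


# ---------------------------------------------------------------------------
# Backbone I/O
# ---------------------------------------------------------------------------

def write_backbone_csv(taxa: Iterable[BackboneTaxon], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["accepted_name", "authority", "family",
                         "distribution", "is_tree", "n_global_collections"])
        for t in taxa:
            writer.writerow([
                t.accepted_name, t.authority, t.family,
                "|".join(sorted(t.distribution)),
                "TRUE" if t.is_tree else "FALSE", t.n_global_collections,
            ])


def read_backbone_csv(path: str | Path) -> list[BackboneTaxon]:
    taxa = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        for row in csv.DictReader(fh):
            dist = frozenset(c for c in (row.get("distribution") or "").split("|") if c)
            taxa.append(BackboneTaxon(
                accepted_name=row["accepted_name"],
                authority=row.get("authority", "") or "",
                family=row.get("family", "") or "",
                distribution=dist,
                is_tree=(row.get("is_tree", "").upper() in ("TRUE", "1")),
                n_global_collections=int(row.get("n_global_collections") or 0),
            ))
    return taxa


# ---------------------------------------------------------------------------
# Name matching cascade
# ---------------------------------------------------------------------------

class BackboneIndex:
    """Pre-indexed backbone for repeated matching of raw names."""

    def __init__(self, taxa: Sequence[BackboneTaxon]):
        if not taxa:
            raise ValueError("backbone must be nonempty")
        # Sort for determinism / order-independence of tie handling.
        self.taxa = sorted(taxa, key=lambda t: (t.accepted_name, t.authority))
        self.exact: dict[str, list[BackboneTaxon]] = {}
        self.ranknorm: dict[str, list[BackboneTaxon]] = {}
        self._tokenized: list[tuple[tuple[str, ...], BackboneTaxon]] = []
        for t in self.taxa:
            toks = canonical_tokens(t.accepted_name)
            rtoks = tuple(rank_normalized_tokens(toks))
            self.exact.setdefault(" ".join(toks), []).append(t)
            self.ranknorm.setdefault(" ".join(rtoks), []).append(t)
            self._tokenized.append((rtoks, t))

    def candidates_by_length(self, n: int):
        return [(toks, t) for toks, t in self._tokenized if len(toks) == n]


def _author_agreement(raw_authority: str, taxon: BackboneTaxon) -> AuthorAgreement:
    q = author_tokens(raw_authority)
    c = author_tokens(taxon.authority)
    if not q or not c:
        return AuthorAgreement.NO_AUTHOR
    if q == c:
        return AuthorAgreement.FULL
    if q & c:
        return AuthorAgreement.PARTIAL
    return AuthorAgreement.NONE


def match_taxon_name(
    raw_name: str,
    raw_authority: str,
    backbone: Sequence[BackboneTaxon] | BackboneIndex,
    per_token_bound: int = 1,
    total_bound: int = 2,
) -> MatchResult:
    """Standardize one raw name against the backbone.

    First-success cascade: EXACT -> RANK_NORMALIZED (var./subsp./f.
    interchangeable) -> TYPO (bounded Levenshtein, default <=1 per token and
    <=2 overall). Distinct candidates at equal best distance give AMBIGUOUS.
    Author disagreement (disjoint tokenized authorities) demotes a TYPO match
    to UNMATCHED, but never an exact name match.
    """
    index = backbone if isinstance(backbone, BackboneIndex) else BackboneIndex(backbone)
    # cultivar epithets sit below the species-level backbone: match without them
    toks = canonical_tokens(strip_cultivar(raw_name))
    key = " ".join(toks)

    def result(taxon, cls):
        return MatchResult(raw_name, taxon, cls, _author_agreement(raw_authority, taxon))

    hits = index.exact.get(key, [])
    if len({t.accepted_name for t in hits}) == 1:
        return result(hits[0], MatchClass.EXACT)
    if len(hits) > 1:
        return MatchResult(raw_name, None, MatchClass.AMBIGUOUS, AuthorAgreement.NO_AUTHOR)

    rtoks = tuple(rank_normalized_tokens(toks))
    hits = index.ranknorm.get(" ".join(rtoks), [])
    names = {t.accepted_name for t in hits}
    if len(names) == 1:
        return result(hits[0], MatchClass.RANK_NORMALIZED)
    if len(names) > 1:
        return MatchResult(raw_name, None, MatchClass.AMBIGUOUS, AuthorAgreement.NO_AUTHOR)

    best: list[BackboneTaxon] = []
    best_d: Optional[int] = None
    for ctoks, taxon in index.candidates_by_length(len(rtoks)):
        d = token_sequence_distance(rtoks, ctoks, per_token_bound, total_bound)
        if d is None or d == 0:
            continue
        if best_d is None or d < best_d:
            best, best_d = [taxon], d
        elif d == best_d:
            best.append(taxon)
    unique_names = {t.accepted_name for t in best}
    if len(unique_names) == 1:
        res = result(best[0], MatchClass.TYPO)
        if res.author_agreement is AuthorAgreement.NONE:
            return MatchResult(raw_name, None, MatchClass.UNMATCHED, AuthorAgreement.NONE)
        return res
    if len(unique_names) > 1:
        return MatchResult(raw_name, None, MatchClass.AMBIGUOUS, AuthorAgreement.NO_AUTHOR)
    return MatchResult(raw_name, None, MatchClass.UNMATCHED, AuthorAgreement.NO_AUTHOR)


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def is_endemic(distribution: Iterable[str]) -> str:
    """Classify a TDWG level-3 distribution as endemic/widespread/unknown.

    Endemic means the taxon occurs in exactly one botanical country.
    """
    n = len(set(distribution))
    if n == 0:
        return "unknown"
    return "endemic" if n == 1 else "widespread"


def enrich_records(
    records: Sequence[PlantingRecord],
    backbone: Sequence[BackboneTaxon] | BackboneIndex,
    iucn_snapshot: Mapping[str, str] | None = None,
    tree_list: Iterable[str] | None = None,
    holdings: Mapping[str, int] | None = None,
) -> list[EnrichedRecord]:
    """Standardize and enrich records; unmatched records are kept with NE.

    ``iucn_snapshot`` maps accepted name -> current Red List category,
    ``tree_list`` is a set of accepted names that are trees, and ``holdings``
    maps accepted name -> number of institutions holding the taxon globally;
    each overlays the corresponding backbone attribute when present.
    """
    index = backbone if isinstance(backbone, BackboneIndex) else BackboneIndex(backbone)
    snapshot = dict(iucn_snapshot or {})
    trees = set(tree_list or ())
    held = dict(holdings or {})
    cache: dict[tuple[str, str], MatchResult] = {}
    out: list[EnrichedRecord] = []
    for rec in records:
        cache_key = (rec.raw_name, rec.raw_authority)
        match = cache.get(cache_key)
        if match is None:
            match = match_taxon_name(rec.raw_name, rec.raw_authority, index)
            cache[cache_key] = match
        taxon = match.matched_taxon
        if taxon is not None:
            if taxon.accepted_name in trees and not taxon.is_tree:
                taxon = replace(taxon, is_tree=True)
            if taxon.accepted_name in held:
                taxon = replace(taxon, n_global_collections=held[taxon.accepted_name])
            category = snapshot.get(taxon.accepted_name, "NE")
        else:
            category = "NE"
        if category not in IUCN_CATEGORIES:
            raise ValueError(f"unknown IUCN category {category!r}")
        parsed = parse_name(rec.raw_name)
        name_class = (NameClass.HORTICULTURAL if parsed.is_horticultural
                      else NameClass.BIOLOGICAL)
        out.append(EnrichedRecord(
            record=rec, backbone=taxon, match=match,
            iucn_current_category=category, name_class=name_class,
        ))
    return out
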