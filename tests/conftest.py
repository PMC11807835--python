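"""Shared fixtures: record factories, tiny backbones, synthetic datasets."""

from __future__ import annotations

from datetime import date

import pandas as pd
import pytest

from exsitu import (
    BackboneTaxon,
    EnrichedRecord,
    MaterialType,
    NameClass,
    PlantingRecord,
    Provenance,
    SyntheticConfig,
    enrich_records,
    generate_meta_collection,
)


@pytest.fixture
def make_record():
    """Factory for planting records with sensible defaults."""

    def _make(
        collection_id="C001",
        accession_id="A000001",
        planting_id=None,
        raw_name="Quercus robur",
        raw_authority="L.",
        provenance=Provenance.WILD,
        accession_date=date(1990, 7, 1),
        last_status_date=date(2010, 7, 1),
        status_alive=True,
        material_type=MaterialType.LIVING_PLANTING,
    ):
        if planting_id is None:
            _make.counter += 1
            planting_id = f"P{_make.counter:05d}"
        return PlantingRecord(
            collection_id=collection_id,
            accession_id=accession_id,
            planting_id=planting_id,
            raw_name=raw_name,
            raw_authority=raw_authority,
            provenance=provenance,
            accession_date=accession_date,
            last_status_date=last_status_date,
            status_alive=status_alive,
            material_type=material_type,
        )

    _make.counter = 0
    return _make


@pytest.fixture
def make_enriched(make_record):
    """Factory for enriched records bypassing the matching cascade."""

    def _make(backbone=None, iucn_current_category="NE",
              name_class=NameClass.BIOLOGICAL, **record_kwargs):
        rec = make_record(**record_kwargs)
        return EnrichedRecord(record=rec, backbone=backbone, match=None,
                              iucn_current_category=iucn_current_category,
                              name_class=name_class)

    return _make


@pytest.fixture
def small_backbone():
    return [
        BackboneTaxon("Quercus robur", authority="L.", family="Fagaceae",
                      distribution=frozenset({"GRB", "IRE", "FRA"}),
                      is_tree=True, n_global_collections=120),
        BackboneTaxon("Quercus petraea", authority="(Matt.) Liebl.",
                      family="Fagaceae",
                      distribution=frozenset({"GRB", "GER"}), is_tree=True),
        BackboneTaxon("Abies alba subsp. apennina", authority="Brullo",
                      family="Pinaceae", distribution=frozenset({"ITA"}),
                      is_tree=True),
        BackboneTaxon("Abies alba", authority="Mill.", family="Pinaceae",
                      distribution=frozenset({"GER", "SWI", "FRA"}),
                      is_tree=True),
        BackboneTaxon("Gentiana verna", authority="L.", family="Gentianaceae",
                      distribution=frozenset({"GRB"})),
        BackboneTaxon("Gentiana verda", authority="Griseb.",
                      family="Gentianaceae", distribution=frozenset({"NEP"})),
    ]


def interval_frame(rows):
    """Build a minimal interval frame from (start, end, event[, extras]) rows."""
    out = []
    for i, row in enumerate(rows):
        start, end, event = row[:3]
        extra = row[3] if len(row) > 3 else {}
        base = {
            "collection_id": extra.get("collection_id", "C001"),
            "accession_id": extra.get("accession_id", f"A{i:05d}"),
            "start_year": start, "end_year": end, "terminal_event": event,
            "provenance": extra.get("provenance", "WILD"),
            "species": extra.get("species", f"Sp {i}"),
            "genus": extra.get("genus", "Sp"),
            "family": extra.get("family", "Fam"),
            "is_tree": extra.get("is_tree", False),
            "endemism": extra.get("endemism", "widespread"),
            "iucn_current_category": extra.get("iucn_current_category", "LC"),
            "name_class": "BIOLOGICAL",
            "matched": extra.get("matched", True),
            "n_plantings": extra.get("n_plantings", 1),
        }
        out.append(base)
    return pd.DataFrame(out)


@pytest.fixture
def three_interval_fixture():
    return interval_frame([
        (1950, 1960, True),
        (1955, 2021, False),
        (1958, 1958, True),
    ])


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic meta-collection for structural checks."""
    cfg = SyntheticConfig(seed=7, carrying_capacity=2500, n_collections=8,
                          n_species=150, n_genera=50, n_families=18)
    return generate_meta_collection(cfg)


@pytest.fixture(scope="session")
def small_enriched(small_dataset):
    ds = small_dataset
    return enrich_records(ds.records, ds.backbone, ds.iucn_snapshot,
                          ds.tree_list, ds.holdings)


@pytest.fixture(scope="session")
def default_dataset():
    """The full study-condition dataset (~20,000 accessions)."""
    return generate_meta_collection(SyntheticConfig(seed=0))


@pytest.fixture(scope="session")
def default_enriched(default_dataset):
    ds = default_dataset
    return enrich_records(ds.records, ds.backbone, ds.iucn_snapshot,
                          ds.tree_list, ds.holdings)
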