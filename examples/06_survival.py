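"""Kaplan-Meier survival of accessions and species.

An accession's duration runs from accessioning to death (event) or to its
most recent status update (right-censored). The median survival probability
(MSP) is the first time the product-limit curve reaches 0.5; species-level
survival uses maximal windows during which at least one accession of the
species was alive.
"""

from datetime import date

from exsitu import (
    SyntheticConfig,
    accession_survival_inputs,
    enrich_records,
    generate_meta_collection,
    km_fit,
    km_median,
    stratified_km,
)
from exsitu.provenance import native_region, native_status_map

dataset = generate_meta_collection(SyntheticConfig(seed=1))
enriched = enrich_records(dataset.records, dataset.backbone,
                          dataset.iucn_snapshot, dataset.tree_list,
                          dataset.holdings)

inputs, _ = accession_survival_inputs(enriched)
curve = km_fit(inputs)
median, (lo, hi) = km_median(curve, with_ci=True)
print(f"all accessions: MSP = {median:.1f} y (95% CI {lo:.1f}-{hi:.1f}, "
      f"n = {curve.n_total}, censoring "
      f"{100 * (1 - inputs['event'].mean()):.0f}%)")

regions = {cid: native_region(country, collection_id=cid)
           for cid, country in dataset.collection_countries.items()}
status = native_status_map(enriched, regions)
for strat, kwargs in [("TREE", {}), ("ENDEMIC", {}),
                      ("THREATENED_ACCESSIONS", {}),
                      ("THREATENED_SPECIES",
                       {"snapshot_date": date(2021, 12, 31)}),
                      ("NATIVE", {"native_status": status}),
                      ("NAME_CLASS", {})]:
    fits = stratified_km(enriched, strat, **kwargs)
    parts = ", ".join(f"{name} {res.median:.1f} y (n={res.n})"
                      for name, res in sorted(fits.items())
                      if res.median is not None)
    print(f"{strat:22s}: {parts}")
# Trees were generated with a 20-year median lifespan vs 15 for the rest;
# the stratified fit recovers that gap from censored records alone.
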