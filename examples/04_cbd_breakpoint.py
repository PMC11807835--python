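"""Quantify the policy-breakpoint effect on wild and non-native acquisition.

The Convention on Biological Diversity entered into force at the end of
1993. The breakpoint statistic compares mean annual acquisition in the
decade after 1993 against the decade before it, as a percentage of the
pre-breakpoint mean; this dataset was generated with multipliers 0.56
(wild) and 0.62 (non-native), i.e. true effects of -44% and -38%.
"""

from exsitu import (
    SyntheticConfig,
    accession_intervals,
    enrich_records,
    generate_meta_collection,
    incoming_by_provenance,
    relative_change,
    turnover,
)
from exsitu.provenance import native_region, native_status_map

dataset = generate_meta_collection(SyntheticConfig(seed=1))
cfg = dataset.config
enriched = enrich_records(dataset.records, dataset.backbone,
                          dataset.iucn_snapshot, dataset.tree_list,
                          dataset.holdings)
intervals, _ = accession_intervals(enriched, snapshot_year=2021)

incoming = incoming_by_provenance(intervals)
for prov in ("WILD", "WILD_DERIVED", "GARDEN", "UNKNOWN"):
    change = relative_change(incoming[prov], cfg.breakpoint_year)
    print(f"{prov:13s}: {change:+6.1f}% change in annual acquisition "
          f"across {cfg.breakpoint_year}")

regions = {cid: native_region(country, collection_id=cid)
           for cid, country in dataset.collection_countries.items()}
status = native_status_map(enriched, regions)
intervals["native_status"] = [
    status.get((c, a), "unknown")
    for c, a in zip(intervals["collection_id"], intervals["accession_id"])]
non_native = intervals[intervals["native_status"] == "non_native"]
nn_gains, _, _ = turnover(non_native)
change = relative_change(nn_gains, cfg.breakpoint_year)
print(f"{'NON-NATIVE':13s}: {change:+6.1f}% change in annual acquisition")
# The wild decline matches the injected multiplier; the other provenance
# categories absorb the freed acquisition effort (the mixture renormalizes),
# mirroring the real-world offset of recycling garden and wild-derived stock.
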