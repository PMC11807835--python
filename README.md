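# exsitu

Century-scale analysis of **ex situ living plant collections** — the accession
records that botanic gardens keep for every batch of living plants they hold.
The package is written for collection curators and biodiversity scientists who
want to ask, from raw accession exports: how has a collection (or a pooled
*meta-collection* of many institutions) grown over a century, how much
taxonomic and phylogenetic diversity does it hold, how did international
biodiversity policy change what it acquires, how well does it track threatened
species, and how long do its plants actually persist?

## What it computes

Each accession record carries an accession date, a most-recent status update
and an alive/dead flag, so an accession defines a presence interval and,
equivalently, a right-censored survival time. On top of that representation
the package provides:

* **Reconstruction** — annual collection size `count(y)`, turnover
  (gains = new accessions, losses = accessions whose last individual died,
  net = gains − losses), rolling means, and a declared trajectory rule
  (increasing / plateauing / decreasing) based on the OLS slope of the final
  decade scaled by the series peak.
* **Diversity** — species/genus/family accumulation per year, and Faith's
  phylogenetic diversity through time: `PD(S) = Σ` branch lengths on the union
  of root-to-tip paths of the genera present (root-inclusive), computed on a
  phylogeny trimmed to one tip per genus.
* **Provenance & geography** — proportions of wild-origin, wild-derived,
  garden-origin and unknown-origin accessions through time; native vs
  non-native sourcing, where a taxon is *native* to a collection when its TDWG
  level-3 distribution overlaps the minimal set of botanical countries
  covering the collection's political country; and a policy-breakpoint
  statistic `100·(post-mean − pre-mean)/pre-mean` over the decades flanking
  1993 (the Convention on Biological Diversity).
* **Threat dynamics** — threatened vs non-threatened accumulation under
  retrospective Red List categories (threatened = VU/EN/CR/EW), first
  threat-designation years from assessment histories (the defunct E and R
  codes count as threatened), net-year alignment of accessions around
  designation, and a Welch two-sample *t*-test (Welch–Satterthwaite df,
  Cohen's *d* with equal-weight pooled SD) for responsiveness; plus
  individuals-per-species distributions and conservation-programme cohort
  comparison.
* **Survival** — the Kaplan–Meier product-limit estimator with Greenwood
  variance and Brookmeyer–Crowley median confidence intervals, written
  in-package; accession-level fits stratified by tree habit, endemism, threat
  status, nativeness and name class (biological vs horticultural), and
  species-level fits over *survival windows* (maximal intervals during which
  at least one accession of a species was alive; reintroductions start new
  windows).

A **synthetic-data module** generates record sets with the statistical
structure these analyses assume (sigmoidal arrival intensity, provenance
mixture with post-1993 multipliers, Weibull lifespans with median 15 y — 20 y
for trees — and lagged status updates), so the whole pipeline runs and is
testable with no downloads. See `docs/methods.md` for the model details and
what the generator does and does not emulate.

## Worked example

```bash
python examples/06_survival.py
```

prints (seed 1, the default synthetic conditions):

```
all accessions: MSP = 15.6 y (95% CI 15.4-15.9, n = 20159, censoring 31%)
TREE                  : non_tree 15.1 y (n=17410), tree 20.1 y (n=2748)
ENDEMIC               : endemic 15.9 y (n=2294), widespread 15.6 y (n=17864)
THREATENED_ACCESSIONS : non_threatened 15.6 y (n=12688), threatened 16.2 y (n=2296)
THREATENED_SPECIES    : non_threatened 21.0 y (n=6017), threatened 22.3 y (n=1018)
NATIVE                : native 15.6 y (n=9109), non_native 15.7 y (n=11049)
NAME_CLASS            : biological 15.6 y (n=17372), horticultural 16.1 y (n=2787)
```

MSP is the median survival probability: the first time the Kaplan–Meier curve
reaches 0.5. The generator drew non-tree lifespans with a 15-year median and
tree lifespans with a 20-year median; the stratified fits recover both from
censored records alone (15.1 and 20.1 y), and species-level windows are
longer than accession-level durations because overlapping accessions of a
species merge. Similarly,

```bash
python examples/04_cbd_breakpoint.py
```

prints `WILD : -45.9% change in annual acquisition across 1993` against an
injected true effect of −44%, with the other provenance categories rising as
they absorb the freed acquisition effort.

The other examples cover dataset generation (`01`), growth and turnover
(`02`), diversity accrual (`03`) and threat dynamics (`05`). A thin CLI wraps
the same pipeline: `exsitu simulate --seed 1 --out inputs/`,
`exsitu all --seed 1 --out results/` (subcommands `reconstruct`, `diversity`,
`provenance`, `threat`, `survival` run single stages; outputs are year-indexed
CSVs plus a `manifest.json` with content hashes, byte-identical on rerun).

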