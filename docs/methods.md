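# Methods

This note documents the models, conventions and design choices behind the
package, in the spirit of a statistical software methods appendix. Nothing
here states an empirical result that the tests or `scripts/acceptance.py` do
not themselves compute.

## Data model

A *planting* is one living individual; an *accession* is the batch of
plantings of one taxon that entered a collection together; a *meta-collection*
pools many institutions. Records carry an accession date, a most-recent status
date and an alive/dead flag at that date. Dates given at year resolution are
anchored to 1 July (year–month to the 15th): the midpoint choice keeps
duration arithmetic unbiased. Records whose status date precedes their
accession date, or whose dates fail to parse, are excluded and counted in the
parse report — never silently dropped. Only living plantings enter analysis;
seed, herbarium and propagation material is filtered at parse time.

## Name standardization

Raw taxon names are matched to a species-level backbone by a first-success
cascade: exact canonical equality (case, whitespace and hybrid-sign
normalization; quoted cultivar epithets are ignored for matching, since they
sit below the species level) → rank-normalized equality (the infraspecific
rank tokens `var.`, `subsp.`/`ssp.`, `f.`/`forma` are interchangeable) →
bounded-typo matching (Levenshtein distance ≤ 1 per word token and ≤ 2 per
name, both configurable). Distinct candidates at equal best distance yield an
ambiguous non-match. Authorities are tokenized on punctuation; disjoint
authority tokens demote a typo match to unmatched but never an exact name
match — a typo plus a contradicting author is more likely a different taxon,
while an exact name with a divergent author string is usually an abbreviation
mismatch. The distance bounds and the author rule are declared package
choices; no published rule exists for them. Unmatched records are retained
for capacity, turnover and accession-level survival analyses (which need no
taxonomy) and excluded from diversity, geography and threat analyses.

## Census convention and the accounting identity

Each accession defines a presence interval from its accession year to the
year of its last status update, with a terminal event when every planting is
dead. The census is inclusive at both ends: an accession whose last
individual died in year *d* counted as part of that year's collection. This
gives the shifted accounting identity

    count(y) − count(y−1) = gains(y) − losses(y−1).

Two census modes exist for accessions alive at their last update: the default
counts them through their last observed year only (consistent with
right-censoring in the survival module); the alternative
(`extend_alive_to_snapshot`) carries them to the snapshot year. The identity
above is an algebraic fact only when non-terminal intervals reach the window
end — under the default mode a censored accession that vanishes mid-window
drops the count without a recorded loss (losses count deaths only). Tests
therefore verify the identity under the extended census, and under the
default census for the years before the first censored end.

## Diversity

Faith's PD of a set of genera is the branch-length sum of the union of their
root-to-tip paths — the root-inclusive convention, which makes single-tip PD
nonzero and PD of the full tip set exactly the total branch length (both are
tested identities; the non-root convention is selectable). PD is computed at
genus level on a phylogeny trimmed to one tip per genus; the alphabetically
first species label per genus is retained — a deterministic stand-in for an
arbitrary published choice — and pruning collapses degree-2 nodes with branch
lengths summed, preserving all path lengths among retained tips (tested
against independent distance matrices, scikit-bio's PD implementation and R
picante). Genera absent from the tree are excluded from PD and reported in a
coverage table.

## Provenance, nativeness and the breakpoint statistic

Provenance is the four-way classification wild-origin / wild-derived /
garden-origin / unknown. Nativeness compares a taxon's TDWG level-3
("botanical country") distribution with the collection's *native region*: the
minimal set of level-3 units covering its political country, shipped as a
curated data table for the 19 study countries (e.g. Argentina → AGE + AGS +
AGW; United Kingdom → GRB + IRE). The table is data, not geometry: the
minimal cover is a fixed geographic fact. Taxa with empty distributions are
"unknown" and excluded from native/non-native denominators.

The breakpoint statistic `relative_change` is
`100 · (mean over (b, b+10] − mean over [b−10, b)) / mean over [b−10, b)`
with the breakpoint year *b* itself in neither window. The ten-year flanking
windows are a declared choice (no published definition exists); the statistic
is invariant to positive rescaling of the series and is reported on
acquisition *counts*.

## Threat dynamics

Threatened means VU, EN, CR or EW under the current Red List scheme; NE, DD,
LC, NT (and EX) are non-threatened. Historical designation analyses
additionally treat the defunct categories E (endangered/extinct) and R (rare)
as threatened and use assessment years, not publication years. Two procedures
are deliberately kept distinct: retrospective analyses map the *current*
category snapshot onto the whole reconstruction; timeline analyses locate
each taxon's first threatened assessment. The responsiveness test takes the
taxa first designated threatened in 2000–2009 that stay threatened, aligns
their accessions on the *net year* (calendar year minus designation year),
and compares the ten yearly sums before designation against the ten after
with a two-sided Welch *t*-test; net year 0 belongs to neither group (this
grouping reproduces the published df of 17.65 from the published group
summaries, confirming the reading). Cohen's *d* uses the equal-weight pooled
SD `sqrt((s1² + s2²)/2)` for equal group sizes. Quantiles everywhere use
linear interpolation between order statistics. The local-regression smoother
is tricube-weighted local linear regression over the nearest `ceil(span·n)`
points, evaluated at every year; it reproduces straight lines exactly and is
cross-checked against statsmodels lowess.

## Survival

Durations are `(last status date − accession date)` in years (days/365.25);
the event is death (all plantings of the accession dead). The Kaplan–Meier
product-limit estimator is implemented directly: at tied times deaths precede
censorings (censored subjects remain at risk for events at their own time);
variance is Greenwood's formula; the median is the first event time with
S(t) ≤ 0.5, reported as "not reached" when S stays above 0.5; its 95%
confidence interval is Brookmeyer–Crowley — the crossing times of 0.5 by the
pointwise log(−log) band. The implementation is verified against lifelines to
1e−12 on randomized censored datasets.

Species-level survival uses windows: per (collection, species), accession
presence intervals are unioned; overlapping or touching intervals merge, any
positive gap splits (a reintroduction), and each maximal window is one
survival time, censored only if some accession in it was alive at its last
update. Windows use full dates, not integer years. The threatened-accession
and threatened-species stratifications restrict to accessions from 1980
onwards by default (the restriction year is a parameter; 1978 — the start of
digital Red Listing — is the natural alternative).

## Synthetic generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

* **Arrivals**: inhomogeneous Poisson, intensity the year-difference of a
  logistic `K·σ(r·(t − t₀))` with K = 21,800 (≈ 20,000 expected accessions
  over 1921–2021), r = 0.09 /y, t₀ = 1993. The midpoint sits at the policy
  breakpoint because the emulated system's most rapid expansion ran to the
  early 1990s and moderated after — and a derivative symmetric about the
  breakpoint is what makes the flanking-decade comparison estimate the
  injected multiplier without trend bias. Cumulative arrivals are capped at K.
* **Provenance**: pre-breakpoint mixture wild 0.35, wild-derived 0.10, garden
  0.15, unknown 0.40. After the breakpoint the wild probability is multiplied
  by 0.56 and the remaining categories rescale to keep the mixture summing to
  one — so wild acquisition falls by 44% while the other categories absorb
  the freed effort, mirroring the recycling offset seen in real collections.
  Non-native sourcing (pre-breakpoint probability 0.65) is likewise
  multiplied by 0.62 after the breakpoint (a 38% fall).
* **Lifespans**: Weibull, shape 1.2, medians 15 y (non-trees) and 20 y
  (trees); the shape produces ≳30% right-censoring at the snapshot under the
  default arrival history. Exponential lifespans are selectable.
* **Censoring**: each accession has a "last inventory" date lagging 0–3 years
  (uniform) behind the 2021 snapshot; plantings alive then are censored at
  that date — emulating the lag in death recording noted for real systems.
* **Structure**: 600 species in 150 genera and 40 families on a pure-birth
  ultrametric genus tree (terminal edges extended by 1% of tree depth so all
  branch lengths are strictly positive); 15% of taxa endemic (single
  botanical country); 15% trees; 20 collections assigned round-robin to the
  19 study countries with lognormal size weights; the first collection is a
  conservation-programme cohort with boosted wild share (0.75) and five-fold
  oversampling of threatened taxa. Assessment histories arise from an annual
  designation hazard of 0.004 over 1980–2019 with occasional defunct E/R
  first categories and 10% down-listing at reassessment. Record noise: 2%
  single-character typos, 12% cultivar epithets, 3% hybrid signs, 20% blank
  authorities, extra plantings per accession ~ Poisson(0.4).

What the generator does **not** emulate: the secular improvement in
provenance recording (the real unknown-origin share fell over the century;
here the mixture is time-constant apart from the breakpoint), spatial
coordinates, collection-specific histories, taxonomy revisions, and
assessment-rate acceleration. Passing recovery tests therefore demonstrates
that the analysis chain measures what it claims under the assumed structure —
not that real collections satisfy that structure.

## Problem sizes

Tests run the full chain on a ~20,000-accession dataset (the study scale for
the recovery checks) and on ~1,500–2,500-accession datasets for structural
checks; the acceptance script uses the default ~20,000-accession
configuration. All randomness flows from a single seed; identical seeds give
byte-identical outputs end to end.

## Known limitations

* The matching cascade resolves spelling variation only — no synonym-graph
  resolution; a correctly spelled synonym is an unmatched record.
* The accounting identity holds exactly only under the extended census (see
  above); published turnover practice is ambiguous on this point.
* Median survival estimates inherit the upper-bound bias of lagged death
  recording; the generator reproduces the mechanism but not its real-world
  magnitude.
* The country → TDWG level-3 table covers the 19 study countries; other
  countries raise a configuration error rather than guessing a cover.
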