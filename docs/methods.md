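# Methods

## The gene families and the admission filter

The package models 13 SBA production gene families: BSH (deconjugation),
BaiA/B/CD/E/F/G/H (the 7α-dehydroxylation operon) and the 3α/3β/7α/7β/12α
hydroxysteroid dehydrogenases (oxidation/epimerization). A profile-HMM
search hit enters the catalog iff

* full-sequence E-value `< 1e-65` (strict), and
* full-sequence bit score `>=` the family's cutoff (non-strict).

The published cutoffs sit at empirical score drops, and membership is
*defined* by them; we therefore retain a hit exactly at the cutoff. The
E-value bound is strict per its "less than" phrasing. The cutoffs are
applied to the full-sequence score; hmmsearch also reports best-domain
scores, and the choice of the full-sequence score is a documented
assumption of this implementation. Iterative HMM training (align, rebuild,
repeat) is upstream of everything computed here and is out of scope; the
pipeline starts from hit tables.

Seed supplementation: sparsely detected families (the Bai operon, 7βHSDH)
may be supplemented from curated seed records. When a seed duplicates a
retained hit on (genome, family, protein accession) the hit wins, so
score/E-value provenance survives. Copy indices are assigned 1-based by
sorted protein accession within each (genome, family) pair — an arbitrary
but deterministic order.

## Counting conventions

* Composition percentages are `100·count/family_total` rounded **half-up
  to one decimal**, centralized in `families.round_half_up`. This is the
  convention consistent with printed values such as 1374/1668 → 82.4.
* Habitat proportions are reported to five decimals (their magnitudes are
  of order 1e-2 percent).
* Average copy number of a (species, family) pair averages over **carrier
  genomes only**; pairs with no carrier are absent from the output rather
  than 0 or NaN, so downstream weighting never silently multiplies by
  zero.
* A "multi-functional" genome carries BSH plus at least one Bai or HSDH
  family. The "full Bai set" defaults to all seven modeled Bai families
  and is caller-overridable, since the operon can be delimited more
  loosely.

## Homology filter and best-hit rule

Habitat mapping and the Same/Similar/Unique classifier share one quality
filter: identity ≥ 70% (non-strict) and E-value < 1e-50 (strict), the
literal reading of "at least 70%" / "less than 1e-50". A query with
several passing hits is resolved by lowest E-value, then highest bit
score, then lexicographic subject id. The tie-break is this package's own
convention (any deterministic rule would do; results only depend on it
when two hits are exactly tied on both statistics).

## Disease comparison

Species relative abundances are weighted by the species' average
per-carrier-genome copy number (Eqs. 1–2) to undo the inflation multi-copy
genomes cause in gene-derived abundances. BSH is compared as raw RPKM;
the six other gene types (Bai subfamilies pooled, matching the single Bai
weight downstream) are compared as per-sample proportions of their pooled
RPKM. Samples whose pooled non-BSH RPKM is zero get NaN proportions and
are flagged and excluded from proportion comparisons, never imputed as 0.

Tests: two-tailed Mann–Whitney U for unpaired designs, paired *t* for
paired ones.

* The MWU p-value is computed by exhaustive enumeration of all
  `C(n1+n2, n1)` rank splits when both groups have ≤ 8 observations
  (midranks make this exact under ties; two-sided p is the doubled
  smaller tail, clipped to 1). Above that, the tie-corrected normal
  approximation with continuity correction is used. A constant pooled
  sample yields p = 1.
* The paired *t* handles degenerate differences: all-zero differences give
  p = 1; constant nonzero differences give p = 0 (the vanishing-spread
  limit).

`rate of change = 100·|mean(disease) − mean(control)|/mean(control)`,
computed on group means of the compared metric. The defining study never
specifies this quantity precisely; means (not medians) are an explicit
choice here. A zero control mean with nonzero disease mean flags the rate
infinite and the SL then depends on the p-value alone.

Significance levels: p < 1e-4 → 4; p < 1e-3 → 3; p < 0.01 → 2;
p < 0.05 → 1; p ≥ 0.05 with a finite rate > 10% → 0.5; the residual case
(p ≥ 0.05, rate ≤ 10%) maps to 0 — the published mapping omits it and 0 is
the only value consistent with SL measuring the strength of a difference.

Difference score: `0.5·SL_BSH + 0.5·Σ_j SL_j·Proportion_j` over the six
non-BSH types. `Proportion_j` is the mean proportion of type j across
**all usable samples pooled** by default; which group's proportions should
weight the sum is genuinely ambiguous, so `profile_study` exposes
`proportion_weighting = pooled | control | disease`. The score is bounded
by 4 and is monotone in every SL and in every proportion paired with a
positive SL.

Major differential species: among carrier species with p < 0.05 whose
direction of change matches the gene type's, the one with the highest mean
weighted abundance; ties break lexicographically; an empty candidate set
returns an explicit null. When a species carries several subfamilies of a
pooled type it is compared once, weighted by its highest per-subfamily
average copy number.

## Animal-model similarity

Human genes are classified per family: *Same* when the identical gene
identifier occurs in the animal list (identifier spaces are global, so no
sequence evidence is consulted); otherwise *Similar* when any homology
record passes the shared filter (any-hit semantics, no reciprocity
required); otherwise *Unique*. Ratios divide by the **human** gene count,
so animal-only genes never enter the score. Gene score
`= r_same + 0.7·r_similar − r_unique ∈ [−1, 1]`; overall score is the
weighted sum with W = (0.5, 0.125, 4×0.0625, 0.125), which sums to 1
exactly and is asserted, not floating-accumulated.

## The synthetic-data generators

The generators emulate the *shape* of the real inputs, not their content:

* **Genomes/hits.** 11 species across five phyla and two kingdoms
  (defaults), 4 genomes each. Carriage is host-restricted per family
  (BSH in Firmicutes/Actinobacteria/gut archaea, Bai in two
  Lachnospiraceae, 3βHSDH in Bacteroidetes, 7αHSDH led by Proteobacteria,
  7βHSDH in *Ruminococcus*/*Collinsella*), mirroring the taxon structure
  of the real catalog; copies per carrier are drawn on {1..4} — 4 is the
  maximum copy number the catalog reports. Planted hits draw scores
  2–60% above the family cutoff and E-values in [1e-120, 1e-66]; every
  decoy violates at least one criterion (score below cutoff, E-value
  ≥ 1e-65, or both), so the admission filter must recover the planted
  truth exactly and any retained decoy is an implementation error.
* **Cohorts.** Species abundances are log-normal: per-species location
  (log-sd 1.0) plus per-sample deviation (log-sd 0.5), renormalized per
  sample to sum to 1. Disease samples multiply the species named in
  `fold_changes` before renormalization. Gene-type RPKM is
  Σ carriers (abundance × average copy number) × gain under multiplicative
  log-normal noise (log-sd 0.5, a standard magnitude for sequencing-depth
  variation). 50 samples per group by default, matching the planted-
  depletion condition under which the pipeline is validated; paired mode
  shares a per-pair base community between the two partners. A "strong
  depletion" of a gene type (`depletion_folds`) applies the fold change to
  every carrier species of the type — depleting only a subset would be
  partially cancelled by renormalization and carrier redundancy.
* **Correspondence.** Per-family category counts are apportioned from the
  target fractions by largest remainder; with the default 40 human genes
  per family all default fractions are exact multiples of 1/40, so
  recovery is exact. "Similar" genes get one passing record; "Unique"
  genes alternate between no record and a failing one, exercising both
  failure modes of the filter.
* **Habitats.** Per-habitat totals (40k–120k genes) and SBA rates
  (1e-6–1.5e-4, gut- and wastewater-enriched) give planted counts of the
  magnitude seen in global gene catalogs; half as many decoy genes carry
  only filter-failing records.

All generators are pure functions of `SimConfig`; a fixed seed gives
byte-identical output files, and independent streams (`default_rng([seed,
k])`) decouple the four generators. What the simulations do **not**
emulate: sequence content, compositional correlation between taxa,
zero-inflation of real metagenomic profiles, batch effects, and any real
cohort's effect sizes — passing recovery tests therefore demonstrates the
correctness of the arithmetic and the filters, not performance on real
data.

## Calibration of the difference score under the null

Under a null cohort (no planted effects) the seven group tests have
~uniform p-values, so some seed fraction always shows p < 0.05 somewhere,
and the 0.5-SL rule (rate > 10% at p ≥ 0.05) fires frequently at n = 50
with the default noise; exactly-zero scores are accordingly rare (a few
percent of seeds) and the achievable guarantee is separation, not
exactness: over seeds, every null score stays strictly below every
strong-depletion score (observed null max ≈ 1.1 vs planted min ≈ 3.2).
The test suite asserts that separation; the per-comparison false-positive
rate itself is controlled by the underlying tests, which are validated
against exact enumeration.

## Problem sizes

Defaults throughout (44 genomes, ≤ 10,000-record homology fixtures,
50 + 50 samples, 100-seed null sweeps) keep every stage's validation in
seconds while leaving all thresholds and formulas identical to what a
full-scale run would use; only input sizes shrink.

## Known limitations

* The catalog stage consumes hit tables; it does not run or train HMMs.
* No multiple-testing correction is applied across the seven gene-type
  comparisons or the per-species tests — the difference score is a
  descriptive aggregate, not an inferential statistic.
* `rate of change`, the Eq. 3 proportion weighting, and the homology
  tie-break are package conventions where the defining study is silent
  (each flagged above).
* Habitat assignment counts each inventory gene once via its best hit; a
  gene with equally good hits to two families is resolved by the
  deterministic tie-break, not double-counted.
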