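# sbagenes

Tools for building and exploiting catalogs of microbial **secondary bile
acid (SBA) production genes** — the bile salt hydrolases (BSH) that
deconjugate host bile acids, the bile acid-inducible (BaiA–BaiH) operon
that 7α-dehydroxylates them into DCA/LCA, and the position-specific
hydroxysteroid dehydrogenases (3α/3β/7α/7β/12α-HSDH) that oxidize and
epimerize them.

The package covers four stages of a desk-scale analysis chain:

1. **Catalog construction** (`sbagenes.catalog`). Profile-HMM search hits
   (HMMER3 `--tblout`) are admitted when the full-sequence E-value is below
   1e-65 and the full-sequence bit score reaches a per-family cutoff
   (BSH 400; BaiA 390; BaiB 1000; BaiCD 1090; BaiE 360; BaiF 1000; BaiG
   950; BaiH 1400; 3αHSDH 300; 3βHSDH 340; 7αHSDH 325; 7βHSDH 580;
   12αHSDH 250). Curated seed proteins can supplement sparse families;
   records carry lineage and 1-based copy indices per (genome, family).
2. **Taxonomy and habitat profiling** (`sbagenes.taxonomy`,
   `sbagenes.habitat`). Composition percentages by phylum/genus/species,
   carrier-genome prevalence, multi-copy and multi-functional genome
   summaries; and mapping of a habitat-tagged gene inventory onto the
   non-redundant protein catalog (hits pass with identity ≥ 70% and
   E-value < 1e-50; the best passing hit assigns the family).
3. **Disease comparison** (`sbagenes.disease`). Species abundances are
   weighted by the average per-carrier-genome copy number,
   `w = c̄ · a` (Eqs. 1–2); BSH RPKM and the non-BSH gene-type proportions
   are compared between cases and controls (two-tailed Mann–Whitney U, or
   paired *t* for paired designs), p-values and rates of change map to
   ordinal significance levels SL ∈ {0, 0.5, 1, 2, 3, 4}, and a cohort
   **difference score** aggregates them:
   `score = 0.5·SL_BSH + 0.5·Σ_j SL_j·Proportion_j` (Eq. 3).
4. **Animal-model similarity** (`sbagenes.similarity`). Human genes are
   classified per family as *Same* (shared identifier), *Similar*
   (identity ≥ 70%, E-value < 1e-50) or *Unique*; per-family
   `gene score = r_same + 0.7·r_similar − r_unique` (Eq. 4) and
   `overall = Σ_j W_j·gene score_j` (Eq. 5) with pathway weights
   W = (BSH 0.5, Bai 0.125, 3α/3β/7α/7β-HSDH 0.0625 each, 12αHSDH 0.125).

`sbagenes.simulate` generates every input from a seed — planted genomes
with 0–4 gene copies, hit tables whose decoys straddle the cutoffs,
case/control cohorts with planted carrier-species fold changes, and
human/animal correspondence tables with configurable category fractions —
together with truth tables that let every stage be scored exactly.

## Worked example

```python
from sbagenes import *
from sbagenes.simulate import (SimConfig, simulate_genome_hits,
                               simulate_abundance_study, depletion_folds)

config = SimConfig(rng_seed=42)
genomes = simulate_genome_hits(config)
catalog = assemble_catalog(filter_hits(genomes.hits), genomes.lineage)
print(f"catalog: {len(catalog)} genes across "
      f"{catalog.to_frame()['genome_id'].nunique()} genomes")
print(compose_by_rank(catalog, "BSH", "phylum").to_string(index=False))

study = simulate_abundance_study(
    SimConfig(rng_seed=42, fold_changes=depletion_folds(genomes, "BSH", 0.1)),
    genomes)
profile = profile_study(study, catalog)
for c in profile.comparisons:
    print(f"{c.gene_type:8s} p={c.p_value:.2e} rate={c.rate_of_change:6.1f}% SL={c.sl}")
print(f"difference score: {profile.score:.3f}")
```

prints

```
catalog: 132 genes across 40 genomes
family_id   rank          taxon  count  percent
      BSH phylum     Firmicutes     22     64.7
      BSH phylum Actinobacteria      6     17.6
      BSH phylum  Euryarchaeota      6     17.6
BSH      p=1.50e-13 rate=  64.7% SL=4.0
Bai      p=2.44e-11 rate=  71.2% SL=4.0
3aHSDH   p=3.76e-01 rate=  10.6% SL=0.5
3bHSDH   p=4.76e-16 rate= 210.1% SL=4.0
7aHSDH   p=3.96e-12 rate= 144.0% SL=4.0
7bHSDH   p=2.44e-11 rate=  64.3% SL=4.0
12aHSDH  p=7.48e-05 rate=  31.4% SL=4.0
difference score: 3.773
```

The simulated catalog holds 132 genes; BSH genes concentrate in
Firmicutes (64.7%). The cohort was generated with a 10-fold depletion of
every BSH-carrier species in the disease group, so the BSH abundance test
reaches the maximum significance level (SL = 4; the depletion drags the
co-carried families with it) and the difference score approaches its
ceiling of 4.

The same stages are available from a shell via the `sbagenes` CLI
(`simulate`, `build-catalog`, `summarize`, `map-habitat`, `disease-score`,
`model-sim`); see `sbagenes --help`.

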