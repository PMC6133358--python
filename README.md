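# galaxybin

Coverage+GC "galaxy" binning of metagenome assemblies and strain-level
subsystem variation scoring, with a synthetic-community simulator so the
whole pipeline is testable without sequence downloads.

## Who this is for

Microbial ecologists working with multi-sample shotgun metagenomes of
complex communities (the motivating system is a hypersaline phototrophic
microbial mat) who want to

1. recover metagenome-assembled genomes (MAGs) from assembled scaffolds
   using per-sample read coverage and %GC as features, and
2. quantify strain-level micro-heterogeneity of a dominant organism by
   scoring the accumulation of reference-mapped SNPs in gene subsystems.

## The methods

**Binning.** Each scaffold gets the feature vector
`[log10(cov_1 + 1), ..., log10(cov_S + 1), GC]` (one coverage per sample;
GC over unambiguous bases). Columns are standardised, the GC column
optionally re-weighted, and the scaffolds projected onto the top three
principal components — the "galaxy", where genomes appear as dense clouds.
Scaffolds > 5 kbp are clustered with DBSCAN; the clusters train an
RBF-kernel SVM that propagates bin labels to all scaffolds > 1.5 kbp, gated
on calibrated confidence. Long scaffolds DBSCAN calls noise go to a
`background` recruitment bin; low-confidence propagations stay `unbinned`.
DBSCAN/feature parameters are tuned by maximising mean bin completeness
minus mean duplication against a universe of ~100 single-copy essential
marker genes. Bins from repeated assemblies (different word sizes) are
reconciled by marker-content Jaccard similarity, keeping the best
(completeness − duplication) representative per group.

**Subsystem variation score.** SNPs called against a reference genome are
filtered to an inclusive depth window (default 50–200x) that isolates a
rarer strain stratum (~150x) from the dominant strain's coverage (~600x),
then aggregated per gene as a density (percent: variants per 100 bp) and
binned into rate classes [0,1), [1,2), [2,3), [3,∞) percent. Each gene set
(SEED-style subsystem) *g* is scored as

    score_g = 10^3 · Σ_{n=1..4} C_n · ( V_{g,n}/V_{G,n} − V_{g,all}/V_{G,all} )

with unit weights C_n, where V_{g,n} counts the genes of *g* in rate class
*n* and V_{G,n} the genome-wide counterpart. Positive scores mark
subsystems accumulating more variation than the genome-wide average
(candidate niche-differentiating functions), negative scores mark conserved
core subsystems. Zero-variant genes count toward V_{g,all} but not toward
any class (switchable).

## Worked example

```python
from galaxybin import (CommunitySpec, GalaxyBinningModel,
                       simulate_community, evaluate_binning)

spec = CommunitySpec(seed=1)              # 8 genomes, 4 samples
scaffolds, coverage, marker_hits, truth = simulate_community(spec)
model = GalaxyBinningModel(scaffolds, marker_hits=marker_hits)
result = model.fit(eps=0.4, min_samples=5)
print(result.summary())
```

```
Galaxy binning results
======================================================
scaffolds considered (> 1500 bp): 146
training scaffolds (> 5000 bp):  122
clusters (bins): 8   noise -> background: 0
binned: 146   background: 0   unbinned: 0
...
  bin  l50_kbp  total_mbp  mean_cov  ess  dup  tot  completeness  duplication     majority_phylum ...
bin:1     11.7        0.2     126.4  100    0  100          1.00          0.0       Cyanobacteria
bin:6     13.6        0.2      70.6   99    0  100          0.99          0.0 Gammaproteobacteria
...
```

All eight planted genomes come back as bins ordered by mean coverage, each
nearly complete (`ess`/`tot`) with no duplicated markers, and
`evaluate_binning(result.assignment, truth, scaffolds)` reports an adjusted
Rand index of 1.0 on the training scaffolds.

Strain variation, with three subsystems enriched fourfold among thirty:

```python
from galaxybin import (StrainVariantSpec, SubsystemVariationModel,
                       simulate_strain_variants)

spec = StrainVariantSpec(seed=0,
                         enriched_subsystems=frozenset({"SS_05", "SS_12", "SS_21"}))
sites, genes, subsystem_map, truth = simulate_strain_variants(spec)
res = SubsystemVariationModel(sites, genes, subsystem_map).fit()
print(res.summary())
```

```
Subsystem variation results
======================================================
SNP sites: 4566 total, 3663 in [50,200]x window (903 outside)
genes: 600   subsystems scored: 30
score mean 13.2   median -13.7   SD 80.4

most variable subsystems:
subsystem_id  v_g_all  class_1  class_2  class_3  class_4      score
       SS_12       12        0        9        2        1 266.279537
       SS_05       12        1        8        1        2 245.809192
       SS_21       12        2        8        0        2 189.014060
...
```

The three planted enriched subsystems rank on top; the class columns show
their genes shifted into the higher variant-density classes.

## Command line

```bash
galaxybin simulate community --seed 1 --out-dir sim/
galaxybin bin --scaffolds sim/scaffolds.fasta --coverage sim/coverage.tsv \
              --markers sim/markers.tsv --eps 0.4 --out-dir run/
galaxybin qc --assignment run/assignments.tsv --markers sim/markers.tsv \
             --scaffolds sim/scaffolds.fasta --coverage sim/coverage.tsv --out qc.tsv
galaxybin score-variants --vcf v.vcf --gff genes.gff3 --subsystems ss.tsv --out-dir scored/
galaxybin run --config run.yaml --seed 1 --out-dir out/   # full pipeline + manifest
```

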