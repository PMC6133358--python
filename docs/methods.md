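# Methods

## Scaffold binning

### Feature space

A scaffold's features are one log-coverage per sample plus its G+C
fraction: `log10(coverage + pseudocount)` with pseudocount 1 (handles
zero coverage; log base 10 keeps values readable as "dex"). GC is computed
over unambiguous A/C/G/T only; N and IUPAC ambiguity codes are excluded
from the denominator, so gap-padded scaffolds are not biased toward 0.

Each column is standardised to zero mean and unit spread over the included
scaffolds. The original procedure scaled features manually; a per-column
standardisation with an explicit GC weight (`gc_weight`, default 1) is the
reproducible equivalent — the weight is the single remaining manual degree
of freedom and is part of the tuning grid. A zero-variance column keeps
spread 1 (with a warning) instead of dividing by zero.

### Projection, clustering, propagation

The top three principal components are fitted on the training scaffolds
(> `min_train_len` = 5000 bp) and applied to every scaffold above the
classification gate (`min_class_len` = 1500 bp), so trained and propagated
scaffolds share one coordinate system. Component signs are fixed (largest
absolute loading positive) to make projections deterministic.

DBSCAN clusters the projected training scaffolds; clusters are renumbered
1..K by descending size for stable reporting. The DBSCAN radius `eps` and
`min_samples` have no universal default — they are exposed and tuned (see
below); the library defaults (0.5 / 5) suit standardised features.

Label propagation uses an RBF-kernel SVM (C = 1, gamma = "scale") trained
on the non-noise clusters in PC space. Confidence is a Platt-calibrated
class probability; when the smallest cluster has fewer than the five
members the calibration's internal cross-validation needs, a softmax over
the decision margins is used instead. Scaffolds whose best-class
confidence falls below `conf_threshold` (default 0.5) stay `unbinned`.
Training scaffolds keep their cluster label (provenance `trained`); noise
training scaffolds — large but un-clustered — go to the `background`
recruitment bin. With a single cluster, propagation is gated on an RBF
similarity to the cluster centre rather than a degenerate classifier.

### Tuning and the marker objective

`tune_clustering` grid-searches (eps, min_samples, gc_weight), running the
full cluster → propagate → QC chain per point and maximising

    mean bin completeness − λ · mean bin duplication      (λ = 1)

over bins containing at least one marker. Ties break toward fewer noise
scaffolds, then smaller eps (tighter clusters preferred at equal quality).
Completeness is the fraction of a single-copy marker universe found at
least once in the bin, duplication the fraction found at least twice;
"present at least twice" (rather than counting excess copies) is the
definition used throughout, documented here because marker-count reports
of the form found/duplicated/total are ambiguous on this point.

### Bin statistics and reconciliation

Mean bin coverage is the length-weighted mean over scaffolds of each
scaffold's mean per-sample coverage — robust to scaffold-size skew. L50 is
the scaffold length at which the cumulative length from the largest
scaffold down first reaches half the bin total. Top bins are those above a
completeness threshold (default 0.8), ordered by mean coverage.

When the same read set is assembled several times (different word sizes),
corresponding bins are found by Jaccard similarity over the sets of
distinct marker genes present (threshold 0.5), with grouping blocked when
both bins have determined but different majority phyla. Because complete
bins of *any* taxon share most of a universal single-copy marker set, the
phylum refinement carries real discriminative weight; the Jaccard
threshold mainly separates partial bins. Within each connected group the
bin maximising completeness − duplication is kept (ties to higher mean
coverage). No matching rule is canonical here; this one is transparent and
needs no sequence alignment.

## Strain-variation scoring

### Coverage window

Only SNP sites are scored (REF and every ALT a single differing base);
indels, MNPs and complex alleles are dropped at read time. Site depth
comes from INFO/DP when present, else the sum of per-sample depths; the
depth is taken from the VCF rather than an external pileup. The analysis
window [low, high] = [50, 200] (inclusive both ends) isolates the minor
strain stratum (~150x) from the dominant distribution (~600x). Sites in
no gene are ignored for per-gene summaries but kept in the depth
histogram report.

### Densities, classes, score

Per-gene variant density is 100 · (filtered sites in [start, end]) / gene
length, in percent. Gene length (not aligned covered length) is the
denominator. A site inside two overlapping genes counts once in each;
a gene in several subsystems contributes to each subsystem's counts but is
counted once genome-wide.

Rate classes are left-closed right-open on density percent with edges
(0, 1, 2, 3) and an open last class. Zero-variant genes are excluded from
the classes but counted in V_g,all and V_G,all — the choice that makes a
subsystem's class counts sum to less than its gene total, as observed in
real strain-variation tables; `include_zero_variant_genes_in_classes`
flips this. V_G,all counts all reference genes (not only those in a
subsystem); V_G,n counts genes with variants. Classes empty genome-wide
contribute zero to any score (logged), avoiding 0/0.

The score is `scale · Σ_n C_n (V_g,n/V_G,n − V_g,all/V_G,all)` with unit
weights and scale 1000 for readability. Two exact calibration properties
are tested: every score is zero when class proportions match the
genome-wide proportions, and scores sum to exactly zero when the gene sets
partition the gene universe. The summary reports the unweighted mean,
median and population SD across subsystems (population vs sample SD is
immaterial at 30+ subsystems and population is the simpler convention).

A caution for interpretation: when an upper rate class holds few genes
genome-wide, 1/V_G,n is large and a subsystem catching one such gene jumps
in score. This is inherent to the statistic, not an artefact; scores from
sparse classes should be read together with the class counts that the
per-subsystem table always carries.

## Synthetic data

`simulate_community` emulates exactly the statistical structure the
binning features use: per-genome G+C bias (i.i.d. nucleotides — no k-mer
structure, since composition beyond GC is never consumed), distinct
per-sample abundance profiles, scaffold coverage = abundance ×
depth_factor × mean-one lognormal noise (sigma 0.15; the mean-one
parameterisation makes expected coverage exactly abundance ×
depth_factor), and one copy of each of 100 single-copy markers planted per
genome on length-weighted scaffolds. Defaults are an 8-genome, 4-sample
community, genome size 200 kbp (scaled down from Mbp-size genomes to keep
simulations fast; fragment statistics — mean 10 kbp, sd 6 kbp, min 1 kbp —
give realistic training/classification gate occupancy), GC spread
0.30–0.65 assigned in an order decoupled from abundance rank, and base
abundances log-spaced so mean coverages span roughly 6–120x, the range
typical of the motivating mat metagenomes. Re-fragmenting the same
genomes with a different `fragment_seed` emulates repeated assemblies at
different word sizes.

What it does *not* emulate: chimeric scaffolds, shared/mobile sequence
between genomes, within-genome GC heterogeneity, coverage biases
correlated along the genome. Passing bin-recovery tests therefore shows
the clustering/propagation machinery is correct under the model's own
assumptions, not that any real community with overlapping signatures would
bin this cleanly.

`simulate_strain_variants` lays ~600 genes (length ~N(900, 250), min 300,
150 bp gaps) on one reference contig. Most genes carry SNPs at a base
density of 0.5% of gene length; a 10% subpopulation of "variable" genes
draws its density uniformly from 1–4% — the overdispersion real strain
mixtures show, which also populates every rate class genome-wide and keeps
the score's denominators meaningful. Genes of designated enriched
subsystems have their rate multiplied (default 4x). Site depths are
Poisson around the minor (150x, fraction 0.8 of sites) or major (600x)
stratum, so the two strata stay separable and the default window keeps
essentially all minor-stratum sites. Per-site depths are independent,
unlike real data where depth is locally correlated; tests of the window
filter are therefore exact at the stratum centres but say nothing about
boundary behaviour on real pileups.

All randomness flows from a single seed per spec; generated files carry a
`#seed=` header line.

## Indicator matrices

Indicator genes are detected by case-insensitive substring search of
catalog terms against ORF product strings — annotation-system-agnostic,
matching how mixed EC/KEGG/SEED annotation exports are in practice
queried. The shipped catalogs cover the standard biogeochemical-cycling
indicators (DSR, APR, SOX, NIF, NAR, NOS, PSA/PSB, PUF, RBC, CCM, ... )
and a carbohydrate production/breakdown set (BCS, PGM, CEL, BGL, GH,
GLG*, TRE*, ...); both are plain data and user-overridable via TSV.
Substring matching inherits the annotations' vocabulary: a product string
using a synonym outside the term list is missed, so catalogs should be
reviewed against the annotation source in use.

## Numerical and degenerate-input choices

- Coordinates are 1-based inclusive end-to-end (GFF3 and VCF agree), so no
  conversions occur internally.
- Multi-allelic SNP sites count as one site.
- Taxonomy ties break lexicographically with a logged warning; absent
  labels yield "undetermined".
- DBSCAN and PCA are deterministic; the SVM's seed is threaded through and
  recorded, making whole-pipeline runs byte-reproducible (verified via
  manifest checksums).
- Empty bins are flagged with completeness 0 rather than erroring;
  subsystems with no known genes are excluded with a warning.

## Problem sizes used in the test and acceptance runs

Bin-recovery and reconciliation checks run on the default 8-genome,
200 kbp-genome community (~160 scaffolds) with a 6-point tuning grid
(eps ∈ {0.3, 0.4, 0.6} × gc_weight ∈ {1, 2}, min_samples 5); enrichment
detection uses 20 seeded strain simulations of 600 genes and 30
subsystems. These sizes were chosen so a full verification completes in
well under a minute while leaving every statistical margin (ARI,
completeness, top-5 ranking) comfortably wide.
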