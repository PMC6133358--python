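"""Synthetic metagenomic communities and strain-variant call sets with
ground truth, giving every pipeline stage a testable input.

``simulate_community`` emulates the statistical structure the binning
features rely on: several genomes with distinct G+C content, each with its
own relative-abundance profile across samples, sheared into scaffolds whose
per-sample coverage is abundance x depth_factor with multiplicative
lognormal noise, and a set of single-copy marker genes planted once per
genome. ``simulate_strain_variants`` emulates a two-strain SNP mixture
against a reference: SNP sites sit at either a minor-strain depth stratum
(~150x) or the dominant stratum (~600x), with per-gene SNP rates elevated
in designated "enriched" subsystems.

Sequences are i.i.d. nucleotides with a G+C bias — adequate because the
binning features use only coverage and G+C, not k-mer composition. A single
seeded generator drives all randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .io import GeneModel, ScaffoldRecord, VariantSite

__all__ = [
    "CommunitySpec",
    "StrainVariantSpec",
    "CommunityTruth",
    "StrainTruth",
    "simulate_community",
    "simulate_strain_variants",
    "evaluate_binning",
    "write_variants_vcf",
    "write_gene_models_gff",
]

_PHYLA = [
    "Cyanobacteria", "Gammaproteobacteria", "Bacteroidetes", "Firmicutes",
    "Alphaproteobacteria", "Deltaproteobacteria", "Chloroflexi", "Planctomycetes",
    "Verrucomicrobia", "Gemmatimonadetes",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CommunitySpec:
    """Study conditions for a simulated multi-sample community.

    Defaults give an 8-genome, 4-sample community with well-separated G+C
    (0.30-0.65) and coverage signatures spanning roughly 6-120x — the
    abundance and replicate structure of a pooled multi-sample mat
    sequencing design, scaled down in genome size for fast simulation.
    """

    n_genomes: int = 8
    n_samples: int = 4
    genome_size_bp: int | list[int] = 200_000
    gc_targets: list[float] | None = None  # default: even spread 0.30-0.65
    abundances: np.ndarray | None = None  # (n_genomes, n_samples), relative
    depth_factor: float = 100.0
    coverage_noise_sd: float = 0.15  # lognormal sigma (natural log)
    fragment_mean: int = 10_000
    fragment_sd: int = 6_000
    fragment_min: int = 1_000
    markers_per_genome: int = 100
    marker_universe_size: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.fragment_min < 500:
            raise ValueError("fragment_min must be >= 500")
        rng = np.random.default_rng(self.seed)
        if self.gc_targets is None:
            # evenly spread G+C, assigned in an order decoupled from the
            # abundance ranking so composition and coverage are independent
            # axes, as they are across real taxa
            spread = np.linspace(0.30, 0.65, self.n_genomes)
            self.gc_targets = list(rng.permutation(spread))
        if any(not (0 < g < 1) for g in self.gc_targets):
            raise ValueError("gc_target must be in (0,1)")
        if isinstance(self.genome_size_bp, int):
            self.genome_size_bp = [self.genome_size_bp] * self.n_genomes
        if min(self.genome_size_bp) < self.fragment_min:
            raise ValueError("fragment_min exceeds a genome size")
        if self.abundances is None:
            # distinct log-spaced base abundances with a per-sample profile;
            # deterministic in the seed
            base = np.geomspace(1.2, 0.06, self.n_genomes)
            profile = rng.uniform(0.5, 1.5, size=(self.n_genomes, self.n_samples))
            self.abundances = base[:, None] * profile
        self.abundances = np.asarray(self.abundances, dtype=float)
        if (self.abundances < 0).any():
            raise ValueError("abundances must be non-negative")
        if self.abundances.shape != (self.n_genomes, self.n_samples):
            raise ValueError("abundances must be (n_genomes, n_samples)")
        if self.markers_per_genome > self.marker_universe_size:
            raise ValueError("markers_per_genome exceeds the marker universe")


@dataclass
class CommunityTruth:
    scaffold_to_genome: dict[str, str]
    genome_ids: list[str]
    genome_phylum: dict[str, str]
    marker_placements: pd.DataFrame  # genome_id, marker_gene_id, scaffold_id
    expected_coverage: np.ndarray  # (n_genomes, n_samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"scaffold_id": list(self.scaffold_to_genome),
             "genome_id": list(self.scaffold_to_genome.values())}
        )


def _random_sequence(rng: np.random.Generator, size: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    codes = rng.choice(4, size=size, p=p)
    return _BASES[codes].tobytes().decode("ascii")


def _fragment_lengths(rng: np.random.Generator, total: int, mean: int, sd: int, lo: int) -> list[int]:
    lens: list[int] = []
    remaining = total
    while remaining > 0:
        ln = int(max(lo, rng.normal(mean, sd)))
        if remaining - ln < lo:  # absorb the tail into the final scaffold
            ln = remaining
        lens.append(ln)
        remaining -= ln
    return lens


def simulate_community(
    spec: CommunitySpec,
    assembly_id: str = "k29",
    fragment_seed: int | None = None,
) -> tuple[list[ScaffoldRecord], pd.DataFrame, pd.DataFrame, CommunityTruth]:
    """Generate scaffolds, a coverage table, planted marker hits and truth.

    Genome sequences are a deterministic function of ``spec.seed`` alone,
    so calling again with a different ``fragment_seed`` re-shears the same
    genomes — three such calls emulate three assembly word sizes of one
    community.
    """
    genome_rng = np.random.default_rng(spec.seed)
    frag_rng = np.random.default_rng(
        spec.seed + 1 if fragment_seed is None else fragment_seed
    )
    sample_names = [f"sample_{i+1}" for i in range(spec.n_samples)]
    universe = [f"ESS_{i:03d}" for i in range(1, spec.marker_universe_size + 1)]

    scaffolds: list[ScaffoldRecord] = []
    truth_map: dict[str, str] = {}
    phylum_of: dict[str, str] = {}
    marker_rows = []
    hit_rows = []
    genome_ids = []
    k = 0
    for g in range(spec.n_genomes):
        gid = f"genome_{g+1}"
        genome_ids.append(gid)
        phylum_of[gid] = _PHYLA[g % len(_PHYLA)]
        seq = _random_sequence(genome_rng, spec.genome_size_bp[g], spec.gc_targets[g])
        lens = _fragment_lengths(
            frag_rng, len(seq), spec.fragment_mean, spec.fragment_sd, spec.fragment_min
        )
        pos = 0
        genome_scaffolds = []
        for ln in lens:
            sid = f"{assembly_id}.s{k:05d}"
            k += 1
            frag = seq[pos : pos + ln]
            pos += ln
            expected = spec.abundances[g] * spec.depth_factor
            # mean-one lognormal jitter so E[coverage] = abundance * depth_factor
            noise = frag_rng.lognormal(
                -spec.coverage_noise_sd**2 / 2, spec.coverage_noise_sd, spec.n_samples
            )
            rec = ScaffoldRecord(sid, assembly_id, frag, coverage=expected * noise)
            scaffolds.append(rec)
            genome_scaffolds.append(rec)
            truth_map[sid] = gid
        # plant each marker exactly once, on a length-weighted scaffold
        weights = np.array([s.length_bp for s in genome_scaffolds], dtype=float)
        weights /= weights.sum()
        markers = frag_rng.choice(universe, size=spec.markers_per_genome, replace=False)
        homes = frag_rng.choice(len(genome_scaffolds), size=len(markers), p=weights)
        for m, h in zip(markers, homes):
            sid = genome_scaffolds[h].scaffold_id
            marker_rows.append({"genome_id": gid, "marker_gene_id": m, "scaffold_id": sid})
            hit_rows.append(
                {"scaffold_id": sid, "marker_gene_id": m, "taxon_label": phylum_of[gid]}
            )

    coverage = pd.DataFrame(
        np.vstack([s.coverage for s in scaffolds]),
        index=pd.Index([s.scaffold_id for s in scaffolds], name="scaffold_id"),
        columns=sample_names,
    )
    marker_hits = pd.DataFrame(hit_rows)
    truth = CommunityTruth(
        scaffold_to_genome=truth_map,
        genome_ids=genome_ids,
        genome_phylum=phylum_of,
        marker_placements=pd.DataFrame(marker_rows),
        expected_coverage=spec.abundances * spec.depth_factor,
    )
    return scaffolds, coverage, marker_hits, truth


@dataclass
class StrainVariantSpec:
    """Study conditions for a two-strain SNP mixture against a reference.

    Defaults plant SNPs at a base rate of 0.5% of gene length, with a
    dominant-strain depth stratum at ~600x and a minor-strain stratum at
    ~150x holding most of the SNP sites, mirroring a community where a
    rarer strain carries the variation. Per-gene rates are overdispersed:
    a ``variable_gene_fraction`` of genes draw their density uniformly from
    ``variable_density_pct`` (strain-divergent genes reaching several
    percent), so every rate class is populated genome-wide as in real
    strain mixtures.
    """

    n_genes: int = 600
    gene_length_mean: int = 900
    gene_length_sd: int = 250
    gene_length_min: int = 300
    intergenic_gap: int = 150
    n_subsystems: int = 30
    genes_per_subsystem: int = 12
    enriched_subsystems: frozenset[str] = frozenset()
    enrichment_multiplier: float = 4.0
    base_density_pct: float = 0.5
    variable_gene_fraction: float = 0.10
    variable_density_pct: tuple[float, float] = (1.0, 4.0)
    major_depth: int = 600
    minor_depth: int = 150
    minor_site_fraction: float = 0.8
    contig_id: str = "ref_1"
    seed: int = 0

    def __post_init__(self):
        if self.enrichment_multiplier < 1:
            raise ValueError("enrichment multiplier must be >= 1")
        if self.major_depth <= 0 or self.minor_depth <= 0:
            raise ValueError("depths must be > 0")
        if not 0 <= self.minor_site_fraction <= 1:
            raise ValueError("minor_site_fraction must be in [0,1]")
        self.enriched_subsystems = frozenset(self.enriched_subsystems)


@dataclass
class StrainTruth:
    gene_multiplier: dict[str, float]
    enriched_subsystems: frozenset[str]
    expected_density_pct: dict[str, float]


def simulate_strain_variants(
    spec: StrainVariantSpec,
) -> tuple[list[VariantSite], list[GeneModel], pd.DataFrame, StrainTruth]:
    """Lay genes on a synthetic reference contig, sprinkle SNP sites per
    gene at the base rate (times the multiplier for genes of enriched
    subsystems) and draw each site's depth from the minor (~150x) or major
    (~600x) Poisson stratum."""
    rng = np.random.default_rng(spec.seed)

    genes: list[GeneModel] = []
    pos = 1
    for i in range(spec.n_genes):
        ln = int(max(spec.gene_length_min, rng.normal(spec.gene_length_mean, spec.gene_length_sd)))
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(
            GeneModel(f"gene_{i+1:04d}", spec.contig_id, pos, pos + ln - 1, strand,
                      product=f"protein {i+1}")
        )
        pos += ln + spec.intergenic_gap

    subsystem_ids = [f"SS_{j+1:02d}" for j in range(spec.n_subsystems)]
    unknown = set(spec.enriched_subsystems) - set(subsystem_ids)
    if unknown:
        raise ValueError(f"enriched subsystems not in catalog: {sorted(unknown)}")
    rows = []
    for ss in subsystem_ids:
        members = rng.choice(spec.n_genes, size=spec.genes_per_subsystem, replace=False)
        for m in members:
            rows.append({"gene_id": genes[m].gene_id, "subsystem_id": ss})
    subsystem_map = pd.DataFrame(rows).drop_duplicates()

    enriched_genes = set(
        subsystem_map.loc[
            subsystem_map["subsystem_id"].isin(spec.enriched_subsystems), "gene_id"
        ]
    )

    n_variable = int(round(spec.variable_gene_fraction * spec.n_genes))
    variable_genes = set(
        rng.choice(spec.n_genes, size=n_variable, replace=False)
    )

    sites: list[VariantSite] = []
    gene_multiplier: dict[str, float] = {}
    expected_density: dict[str, float] = {}
    for i, g in enumerate(genes):
        mult = spec.enrichment_multiplier if g.gene_id in enriched_genes else 1.0
        gene_multiplier[g.gene_id] = mult
        if i in variable_genes:
            base = rng.uniform(*spec.variable_density_pct)
        else:
            base = spec.base_density_pct
        rate = base / 100.0 * mult
        expected_density[g.gene_id] = 100.0 * rate
        n_sites = min(rng.poisson(rate * g.length_bp), g.length_bp)
        if n_sites == 0:
            continue
        positions = rng.choice(np.arange(g.start, g.end + 1), size=n_sites, replace=False)
        for p in np.sort(positions):
            stratum = spec.minor_depth if rng.random() < spec.minor_site_fraction else spec.major_depth
            sites.append(VariantSite(spec.contig_id, int(p), "snp", int(rng.poisson(stratum))))

    truth = StrainTruth(
        gene_multiplier=gene_multiplier,
        enriched_subsystems=spec.enriched_subsystems,
        expected_density_pct=expected_density,
    )
    return sites, genes, subsystem_map, truth


def write_variants_vcf(
    sites: list[VariantSite], contig_lengths: dict[str, int], path, seed: int | None = None
) -> None:
    """Write sites as a minimal VCF (SNP records with INFO/DP)."""
    import pysam

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">')
    if seed is not None:
        header.add_line(f"##seed={seed}")
    for cid, ln in contig_lengths.items():
        header.add_line(f"##contig=<ID={cid},length={ln}>")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for s in sorted(sites, key=lambda x: (x.contig_id, x.position)):
            rec = out.new_record(
                contig=s.contig_id, start=s.position - 1, stop=s.position,
                alleles=("A", "G"),
            )
            rec.info["DP"] = s.depth
            out.write(rec)


def write_gene_models_gff(genes: list[GeneModel], path, seed: int | None = None) -> None:
    """Write gene models as GFF3 (type=gene, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        if seed is not None:
            fh.write(f"#seed={seed}\n")
        for g in genes:
            attrs = f"ID={g.gene_id};product={g.product}" if g.product else f"ID={g.gene_id}"
            fh.write(
                f"{g.contig_id}\tgalaxybin\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def evaluate_binning(
    assignment,
    truth: CommunityTruth,
    scaffolds: list[ScaffoldRecord],
    min_len: int = 5000,
) -> dict:
    """Compare a bin assignment against genome-of-origin truth.

    Returns the adjusted Rand index over scaffolds above ``min_len``,
    per-genome recall (fraction of the genome's bp landing in its modal
    bin) and per-bin precision (fraction of the bin's bp from its modal
    genome).
    """
    table = assignment.table if hasattr(assignment, "table") else assignment
    lengths = {s.scaffold_id: s.length_bp for s in scaffolds}
    merged = table[table["scaffold_id"].isin(truth.scaffold_to_genome)].copy()
    if merged.empty:
        raise ValueError("assignment and truth share no scaffolds")
    merged["genome"] = merged["scaffold_id"].map(truth.scaffold_to_genome)
    merged["length"] = merged["scaffold_id"].map(lengths)
    big = merged[merged["length"] > min_len]
    ari = adjusted_rand_score(big["genome"], big["bin_label"]) if len(big) else float("nan")

    recall = {}
    for gid, grp in merged.groupby("genome"):
        bp = grp.groupby("bin_label")["length"].sum()
        binned = bp[bp.index.str.startswith("bin:")]
        recall[gid] = float(binned.max() / grp["length"].sum()) if len(binned) else 0.0
    precision = {}
    for lab, grp in merged[merged["bin_label"].str.startswith("bin:")].groupby("bin_label"):
        bp = grp.groupby("genome")["length"].sum()
        precision[lab] = float(bp.max() / bp.sum())
    return {
        "ari_training": float(ari),
        "per_genome_recall": recall,
        "per_bin_precision": precision,
    }
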