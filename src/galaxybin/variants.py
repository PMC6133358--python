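"""Reference-mapped strain-variation analysis.

SNPs called against a reference genome are filtered to a coverage window
(default 50-200x) that isolates the low-coverage strain stratum from the
dominant strain's main coverage distribution, aggregated per gene as a
variant density (percent: variants per 100 bp of gene length), binned into
density rate classes ([0,1)%, [1,2)%, [2,3)%, [3,inf)% by default), and
summarised per gene subsystem with the score

    score_g = scale * sum_n C_n * (V_g,n / V_G,n  -  V_g,all / V_G,all)

where V_g,n counts genes of subsystem g in rate class n, V_g,all all genes
of the subsystem, and V_G,n / V_G,all the genome-wide counterparts. With
unit weights C_n and scale 1000, a positive score means the subsystem
accumulates more variation than the genome-wide average, a negative score
less. Zero-variant genes are excluded from the rate classes by default but
always count toward V_g,all / V_G,all.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import GeneModel, VariantSite

logger = logging.getLogger(__name__)

__all__ = [
    "GeneVariantProfile",
    "RateClassConfig",
    "GenomeWideCounts",
    "SubsystemScore",
    "ScoreSummary",
    "filter_sites_by_coverage",
    "gene_variant_density",
    "tabulate_rate_classes",
    "subsystem_score",
    "score_subsystems",
    "summarize_scores",
    "rank_variable_genes",
    "depth_histogram",
]


@dataclass
class GeneVariantProfile:
    gene_id: str
    length_bp: int
    variant_count: int = 0
    subsystem_ids: frozenset[str] = frozenset()
    product: str = ""

    @property
    def density_pct(self) -> float:
        return 100.0 * self.variant_count / self.length_bp


@dataclass
class RateClassConfig:
    """Rate classes over variant density (percent), left-closed right-open,
    with the last class open-ended: edges (0,1,2,3) -> [0,1) [1,2) [2,3) [3,inf).
    """

    edges: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    weights: tuple[float, ...] | None = None  # C_n; None -> all 1
    scale: float = 1000.0
    include_zero_variant_genes_in_classes: bool = False

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("class edges must be strictly increasing")
        if self.weights is None:
            self.weights = tuple(1.0 for _ in self.edges)
        if len(self.weights) != len(self.edges):
            raise ValueError("need one weight per rate class")

    @property
    def n_classes(self) -> int:
        return len(self.edges)

    def classify(self, density_pct: float) -> int:
        """1-based rate class of a density; last class is open-ended."""
        for n in range(self.n_classes - 1, -1, -1):
            if density_pct >= self.edges[n]:
                return n + 1
        raise ValueError(f"density {density_pct} below first edge {self.edges[0]}")


@dataclass
class GenomeWideCounts:
    v_G_n: np.ndarray  # genes per rate class, genome-wide
    v_G_all: int  # all genes


@dataclass
class SubsystemScore:
    subsystem_id: str
    v_g_n: np.ndarray
    v_g_all: int
    score: float


@dataclass
class ScoreSummary:
    mean: float
    median: float
    sd: float  # population standard deviation
    n_subsystems: int


def filter_sites_by_coverage(
    sites: list[VariantSite], low: int = 50, high: int = 200
) -> list[VariantSite]:
    """Keep sites with low <= depth <= high (both inclusive): the window that
    captures the rarer strain stratum (~150x) and excludes the dominant
    strain's main distribution (~600x)."""
    if low > high:
        raise ValueError(f"low {low} > high {high}")
    return [s for s in sites if low <= s.depth <= high]


def gene_variant_density(
    sites: list[VariantSite],
    genes: list[GeneModel],
    subsystem_map: pd.DataFrame | None = None,
) -> list[GeneVariantProfile]:
    """Assign each site to every gene whose [start, end] span contains its
    position (a site in two overlapping genes counts once in each) and
    summarise per gene. Genes without sites get count 0."""
    trees: dict[str, IntervalTree] = {}
    for i, g in enumerate(genes):
        trees.setdefault(g.contig_id, IntervalTree())[g.start : g.end + 1] = i
    counts = np.zeros(len(genes), dtype=int)
    for s in sites:
        tree = trees.get(s.contig_id)
        if tree is None:
            continue
        for iv in tree[s.position]:
            counts[iv.data] += 1
    membership: dict[str, frozenset[str]] = {}
    if subsystem_map is not None:
        membership = {
            gid: frozenset(grp["subsystem_id"])
            for gid, grp in subsystem_map.groupby("gene_id")
        }
    return [
        GeneVariantProfile(
            gene_id=g.gene_id,
            length_bp=g.length_bp,
            variant_count=int(c),
            subsystem_ids=membership.get(g.gene_id, frozenset()),
            product=g.product,
        )
        for g, c in zip(genes, counts)
    ]


def tabulate_rate_classes(
    profiles: list[GeneVariantProfile],
    subsystem_map: pd.DataFrame,
    config: RateClassConfig | None = None,
) -> tuple[pd.DataFrame, GenomeWideCounts]:
    """Per-subsystem and genome-wide gene counts per density rate class.

    V_g,all counts every gene of the subsystem; the classes count only genes
    with at least one variant unless configured otherwise. Genome-wide
    counts cover ALL genes, not only those belonging to a subsystem; a gene
    in several subsystems contributes to each but is counted once
    genome-wide.
    """
    config = config or RateClassConfig()
    K = config.n_classes

    def gene_class(p: GeneVariantProfile) -> int | None:
        if p.variant_count == 0 and not config.include_zero_variant_genes_in_classes:
            return None
        return config.classify(p.density_pct)

    classes = {p.gene_id: gene_class(p) for p in profiles}
    v_G_n = np.zeros(K, dtype=int)
    for c in classes.values():
        if c is not None:
            v_G_n[c - 1] += 1
    gw = GenomeWideCounts(v_G_n=v_G_n, v_G_all=len(profiles))

    known = {p.gene_id for p in profiles}
    rows = []
    for subsystem_id, grp in subsystem_map.groupby("subsystem_id"):
        genes = [g for g in grp["gene_id"].unique() if g in known]
        if not genes:
            logger.warning("subsystem %r has no known genes; excluded", subsystem_id)
            continue
        v_g_n = np.zeros(K, dtype=int)
        for gid in genes:
            c = classes[gid]
            if c is not None:
                v_g_n[c - 1] += 1
        rows.append(
            {"subsystem_id": subsystem_id, "v_g_all": len(genes),
             **{f"class_{n+1}": int(v_g_n[n]) for n in range(K)}}
        )
    table = pd.DataFrame(rows)
    return table, gw


def subsystem_score(
    v_g_n: np.ndarray,
    v_g_all: int,
    gw: GenomeWideCounts,
    config: RateClassConfig | None = None,
) -> float:
    """The subsystem variation score: scale * sum_n C_n (V_g,n/V_G,n −
    V_g,all/V_G,all). Classes empty genome-wide contribute 0 (logged)."""
    config = config or RateClassConfig()
    if gw.v_G_all == 0:
        raise ValueError("genome-wide gene count is zero")
    total = 0.0
    base = v_g_all / gw.v_G_all
    for n in range(config.n_classes):
        if gw.v_G_n[n] == 0:
            if v_g_n[n] != 0:
                logger.warning("rate class %d empty genome-wide; term skipped", n + 1)
            continue
        total += config.weights[n] * (v_g_n[n] / gw.v_G_n[n] - base)
    return config.scale * total


def score_subsystems(
    profiles: list[GeneVariantProfile],
    subsystem_map: pd.DataFrame,
    config: RateClassConfig | None = None,
) -> tuple[pd.DataFrame, GenomeWideCounts]:
    """Tabulate rate classes and score every subsystem; returns the
    per-subsystem table (counts + score, sorted by score) and the
    genome-wide counts."""
    config = config or RateClassConfig()
    table, gw = tabulate_rate_classes(profiles, subsystem_map, config)
    K = config.n_classes
    class_cols = [f"class_{n+1}" for n in range(K)]
    scores = [
        subsystem_score(row[class_cols].to_numpy(dtype=int), int(row["v_g_all"]), gw, config)
        for _, row in table.iterrows()
    ]
    table = table.assign(score=scores).sort_values("score").reset_index(drop=True)
    return table, gw


def summarize_scores(score_table: pd.DataFrame) -> ScoreSummary:
    """Unweighted mean, median and population SD of scores across subsystems."""
    if score_table.empty:
        raise ValueError("no subsystem scores to summarise")
    s = score_table["score"].to_numpy(dtype=float)
    return ScoreSummary(
        mean=float(np.mean(s)),
        median=float(np.median(s)),
        sd=float(np.std(s)),  # population SD
        n_subsystems=len(s),
    )


DEFAULT_UNKNOWN_PATTERNS = ("hypothetical", "unknown", "uncharacterized", "putative protein")


def rank_variable_genes(
    profiles: list[GeneVariantProfile],
    score_table: pd.DataFrame,
    top_k_subsystems: int = 5,
    unknown_patterns: tuple[str, ...] = DEFAULT_UNKNOWN_PATTERNS,
) -> pd.DataFrame:
    """Genes of the top-k highest-scoring subsystems ranked by variant
    density (percent), excluding products matching an "unknown" pattern.
    A gene in several qualifying subsystems appears once with all listed."""
    top = set(score_table.nlargest(top_k_subsystems, "score")["subsystem_id"])
    pat = re.compile("|".join(re.escape(p) for p in unknown_patterns), re.IGNORECASE)
    rows = []
    for p in profiles:
        qual = p.subsystem_ids & top
        if not qual:
            continue
        if p.product and pat.search(p.product):
            continue
        rows.append({
            "gene_id": p.gene_id,
            "density_pct": round(p.density_pct, 4),
            "product": p.product,
            "subsystems": ";".join(sorted(p.subsystem_ids)),
        })
    df = pd.DataFrame(rows, columns=["gene_id", "density_pct", "product", "subsystems"])
    return df.sort_values("density_pct", ascending=False, kind="stable").reset_index(drop=True)


def depth_histogram(sites: list[VariantSite], bin_width: int = 25) -> pd.DataFrame:
    """SNP counts per depth bin — the coverage-stratified SNP report that
    motivates the 50-200x window (two strata: rare strain ~150x, dominant
    ~600x)."""
    if not sites:
        return pd.DataFrame(columns=["depth_low", "depth_high", "n_snps"])
    depths = np.array([s.depth for s in sites])
    top = (int(depths.max()) // bin_width + 1) * bin_width
    edges = np.arange(0, top + bin_width, bin_width)
    counts, _ = np.histogram(depths, bins=edges)
    return pd.DataFrame({
        "depth_low": edges[:-1],
        "depth_high": edges[1:],
        "n_snps": counts,
    })
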