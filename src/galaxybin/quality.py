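"""Single-copy marker QC, majority-vote taxonomy, top-bin selection and
cross-assembly reconciliation.

Completeness is the fraction of a single-copy marker universe found at least
once in a bin; duplication the fraction found at least twice (a
contamination proxy). Taxonomy is called twice per bin: the modal phylum
over taxonomy-bearing marker hits, and the modal nearest-genome label over
all ORFs. When the same community is assembled several times, bins are
matched across assemblies by marker-content Jaccard similarity and the best
(completeness − duplication) representative of each group is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ScaffoldRecord

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerUniverse",
    "BinQuality",
    "TaxonomyCall",
    "AssemblyBin",
    "assess_bin_quality",
    "call_majority_phylum",
    "call_majority_reference_taxon",
    "select_top_bins",
    "reconcile_across_assemblies",
    "compute_l50",
    "bin_summary_table",
]


@dataclass
class MarkerUniverse:
    """The set of single-copy essential genes expected once per genome.

    ``per_lineage_sizes`` optionally maps a phylum to its universe size so
    completeness denominators can be lineage-aware (the universe varies a
    little between lineages, roughly 104-106 genes).
    """

    marker_gene_ids: frozenset[str]
    per_lineage_sizes: dict[str, int] | None = None

    def __post_init__(self):
        if not self.marker_gene_ids:
            raise ValueError("marker universe is empty")
        self.marker_gene_ids = frozenset(self.marker_gene_ids)

    def size_for(self, phylum: str | None = None) -> int:
        if phylum and self.per_lineage_sizes and phylum in self.per_lineage_sizes:
            return self.per_lineage_sizes[phylum]
        return len(self.marker_gene_ids)

    @classmethod
    def generic(cls, n: int = 100, prefix: str = "ESS") -> "MarkerUniverse":
        return cls(frozenset(f"{prefix}_{i:03d}" for i in range(1, n + 1)))

    @classmethod
    def from_tsv(cls, path) -> "MarkerUniverse":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        col = "marker_gene_id" if "marker_gene_id" in df.columns else df.columns[0]
        return cls(frozenset(df[col].dropna()))


@dataclass
class BinQuality:
    bin_label: str
    ess_found: int
    ess_duplicated: int
    ess_total: int
    mean_coverage: float
    total_bp: int
    l50_bp: int
    flagged_empty: bool = False

    @property
    def completeness(self) -> float:
        return self.ess_found / self.ess_total if self.ess_total else 0.0

    @property
    def duplication(self) -> float:
        return self.ess_duplicated / self.ess_total if self.ess_total else 0.0


@dataclass
class TaxonomyCall:
    majority_phylum: str = "undetermined"
    phylum_support: tuple[int, int] = (0, 0)  # winning count / labelled count
    majority_reference_taxon: str = "undetermined"
    reference_fraction: float = 0.0


def compute_l50(lengths) -> int:
    """Length of the scaffold at which the cumulative length, taken from the
    largest scaffold down, first reaches half the total."""
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if arr.size == 0:
        return 0
    half = arr.sum() / 2
    cum = np.cumsum(arr)
    return int(arr[np.searchsorted(cum, half)])


def assess_bin_quality(
    bin_scaffolds: list[ScaffoldRecord],
    marker_hits: pd.DataFrame,
    universe: MarkerUniverse,
    bin_label: str = "",
    phylum: str | None = None,
) -> BinQuality:
    """Marker completeness/duplication plus assembly statistics for one bin.

    ``ess_found`` counts distinct universe markers present at least once on
    the bin's scaffolds, ``ess_duplicated`` those present at least twice.
    Mean coverage is the length-weighted mean (over scaffolds) of each
    scaffold's mean per-sample coverage.
    """
    ids = {s.scaffold_id for s in bin_scaffolds}
    if not ids:
        logger.warning("empty bin %s", bin_label)
        return BinQuality(bin_label, 0, 0, universe.size_for(phylum), 0.0, 0, 0, True)
    hits = marker_hits[
        marker_hits["scaffold_id"].isin(ids)
        & marker_hits["marker_gene_id"].isin(universe.marker_gene_ids)
    ]
    counts = hits["marker_gene_id"].value_counts()
    found = int((counts >= 1).sum())
    duplicated = int((counts >= 2).sum())
    lengths = np.array([s.length_bp for s in bin_scaffolds], dtype=float)
    total_bp = int(lengths.sum())
    covs = np.array(
        [float(np.mean(s.coverage)) if s.coverage is not None else 0.0 for s in bin_scaffolds]
    )
    mean_cov = float(np.average(covs, weights=lengths)) if total_bp else 0.0
    return BinQuality(
        bin_label=bin_label,
        ess_found=found,
        ess_duplicated=duplicated,
        ess_total=universe.size_for(phylum),
        mean_coverage=mean_cov,
        total_bp=total_bp,
        l50_bp=compute_l50(lengths),
    )


def _majority(labels: pd.Series) -> tuple[str, int, int]:
    labels = labels.dropna()
    labels = labels[labels != ""]
    if labels.empty:
        return "undetermined", 0, 0
    counts = labels.value_counts()
    top = counts.max()
    winners = sorted(counts[counts == top].index)
    if len(winners) > 1:
        logger.warning("taxonomy tie between %s; keeping %r", winners, winners[0])
    return winners[0], int(top), int(counts.sum())


def call_majority_phylum(bin_marker_hits: pd.DataFrame) -> TaxonomyCall:
    """Modal phylum over the bin's taxonomy-bearing marker hits; ties break
    lexicographically with a warning."""
    winner, num, den = _majority(bin_marker_hits["taxon_label"])
    return TaxonomyCall(majority_phylum=winner, phylum_support=(num, den))


def call_majority_reference_taxon(bin_orfs: pd.DataFrame) -> TaxonomyCall:
    """Modal nearest-genome label over all ORFs of the bin; fraction of
    bin ORFs that match the winner."""
    winner, num, _den = _majority(bin_orfs["nearest_genome_label"])
    total = len(bin_orfs)
    frac = num / total if total else 0.0
    return TaxonomyCall(majority_reference_taxon=winner, reference_fraction=frac)


def select_top_bins(
    qualities: list[BinQuality], completeness_threshold: float = 0.8
) -> list[BinQuality]:
    """Bins above the completeness threshold, ordered by mean coverage
    (descending); idempotent on its own output."""
    kept = [q for q in qualities if q.completeness > completeness_threshold]
    return sorted(kept, key=lambda q: -q.mean_coverage)


@dataclass
class AssemblyBin:
    """A bin from one assembly, bundled with what reconciliation needs."""

    assembly_id: str
    bin_label: str
    scaffolds: list[ScaffoldRecord]
    quality: BinQuality
    marker_set: frozenset[str]
    taxonomy: TaxonomyCall = field(default_factory=TaxonomyCall)


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def reconcile_across_assemblies(
    bin_sets: list[list[AssemblyBin]],
    jaccard_threshold: float = 0.5,
    require_phylum_agreement: bool = True,
) -> list[AssemblyBin]:
    """Group corresponding bins across assemblies and keep the best of each.

    Bins are linked when their marker-gene content Jaccard similarity is at
    least ``jaccard_threshold`` (and, when both calls are determined, their
    majority phyla agree); groups are the connected components of that
    graph. Within a group the bin maximising completeness − duplication is
    kept, ties broken by higher mean coverage. Single assemblies pass
    through unchanged.
    """
    if not bin_sets:
        raise ValueError("need at least one assembly")
    all_bins = [b for bins in bin_sets for b in bins]
    n = len(all_bins)
    # union-find over similarity links
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            a, b = all_bins[i], all_bins[j]
            if a.assembly_id == b.assembly_id:
                continue
            if _jaccard(a.marker_set, b.marker_set) < jaccard_threshold:
                continue
            if require_phylum_agreement:
                pa, pb = a.taxonomy.majority_phylum, b.taxonomy.majority_phylum
                if pa != "undetermined" and pb != "undetermined" and pa != pb:
                    continue
            union(i, j)

    groups: dict[int, list[AssemblyBin]] = {}
    for i, b in enumerate(all_bins):
        groups.setdefault(find(i), []).append(b)

    kept = []
    for members in groups.values():
        best = max(
            members,
            key=lambda b: (b.quality.completeness - b.quality.duplication,
                           b.quality.mean_coverage),
        )
        kept.append(best)
    kept.sort(key=lambda b: -b.quality.mean_coverage)
    return kept


def bin_summary_table(
    qualities: list[BinQuality], taxonomy: dict[str, TaxonomyCall] | None = None
) -> pd.DataFrame:
    """Summary-statistics table for bins: L50 (kbp), total Mbp, mean
    coverage, Ess/Dup/Tot marker counts, and majority taxonomy calls."""
    rows = []
    for q in qualities:
        tc = (taxonomy or {}).get(q.bin_label, TaxonomyCall())
        rows.append({
            "bin": q.bin_label,
            "l50_kbp": round(q.l50_bp / 1e3, 1),
            "total_mbp": round(q.total_bp / 1e6, 2),
            "mean_cov": round(q.mean_coverage, 1),
            "ess": q.ess_found,
            "dup": q.ess_duplicated,
            "tot": q.ess_total,
            "completeness": round(q.completeness, 4),
            "duplication": round(q.duplication, 4),
            "majority_phylum": tc.majority_phylum,
            "phylum_support": f"{tc.phylum_support[0]}/{tc.phylum_support[1]}",
            "majority_taxon": tc.majority_reference_taxon,
            "taxon_pct": int(round(100 * tc.reference_fraction)),
        })
    return pd.DataFrame(rows)
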