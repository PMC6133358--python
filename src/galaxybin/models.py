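"""Model/Results front-ends over the binning and variant-scoring pipelines.

``GalaxyBinningModel`` is built from scaffolds (plus coverage and marker
hits) and ``fit()`` runs feature building, PCA, DBSCAN seeding, SVM label
propagation and marker QC, returning a ``GalaxyBinningResults`` carrying
the assignment, per-bin quality, taxonomy calls and a summary table.
``SubsystemVariationModel`` is built from variant sites, gene models and a
subsystem map and ``fit()`` runs the coverage-window filter, per-gene
density aggregation and the subsystem variation score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as F
from . import quality as Q
from . import variants as V
from .io import (
    GeneModel,
    ScaffoldRecord,
    VariantSite,
    read_coverage_table,
    read_gene_models,
    read_marker_hits,
    read_orf_annotations,
    read_scaffolds,
    read_subsystem_map,
    read_variant_sites,
)

__all__ = [
    "GalaxyBinningModel",
    "GalaxyBinningResults",
    "SubsystemVariationModel",
    "SubsystemVariationResults",
]


class GalaxyBinningModel:
    """Coverage+GC galaxy binning of assembled scaffolds.

    Parameters
    ----------
    scaffolds : list of ScaffoldRecord with coverage vectors attached.
    marker_hits : optional marker-gene hit table for QC and tuning.
    orf_annotations : optional ORF table for nearest-genome taxonomy.
    universe : marker universe used for completeness denominators;
        defaults to the distinct marker IDs seen in ``marker_hits``.
    min_train_len / min_class_len : length gates for DBSCAN training
        (> 5 kbp) and SVM classification (> 1.5 kbp).
    """

    def __init__(
        self,
        scaffolds: list[ScaffoldRecord],
        marker_hits: pd.DataFrame | None = None,
        orf_annotations: pd.DataFrame | None = None,
        universe: Q.MarkerUniverse | None = None,
        min_train_len: int = 5000,
        min_class_len: int = 1500,
        pseudocount: float = 1.0,
    ):
        self.scaffolds = scaffolds
        self.marker_hits = marker_hits
        self.orf_annotations = orf_annotations
        if universe is None and marker_hits is not None:
            universe = Q.MarkerUniverse(frozenset(marker_hits["marker_gene_id"]))
        self.universe = universe
        self.min_train_len = min_train_len
        self.min_class_len = min_class_len
        self.pseudocount = pseudocount

    @classmethod
    def from_files(
        cls,
        scaffold_fasta,
        coverage_tsv,
        assembly_id: str = "assembly",
        marker_tsv=None,
        orf_tsv=None,
        universe_tsv=None,
        **kwargs,
    ) -> "GalaxyBinningModel":
        scaffolds = read_scaffolds(scaffold_fasta, assembly_id)
        read_coverage_table(coverage_tsv, scaffolds)
        markers = read_marker_hits(marker_tsv) if marker_tsv else None
        orfs = read_orf_annotations(orf_tsv) if orf_tsv else None
        universe = Q.MarkerUniverse.from_tsv(universe_tsv) if universe_tsv else None
        return cls(scaffolds, markers, orfs, universe, **kwargs)

    def fit(
        self,
        eps: float = 0.5,
        min_samples: int = 5,
        gc_weight: float = 1.0,
        conf_threshold: float = 0.5,
        n_components: int = 3,
        tune_grid: list[F.GridPoint] | None = None,
        seed: int = 0,
    ) -> "GalaxyBinningResults":
        """Run the binning pipeline; with ``tune_grid``, grid-search
        (eps, min_samples, gc_weight) on the marker objective first."""
        tuning = None
        if tune_grid is not None:
            if self.marker_hits is None:
                raise ValueError("tuning requires marker hits")
            tuning = F.tune_clustering(
                tune_grid, self.scaffolds, self.marker_hits, self.universe,
                min_train_len=self.min_train_len, min_class_len=self.min_class_len,
                conf_threshold=conf_threshold, pseudocount=self.pseudocount,
                n_components=n_components, seed=seed,
            )
            eps = tuning.best.eps
            min_samples = tuning.best.min_samples
            gc_weight = tuning.best.gc_weight

        fm = F.build_feature_matrix(
            self.scaffolds, min_len=self.min_class_len,
            pseudocount=self.pseudocount, gc_weight=gc_weight,
        )
        proj = F.project_top_components(fm, k=n_components, fit_min_len=self.min_train_len)
        clusters = F.cluster_training_scaffolds(
            proj, eps=eps, min_samples=min_samples, min_train_len=self.min_train_len
        )
        assignment = F.propagate_bin_labels(
            clusters, proj, min_class_len=self.min_class_len,
            conf_threshold=conf_threshold, seed=seed,
        )
        return GalaxyBinningResults(self, assignment, proj, clusters, tuning,
                                    params={"eps": eps, "min_samples": min_samples,
                                            "gc_weight": gc_weight,
                                            "conf_threshold": conf_threshold,
                                            "seed": seed})


@dataclass
class GalaxyBinningResults:
    """Fitted binning: assignment, galaxy coordinates and bin QC."""

    model: GalaxyBinningModel
    assignment: F.BinAssignment
    projection: F.Projection
    clusters: F.ClusterLabels
    tuning: F.TuningResult | None = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self._qualities: list[Q.BinQuality] | None = None

    @property
    def bin_labels(self) -> list[str]:
        return self.assignment.bin_labels

    def bin_scaffolds(self, bin_label: str) -> list[ScaffoldRecord]:
        members = set(self.assignment.members(bin_label))
        return [s for s in self.model.scaffolds if s.scaffold_id in members]

    def bin_qualities(self) -> list[Q.BinQuality]:
        if self.model.marker_hits is None or self.model.universe is None:
            raise ValueError("marker hits are required for bin QC")
        if self._qualities is None:
            self._qualities = [
                Q.assess_bin_quality(
                    self.bin_scaffolds(lab), self.model.marker_hits,
                    self.model.universe, bin_label=lab,
                )
                for lab in self.bin_labels
            ]
        return self._qualities

    def taxonomy_calls(self) -> dict[str, Q.TaxonomyCall]:
        calls: dict[str, Q.TaxonomyCall] = {}
        for lab in self.bin_labels:
            members = set(self.assignment.members(lab))
            tc = Q.TaxonomyCall()
            if self.model.marker_hits is not None:
                hits = self.model.marker_hits[
                    self.model.marker_hits["scaffold_id"].isin(members)
                ]
                part = Q.call_majority_phylum(hits)
                tc.majority_phylum = part.majority_phylum
                tc.phylum_support = part.phylum_support
            if self.model.orf_annotations is not None:
                orfs = self.model.orf_annotations[
                    self.model.orf_annotations["scaffold_id"].isin(members)
                ]
                part = Q.call_majority_reference_taxon(orfs)
                tc.majority_reference_taxon = part.majority_reference_taxon
                tc.reference_fraction = part.reference_fraction
            calls[lab] = tc
        return calls

    def bin_table(self) -> pd.DataFrame:
        """Per-bin summary: L50 kbp, total Mbp, mean coverage, Ess/Dup/Tot
        and majority taxonomy, ordered by mean coverage."""
        qualities = sorted(self.bin_qualities(), key=lambda q: -q.mean_coverage)
        taxonomy = self.taxonomy_calls() if (
            self.model.marker_hits is not None or self.model.orf_annotations is not None
        ) else None
        return Q.bin_summary_table(qualities, taxonomy)

    def top_bins(self, completeness_threshold: float = 0.8) -> list[Q.BinQuality]:
        return Q.select_top_bins(self.bin_qualities(), completeness_threshold)

    def galaxy_coordinates(self) -> pd.DataFrame:
        """Per-scaffold principal-component coordinates (galaxy plot data)."""
        k = self.projection.projected.shape[1]
        df = pd.DataFrame(
            self.projection.projected, columns=[f"PC{i+1}" for i in range(k)]
        )
        df.insert(0, "scaffold_id", self.projection.scaffold_ids)
        df["length_bp"] = self.projection.lengths
        df["bin_label"] = self.assignment.labels_for(self.projection.scaffold_ids).values
        return df

    def plot_galaxy(self, path=None, components=(0, 1)):
        """Scatter the scaffolds in PC space coloured by bin."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        coords = self.galaxy_coordinates()
        i, j = components
        fig, ax = plt.subplots(figsize=(7, 6))
        for lab, grp in coords.groupby("bin_label"):
            kw = {"s": 6, "alpha": 0.6, "label": lab}
            if not lab.startswith("bin:"):
                kw.update(c="lightgrey", alpha=0.3)
            ax.scatter(grp[f"PC{i+1}"], grp[f"PC{j+1}"], **kw)
        ax.set_xlabel(f"PC{i+1}")
        ax.set_ylabel(f"PC{j+1}")
        ax.legend(fontsize=6, ncol=2, markerscale=2)
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig

    def summary(self) -> str:
        n = len(self.assignment.table)
        counts = self.assignment.table["bin_label"].value_counts()
        n_binned = int(counts[counts.index.str.startswith("bin:")].sum())
        lines = [
            "Galaxy binning results",
            "=" * 54,
            f"scaffolds considered (> {self.model.min_class_len} bp): {n}",
            f"training scaffolds (> {self.model.min_train_len} bp):  {int(self.projection.train_mask.sum())}",
            f"clusters (bins): {self.clusters.n_clusters}   noise -> background: {self.clusters.n_noise}",
            f"binned: {n_binned}   background: {int(counts.get('background', 0))}   "
            f"unbinned: {int(counts.get('unbinned', 0))}",
            f"parameters: eps={self.params.get('eps')} min_samples={self.params.get('min_samples')} "
            f"gc_weight={self.params.get('gc_weight')} conf_threshold={self.params.get('conf_threshold')}",
        ]
        if self.model.marker_hits is not None:
            tbl = self.bin_table()
            lines += ["", tbl.to_string(index=False)]
        return "\n".join(lines)


class SubsystemVariationModel:
    """Strain-variation scoring of gene subsystems from reference-mapped
    SNP calls.

    Parameters
    ----------
    sites : variant sites (SNPs) with depth.
    genes : reference gene models.
    subsystem_map : gene_id -> subsystem_id membership (many-to-many).
    low, high : inclusive depth window isolating the minor strain stratum.
    config : rate-class edges, weights and score scale.
    """

    def __init__(
        self,
        sites: list[VariantSite],
        genes: list[GeneModel],
        subsystem_map: pd.DataFrame,
        low: int = 50,
        high: int = 200,
        config: V.RateClassConfig | None = None,
    ):
        self.sites = sites
        self.genes = genes
        self.subsystem_map = subsystem_map
        self.low = low
        self.high = high
        self.config = config or V.RateClassConfig()

    @classmethod
    def from_files(cls, vcf, gff, subsystem_tsv, **kwargs) -> "SubsystemVariationModel":
        return cls(
            read_variant_sites(vcf),
            read_gene_models(gff),
            read_subsystem_map(subsystem_tsv),
            **kwargs,
        )

    def fit(self) -> "SubsystemVariationResults":
        filtered = V.filter_sites_by_coverage(self.sites, self.low, self.high)
        profiles = V.gene_variant_density(filtered, self.genes, self.subsystem_map)
        scores, gw = V.score_subsystems(profiles, self.subsystem_map, self.config)
        return SubsystemVariationResults(self, filtered, profiles, scores, gw)


@dataclass
class SubsystemVariationResults:
    """Fitted variation scores: per-gene densities, per-subsystem scores."""

    model: SubsystemVariationModel
    filtered_sites: list[VariantSite]
    profiles: list[V.GeneVariantProfile]
    scores: pd.DataFrame  # subsystem_id, v_g_all, class_n..., score
    genome_wide: V.GenomeWideCounts

    def score_summary(self) -> V.ScoreSummary:
        return V.summarize_scores(self.scores)

    def gene_table(self, top_k_subsystems: int = 5) -> pd.DataFrame:
        return V.rank_variable_genes(self.profiles, self.scores, top_k_subsystems)

    def depth_histogram(self, bin_width: int = 25) -> pd.DataFrame:
        """Histogram over ALL input sites (pre-filter) — shows both strata."""
        return V.depth_histogram(self.model.sites, bin_width)

    def plot_depth_histogram(self, path=None, bin_width: int = 25):
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        hist = self.depth_histogram(bin_width)
        fig, ax = plt.subplots(figsize=(7, 4))
        ax.bar(hist["depth_low"], hist["n_snps"], width=bin_width, align="edge")
        ax.axvspan(self.model.low, self.model.high, color="orange", alpha=0.2,
                   label=f"analysis window [{self.model.low},{self.model.high}]x")
        ax.set_xlabel("read depth (x)")
        ax.set_ylabel("SNP sites")
        ax.legend()
        fig.tight_layout()
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig

    def summary(self) -> str:
        ss = self.score_summary()
        n_dropped = len(self.model.sites) - len(self.filtered_sites)
        most = self.scores.tail(5).iloc[::-1]
        least = self.scores.head(5)
        lines = [
            "Subsystem variation results",
            "=" * 54,
            f"SNP sites: {len(self.model.sites)} total, {len(self.filtered_sites)} in "
            f"[{self.model.low},{self.model.high}]x window ({n_dropped} outside)",
            f"genes: {len(self.profiles)}   subsystems scored: {ss.n_subsystems}",
            f"score mean {ss.mean:.1f}   median {ss.median:.1f}   SD {ss.sd:.1f}",
            "",
            "most variable subsystems:",
            most.to_string(index=False),
            "",
            "most conserved subsystems:",
            least.to_string(index=False),
        ]
        return "\n".join(lines)
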