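"""End-to-end orchestration: simulate -> bin -> qc -> score-variants ->
indicators, driven by a plain-text config, with a provenance manifest.

Stages communicate only through files in the output directory, so each is
independently runnable and a finished run is fully described by its
manifest (inputs, parameters, seed, stage timings and output checksums).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import features as F
from . import indicators as I
from . import quality as Q
from . import simulate as S
from .io import (
    read_bin_assignments,
    read_coverage_table,
    read_marker_hits,
    read_orf_annotations,
    read_scaffolds,
    write_bin_assignments,
    write_bin_fastas,
    write_coverage_table,
    write_scaffolds,
)
from .models import GalaxyBinningModel, SubsystemVariationModel

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "bin", "qc", "score-variants", "indicators")

__all__ = ["RunConfig", "run_pipeline", "ALL_STAGES"]


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    out_dir: str = "galaxybin_run"
    seed: int = 0
    # indicators needs an ORF annotation table the simulator does not make,
    # so it is opt-in
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "bin", "qc", "score-variants"]
    )
    # inputs (filled by the simulate stage when requested)
    scaffolds: str | None = None
    coverage: str | None = None
    markers: str | None = None
    orf_annotations: str | None = None
    assignment: str | None = None
    vcf: str | None = None
    gff: str | None = None
    subsystems: str | None = None
    # binning tunables
    assembly_id: str = "k29"
    min_train_len: int = 5000
    min_class_len: int = 1500
    eps: float = 0.5
    min_samples: int = 5
    gc_weight: float = 1.0
    conf_threshold: float = 0.5
    pseudocount: float = 1.0
    n_components: int = 3
    tune_grid: list | None = None  # list of [eps, min_samples, gc_weight]
    completeness_threshold: float = 0.8
    # variant-scoring tunables
    low: int = 50
    high: int = 200
    edges: list = field(default_factory=lambda: [0.0, 1.0, 2.0, 3.0])
    scale: float = 1000.0
    include_zero: bool = False
    # simulation tunables (defaults are the CommunitySpec/StrainVariantSpec defaults)
    community: dict = field(default_factory=dict)
    strain: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def resolve_paths(self) -> None:
        self.out_dir = str(Path(self.out_dir).absolute())
        for name in ("scaffolds", "coverage", "markers", "orf_annotations",
                     "assignment", "vcf", "gff", "subsystems"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, str(Path(v).absolute()))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _preflight(cfg: RunConfig) -> None:
    """Fail before any stage runs if a requested stage misses its input."""
    bad = set(cfg.stages) - set(ALL_STAGES)
    if bad:
        raise ValueError(f"unknown stage(s): {sorted(bad)}")
    simulated = "simulate" in cfg.stages
    need = {
        "bin": ["scaffolds", "coverage"],
        "qc": ["assignment" if "bin" not in cfg.stages else None, "markers"],
        "score-variants": ["vcf", "gff", "subsystems"],
        "indicators": ["orf_annotations",
                       "assignment" if "bin" not in cfg.stages else None],
    }
    for stage in cfg.stages:
        for inp in need.get(stage, []):
            if inp is None:
                continue
            if simulated and inp in ("scaffolds", "coverage", "markers",
                                     "vcf", "gff", "subsystems"):
                continue  # produced by the simulate stage
            if getattr(cfg, inp) is None:
                raise ValueError(f"stage {stage!r} requires input {inp!r}")


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the requested stages in dependency order and return the
    manifest (also written to out_dir/manifest.json)."""
    cfg.resolve_paths()
    _preflight(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed,
        "stages": [],
        "parameters": {k: v for k, v in cfg.__dict__.items() if k != "stages"},
        "outputs": {},
    }
    order = [s for s in ALL_STAGES if s in cfg.stages]

    scaffolds = None
    marker_hits = None
    orfs = None
    assignment_df = None
    results = None

    for stage in order:
        t0 = time.time()
        logger.info("stage %s starting", stage)
        try:
            if stage == "simulate":
                cspec = S.CommunitySpec(**{"seed": cfg.seed, **cfg.community})
                scaffolds, cov, marker_hits, truth = S.simulate_community(
                    cspec, assembly_id=cfg.assembly_id
                )
                cfg.scaffolds = str(out / "scaffolds.fasta")
                cfg.coverage = str(out / "coverage.tsv")
                cfg.markers = str(out / "markers.tsv")
                write_scaffolds(scaffolds, cfg.scaffolds)
                write_coverage_table(
                    scaffolds, list(cov.columns), cfg.coverage,
                    header_comment=f"seed={cspec.seed}",
                )
                marker_hits.to_csv(cfg.markers, sep="\t", index=False)
                truth.to_frame().to_csv(out / "truth_scaffolds.tsv", sep="\t", index=False)

                sspec = S.StrainVariantSpec(**{"seed": cfg.seed, **cfg.strain})
                sites, genes, smap, struth = S.simulate_strain_variants(sspec)
                cfg.vcf = str(out / "variants.vcf")
                cfg.gff = str(out / "genes.gff3")
                cfg.subsystems = str(out / "subsystems.tsv")
                contig_len = max(g.end for g in genes) + 100
                S.write_variants_vcf(sites, {sspec.contig_id: contig_len}, cfg.vcf, seed=sspec.seed)
                S.write_gene_models_gff(genes, cfg.gff, seed=sspec.seed)
                smap.to_csv(cfg.subsystems, sep="\t", index=False)

            elif stage == "bin":
                if scaffolds is None:
                    scaffolds = read_scaffolds(cfg.scaffolds, cfg.assembly_id)
                    read_coverage_table(cfg.coverage, scaffolds)
                if marker_hits is None and cfg.markers:
                    marker_hits = read_marker_hits(cfg.markers)
                model = GalaxyBinningModel(
                    scaffolds, marker_hits=marker_hits,
                    min_train_len=cfg.min_train_len, min_class_len=cfg.min_class_len,
                    pseudocount=cfg.pseudocount,
                )
                grid = None
                if cfg.tune_grid:
                    grid = [F.GridPoint(*pt) for pt in cfg.tune_grid]
                results = model.fit(
                    eps=cfg.eps, min_samples=cfg.min_samples, gc_weight=cfg.gc_weight,
                    conf_threshold=cfg.conf_threshold, n_components=cfg.n_components,
                    tune_grid=grid, seed=cfg.seed,
                )
                assignment_df = results.assignment.table.assign(assembly_id=cfg.assembly_id)
                cfg.assignment = str(out / "assignments.tsv")
                write_bin_assignments(assignment_df, cfg.assignment)
                results.galaxy_coordinates().to_csv(
                    out / "galaxy_coordinates.tsv", sep="\t", index=False
                )
                write_bin_fastas(assignment_df, scaffolds, out / "bins")

            elif stage == "qc":
                if assignment_df is None:
                    assignment_df = read_bin_assignments(cfg.assignment)
                if marker_hits is None:
                    marker_hits = read_marker_hits(cfg.markers)
                if scaffolds is None:
                    scaffolds = read_scaffolds(cfg.scaffolds, cfg.assembly_id)
                    read_coverage_table(cfg.coverage, scaffolds)
                universe = Q.MarkerUniverse(frozenset(marker_hits["marker_gene_id"]))
                by_id = {s.scaffold_id: s for s in scaffolds}
                qualities, taxonomy = [], {}
                for label, grp in assignment_df.groupby("bin_label"):
                    if not label.startswith("bin:"):
                        continue
                    members = [by_id[sid] for sid in grp["scaffold_id"] if sid in by_id]
                    qualities.append(
                        Q.assess_bin_quality(members, marker_hits, universe, bin_label=label)
                    )
                    ids = set(grp["scaffold_id"])
                    tc = Q.call_majority_phylum(
                        marker_hits[marker_hits["scaffold_id"].isin(ids)]
                    )
                    if cfg.orf_annotations:
                        if orfs is None:
                            orfs = read_orf_annotations(cfg.orf_annotations)
                        part = Q.call_majority_reference_taxon(
                            orfs[orfs["scaffold_id"].isin(ids)]
                        )
                        tc.majority_reference_taxon = part.majority_reference_taxon
                        tc.reference_fraction = part.reference_fraction
                    taxonomy[label] = tc
                qualities.sort(key=lambda q: -q.mean_coverage)
                Q.bin_summary_table(qualities, taxonomy).to_csv(
                    out / "bin_quality.tsv", sep="\t", index=False
                )

            elif stage == "score-variants":
                from .variants import RateClassConfig

                vm = SubsystemVariationModel.from_files(
                    cfg.vcf, cfg.gff, cfg.subsystems,
                    low=cfg.low, high=cfg.high,
                    config=RateClassConfig(
                        edges=tuple(cfg.edges), scale=cfg.scale,
                        include_zero_variant_genes_in_classes=cfg.include_zero,
                    ),
                )
                vres = vm.fit()
                vres.scores.to_csv(out / "subsystem_scores.tsv", sep="\t", index=False)
                vres.gene_table().to_csv(out / "variable_genes.tsv", sep="\t", index=False)
                vres.depth_histogram().to_csv(out / "depth_histogram.tsv", sep="\t", index=False)

            elif stage == "indicators":
                if assignment_df is None:
                    assignment_df = read_bin_assignments(cfg.assignment)
                if orfs is None:
                    orfs = read_orf_annotations(cfg.orf_annotations)
                mat = I.build_presence_matrix(orfs, assignment_df)
                mat.to_csv(out / "indicator_matrix.tsv", sep="\t")

        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append({"name": stage, "seconds": round(time.time() - t0, 3)})

    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(out))] = _sha256(p)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
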