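"""Readers and writers for the external formats the pipeline touches.

All genomic coordinates are 1-based inclusive, matching both GFF3 and VCF,
so no conversion happens at module boundaries. Sequences are stored
uppercase. Coverage tables are TSV with a ``scaffold_id`` column followed
by one column per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "ScaffoldRecord",
    "VariantSite",
    "GeneModel",
    "read_scaffolds",
    "write_scaffolds",
    "read_coverage_table",
    "write_coverage_table",
    "read_marker_hits",
    "read_orf_annotations",
    "read_subsystem_map",
    "read_variant_sites",
    "read_gene_models",
    "read_bin_assignments",
    "write_bin_assignments",
    "write_bin_fastas",
]


@dataclass
class ScaffoldRecord:
    """One assembled scaffold with its binning features.

    ``coverage`` holds one mean read depth per sample; ``gc`` is the G+C
    fraction of unambiguous bases and is ``None`` until computed.
    """

    scaffold_id: str
    assembly_id: str
    sequence: str
    length_bp: int = 0
    coverage: np.ndarray | None = None
    gc: float | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"scaffold {self.scaffold_id!r} has an empty sequence")
        if self.length_bp == 0:
            self.length_bp = len(self.sequence)
        if self.length_bp != len(self.sequence):
            raise ValueError(
                f"scaffold {self.scaffold_id!r}: declared length {self.length_bp} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass
class VariantSite:
    """A single-nucleotide substitution call against a reference contig."""

    contig_id: str
    position: int  # 1-based
    variant_class: str = "snp"
    depth: int = 0
    gene_id: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position is 1-based and must be >= 1")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


@dataclass
class GeneModel:
    """A gene/CDS feature with 1-based inclusive coordinates."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    product: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(
                f"gene {self.gene_id!r}: end {self.end} < start {self.start}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start + 1


def read_scaffolds(path: str | Path, assembly_id: str) -> list[ScaffoldRecord]:
    """Read scaffolds from FASTA; IDs must be unique within the file."""
    records: list[ScaffoldRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate scaffold ID {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ScaffoldRecord(rec.id, assembly_id, str(rec.seq)))
    return records


def write_scaffolds(scaffolds: list[ScaffoldRecord], path: str | Path) -> None:
    seqs = [
        SeqRecord(Seq(s.sequence), id=s.scaffold_id, description="")
        for s in scaffolds
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_coverage_table(
    path: str | Path, scaffolds: list[ScaffoldRecord] | None = None
) -> pd.DataFrame:
    """Read the per-sample coverage TSV and optionally attach to scaffolds.

    A scaffold absent from the table gets zero coverage with a warning.
    Returns the table indexed by scaffold_id (columns = sample names).
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.columns[0] != "scaffold_id":
        raise ValueError(f"coverage table must start with a 'scaffold_id' column, got {df.columns[0]!r}")
    df = df.set_index("scaffold_id")
    if df.isna().any().any():
        raise ValueError("coverage table contains missing values")
    if scaffolds is not None:
        n_samples = df.shape[1]
        missing = 0
        for s in scaffolds:
            if s.scaffold_id in df.index:
                s.coverage = df.loc[s.scaffold_id].to_numpy(dtype=float)
            else:
                s.coverage = np.zeros(n_samples)
                missing += 1
        if missing:
            logger.warning(
                "%d scaffold(s) absent from coverage table; coverage set to 0", missing
            )
    return df


def write_coverage_table(
    scaffolds: list[ScaffoldRecord], sample_names: list[str], path: str | Path,
    header_comment: str | None = None,
) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"#{header_comment}\n")
        fh.write("scaffold_id\t" + "\t".join(sample_names) + "\n")
        for s in scaffolds:
            cov = "\t".join(f"{c:.4f}" for c in s.coverage)
            fh.write(f"{s.scaffold_id}\t{cov}\n")


def read_marker_hits(path: str | Path) -> pd.DataFrame:
    """Marker-gene hit table: scaffold_id, marker_gene_id, taxon_label."""
    df = pd.read_csv(
        path, sep="\t", comment="#",
        dtype={"scaffold_id": str, "marker_gene_id": str, "taxon_label": str},
    )
    required = {"scaffold_id", "marker_gene_id", "taxon_label"}
    if not required.issubset(df.columns):
        raise ValueError(f"marker hit table needs columns {sorted(required)}")
    return df


def read_orf_annotations(path: str | Path) -> pd.DataFrame:
    """ORF annotation table: scaffold_id, orf_id, nearest_genome_label, product."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    required = {"scaffold_id", "orf_id", "nearest_genome_label", "product"}
    if not required.issubset(df.columns):
        raise ValueError(f"ORF annotation table needs columns {sorted(required)}")
    return df


def read_subsystem_map(path: str | Path) -> pd.DataFrame:
    """Gene-to-subsystem membership map (many-to-many, deduplicated)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = {"gene_id", "subsystem_id"}
    if not required.issubset(df.columns):
        raise ValueError(f"subsystem map needs columns {sorted(required)}")
    return df.drop_duplicates(subset=["gene_id", "subsystem_id"]).reset_index(drop=True)


def _is_snp(ref: str, alts: tuple[str, ...]) -> bool:
    # single-base substitution: REF and every ALT of length 1, ALT != REF
    if len(ref) != 1 or not alts:
        return False
    return all(len(a) == 1 and a != ref and a in "ACGTacgt" for a in alts)


def read_variant_sites(path: str | Path) -> list[VariantSite]:
    """Read a VCF, retaining only SNP sites (the most common variant class).

    Indels, MNPs and complex alleles are dropped. A multi-allelic SNP site
    counts as one site. Depth comes from site-level INFO/DP when present,
    otherwise the sum of per-sample depths; sites with no depth at all are
    dropped with a warning tally.
    """
    sites: list[VariantSite] = []
    n_dropped_class = 0
    n_dropped_depth = 0
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            alts = tuple(a for a in (rec.alts or ()) if a is not None)
            if not _is_snp(rec.ref or "", alts):
                n_dropped_class += 1
                continue
            depth = rec.info.get("DP")
            if depth is None:
                per_sample = [
                    s.get("DP") for s in rec.samples.values() if s.get("DP") is not None
                ]
                depth = sum(per_sample) if per_sample else None
            if depth is None:
                n_dropped_depth += 1
                continue
            sites.append(VariantSite(rec.chrom, rec.pos, "snp", int(depth)))
    if n_dropped_class:
        logger.info("dropped %d non-SNP variant record(s)", n_dropped_class)
    if n_dropped_depth:
        logger.warning("dropped %d SNP site(s) lacking depth", n_dropped_depth)
    return sites


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Read gene/CDS features from GFF3 as 1-based inclusive gene models."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "CDS"):
            continue
        gene_id = feat.attributes.get("ID", [None])[0] or feat.attributes.get(
            "locus_tag", [None]
        )[0]
        if gene_id is None:
            raise ValueError(
                f"feature at {feat.seqid}:{feat.start}-{feat.end} has no ID"
            )
        product = feat.attributes.get("product", [""])[0]
        genes.append(
            GeneModel(gene_id, feat.seqid, feat.start, feat.end, feat.strand or "+", product)
        )
    return genes


_ASSIGNMENT_COLS = ["scaffold_id", "assembly_id", "bin_label", "provenance", "confidence"]


def write_bin_assignments(assignments: pd.DataFrame, path: str | Path) -> None:
    assignments.to_csv(path, sep="\t", index=False, columns=_ASSIGNMENT_COLS)


def read_bin_assignments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"scaffold_id": str})
    if list(df.columns) != _ASSIGNMENT_COLS:
        raise ValueError(f"assignment table needs columns {_ASSIGNMENT_COLS}")
    return df


def write_bin_fastas(
    assignments: pd.DataFrame, scaffolds: list[ScaffoldRecord], out_dir: str | Path
) -> list[Path]:
    """Write one FASTA per bin label (bin:k, background, unbinned)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = {s.scaffold_id: s for s in scaffolds}
    written = []
    for label, group in assignments.groupby("bin_label"):
        safe = label.replace(":", "_")
        path = out_dir / f"{safe}.fasta"
        members = [by_id[sid] for sid in group["scaffold_id"] if sid in by_id]
        write_scaffolds(members, path)
        written.append(path)
    return written
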