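"""Biogeochemical indicator-gene presence/absence matrices across bins.

Indicator genes for sulfur, nitrogen and carbon cycling (and for
carbohydrate metabolism) are detected by case-insensitive substring search
of their catalog terms against ORF product strings, accumulated per bin.
Bins outside the supplied major set are pooled into a ``minor_bins`` row;
``background`` and ``unbinned`` scaffolds get their own aggregate rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "IndicatorEntry",
    "IndicatorCatalog",
    "BIOGEOCHEMICAL_CATALOG",
    "CARBOHYDRATE_CATALOG",
    "build_presence_matrix",
]


@dataclass(frozen=True)
class IndicatorEntry:
    code: str
    full_name: str
    search_terms: tuple[str, ...]

    def __post_init__(self):
        if not self.search_terms:
            raise ValueError(f"indicator {self.code} has no search terms")


@dataclass
class IndicatorCatalog:
    entries: list[IndicatorEntry]

    def __post_init__(self):
        if not self.entries:
            raise ValueError("empty indicator catalog")
        codes = [e.code for e in self.entries]
        if len(set(codes)) != len(codes):
            raise ValueError("duplicate indicator codes")

    @property
    def codes(self) -> list[str]:
        return [e.code for e in self.entries]

    @classmethod
    def from_tsv(cls, path) -> "IndicatorCatalog":
        """Catalog TSV: code, full_name, search_terms (';'-separated)."""
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        entries = [
            IndicatorEntry(r["code"], r.get("full_name", ""), tuple(r["search_terms"].split(";")))
            for _, r in df.iterrows()
        ]
        return cls(entries)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            [{"code": e.code, "full_name": e.full_name,
              "search_terms": ";".join(e.search_terms)} for e in self.entries]
        ).to_csv(path, sep="\t", index=False)


def _E(code, name, *terms):
    return IndicatorEntry(code, name, terms)


# Energy/element-cycling indicator genes (sulfur, nitrogen, phototrophy,
# carbon fixation and respiration), keyed by the conventional abbreviations.
BIOGEOCHEMICAL_CATALOG = IndicatorCatalog([
    _E("DSR", "dissimilatory sulfite reductase", "dissimilatory sulfite reductase"),
    _E("APR", "adenylylsulfate reductase", "adenylylsulfate reductase", "adenylyl-sulfate reductase"),
    _E("SOX", "sulfite oxidase", "sulfite oxidase", "sulfur oxidation protein sox"),
    _E("MVH", "methyl viologen-reducing hydrogenase", "methyl viologen-reducing hydrogenase"),
    _E("NIF", "nitrogenase", "nitrogenase"),
    _E("NAR", "nitrate reductase", "nitrate reductase"),
    _E("NOS", "nitrous-oxide reductase", "nitrous-oxide reductase", "nitrous oxide reductase"),
    _E("PSA", "photosystem I P700 apoprotein", "photosystem i p700"),
    _E("PSB", "photosystem II D1/D2", "photosystem ii protein d1", "photosystem ii protein d2"),
    _E("PUF", "photosynthetic reaction center", "photosynthetic reaction center"),
    _E("PSC", "photosystem P840 reaction center", "p840 reaction center"),
    _E("CHL", "chlorophyll synthase", "chlorophyll synthase", "bacteriochlorophyll a synthase"),
    _E("BCH", "bacteriochlorophyll c synthase", "bacteriochlorophyll c synthase"),
    _E("RBC", "ribulose bisphosphate carboxylase", "ribulose bisphosphate carboxylase", "ribulose-bisphosphate carboxylase"),
    _E("CAH", "carbonic anhydrase", "carbonic anhydrase"),
    _E("CCM", "carboxysome microcompartment protein", "carboxysome"),
    _E("APCC", "acetyl/propionyl-CoA carboxylase", "acetyl-coa carboxylase", "propionyl-coa carboxylase"),
    _E("COO", "carbon monoxide dehydrogenase", "carbon monoxide dehydrogenase"),
    _E("CCON", "cytochrome c oxidase", "cytochrome c oxidase"),
    _E("KOR", "2-oxoglutarate synthase", "2-oxoglutarate synthase", "2-oxoglutarate ferredoxin oxidoreductase"),
    _E("ENO", "enolase / phosphopyruvate hydratase", "enolase", "phosphopyruvate hydratase"),
    _E("PYK", "pyruvate kinase", "pyruvate kinase"),
    _E("PGD", "6-phosphogluconate dehydrogenase", "6-phosphogluconate dehydrogenase", "6-phosphoglucanate dehydrogenase"),
    _E("MCR", "methyl-coenzyme M reductase", "methyl-coenzyme m reductase"),
])

# Carbohydrate production/breakdown indicator genes (cellulose, starch,
# trehalose, maltose cycling).
CARBOHYDRATE_CATALOG = IndicatorCatalog([
    _E("BCS", "cellulose synthase", "cellulose synthase"),
    _E("PGM", "phosphoglucomutase", "phosphoglucomutase"),
    _E("PMM-PGM", "phosphomannomutase/phosphoglucomutase", "phosphomannomutase"),
    _E("UGP", "UTP--glucose-1-phosphate uridylyltransferase", "glucose-1-phosphate uridylyltransferase"),
    _E("CEL", "cellulase / endoglucanase", "cellulase", "endoglucanase"),
    _E("CELM", "cellulase M", "cellulase m"),
    _E("CBH", "cellulose 1,4-beta-cellobiosidase", "cellobiosidase"),
    _E("BGL", "beta-glucosidase", "beta-glucosidase"),
    _E("GH", "glycosyl hydrolase", "glycosyl hydrolase", "glycoside hydrolase"),
    _E("GLGC", "glucose-1-phosphate adenylyltransferase", "glucose-1-phosphate adenylyltransferase"),
    _E("GLGA", "glycogen synthase", "glycogen synthase"),
    _E("GLGB", "1,4-alpha-glucan branching enzyme", "glucan branching enzyme"),
    _E("PYG", "glycogen phosphorylase", "glycogen phosphorylase"),
    _E("TREX", "glycogen operon protein", "glycogen operon protein"),
    _E("TREY", "maltooligosyltrehalose synthase", "maltooligosyltrehalose synthase"),
    _E("TREZ", "maltooligosyltrehalose trehalohydrolase", "trehalohydrolase"),
    _E("TRES", "trehalose synthase", "trehalose synthase"),
    _E("AGL", "glycogen debranching enzyme", "debranching enzyme"),
    _E("MAL", "4-alpha-glucanotransferase", "4-alpha-glucanotransferase"),
    _E("MGAM", "maltase-glucoamylase", "maltase", "glucoamylase"),
    _E("GAA", "alpha-glucosidase", "alpha-glucosidase"),
])

AGGREGATE_ROWS = ("minor_bins", "background", "unbinned")


def build_presence_matrix(
    orf_annotations: pd.DataFrame,
    assignments: pd.DataFrame,
    catalog: IndicatorCatalog = BIOGEOCHEMICAL_CATALOG,
    major_bins: list[str] | None = None,
    counts: bool = False,
) -> pd.DataFrame:
    """Indicator presence/absence (or hit counts) per bin.

    ``orf_annotations`` needs scaffold_id and product columns;
    ``assignments`` maps scaffold_id to bin_label. Rows are the major bins
    plus three aggregates (minor_bins, background, unbinned); columns the
    catalog codes. With ``counts=False`` cells are 0/1 presence.
    """
    if not catalog.entries:
        raise ValueError("empty indicator catalog")
    label_of = assignments.set_index("scaffold_id")["bin_label"]
    ann = orf_annotations.copy()
    ann["bin_label"] = ann["scaffold_id"].map(label_of).fillna("unbinned")
    bin_labels = sorted(
        {b for b in assignments["bin_label"] if b.startswith("bin:")},
        key=lambda b: int(b.split(":")[1]),
    )
    if major_bins is None:
        major_bins = bin_labels

    def row_of(label: str) -> str:
        if label in major_bins:
            return label
        if label in ("background", "unbinned"):
            return label
        return "minor_bins"

    ann["row"] = ann["bin_label"].map(row_of)
    rows = list(major_bins) + list(AGGREGATE_ROWS)
    mat = pd.DataFrame(0, index=rows, columns=catalog.codes, dtype=int)
    products = ann["product"].str.lower().fillna("")
    for entry in catalog.entries:
        hit = pd.Series(False, index=ann.index)
        for term in entry.search_terms:
            hit |= products.str.contains(term.lower(), regex=False)
        hits_per_row = ann.loc[hit, "row"].value_counts()
        for r, c in hits_per_row.items():
            if r in mat.index:
                mat.loc[r, entry.code] += int(c)
    if not counts:
        mat = (mat >= 1).astype(int)
    mat.index.name = "bin"
    return mat
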