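import numpy as np
import pandas as pd
import pytest

from galaxybin import (
    CommunitySpec,
    StrainVariantSpec,
    simulate_community,
    simulate_strain_variants,
)
from galaxybin.io import GeneModel, ScaffoldRecord, VariantSite


@pytest.fixture(scope="session")
def community():
    """A seeded 8-genome, 4-sample community with ground truth."""
    spec = CommunitySpec(seed=1)
    scaffolds, coverage, marker_hits, truth = simulate_community(spec)
    return {
        "spec": spec,
        "scaffolds": scaffolds,
        "coverage": coverage,
        "marker_hits": marker_hits,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def strain_run():
    """A seeded two-strain SNP mixture with 3 enriched subsystems of 30."""
    spec = StrainVariantSpec(
        seed=0, enriched_subsystems=frozenset({"SS_05", "SS_12", "SS_21"})
    )
    sites, genes, smap, truth = simulate_strain_variants(spec)
    return {"spec": spec, "sites": sites, "genes": genes,
            "subsystem_map": smap, "truth": truth}


@pytest.fixture
def toy_scaffolds():
    """Three tiny scaffolds with coverage, for bin QC arithmetic."""
    rng = np.random.default_rng(0)
    out = []
    for i, (ln, cov) in enumerate([(6000, 10.0), (3000, 12.0), (1200, 8.0)]):
        seq = "".join(rng.choice(list("ACGT"), ln))
        out.append(
            ScaffoldRecord(f"s{i+1}", "a1", seq, coverage=np.full(2, cov))
        )
    return out


def make_profiles(counts_lengths):
    """GeneVariantProfile list from (gene_id, variant_count, length) triples."""
    from galaxybin.variants import GeneVariantProfile

    return [
        GeneVariantProfile(gene_id=g, length_bp=ln, variant_count=c)
        for g, c, ln in counts_lengths
    ]
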