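"""Feature construction, projection, DBSCAN seeding and SVM propagation."""

import numpy as np
import pytest

from galaxybin.features import (
    NOISE,
    GridPoint,
    build_feature_matrix,
    cluster_training_scaffolds,
    compute_gc,
    project_top_components,
    propagate_bin_labels,
    tune_clustering,
)
from galaxybin.io import ScaffoldRecord


class TestComputeGc:
    @pytest.mark.parametrize("seq,expected", [
        ("ATGC", 0.5),
        ("GGCC", 1.0),
        ("ATATNNGC", 1 / 3),  # N excluded from the denominator
        ("atgc", 0.5),
    ])
    def test_values(self, seq, expected):
        assert compute_gc(seq) == pytest.approx(expected)

    @pytest.mark.parametrize("seq", ["", "NNNN"])
    def test_degenerate_rejected(self, seq):
        with pytest.raises(ValueError):
            compute_gc(seq)


def _scaffolds_from_matrix(cov, gcs=None, length=6000):
    """ScaffoldRecords with given coverage rows (and optional GC targets)."""
    rng = np.random.default_rng(0)
    out = []
    for i, row in enumerate(cov):
        gc = 0.5 if gcs is None else gcs[i]
        n_gc = int(round(gc * length))
        seq = "G" * n_gc + "A" * (length - n_gc)
        out.append(ScaffoldRecord(f"s{i}", "a", seq, coverage=np.asarray(row, float)))
    return out


class TestFeatureMatrix:
    def test_log_pseudocount_values(self):
        # cov 0 -> log10(1)=0; cov 99 -> log10(100)=2 before scaling
        scafs = _scaffolds_from_matrix([[0.0], [99.0], [9.0]])
        fm = build_feature_matrix(scafs, min_len=1000)
        raw = fm.features[:, 0] * fm.spread[0] + fm.center[0]
        assert raw == pytest.approx([0.0, 2.0, 1.0])

    def test_columns_standardised(self, community):
        fm = build_feature_matrix(community["scaffolds"], min_len=1500)
        assert np.allclose(fm.features.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(fm.features.std(axis=0), 1, atol=1e-9)

    def test_gc_weight_scales_gc_column(self, community):
        fm1 = build_feature_matrix(community["scaffolds"], min_len=1500, gc_weight=1.0)
        fm2 = build_feature_matrix(community["scaffolds"], min_len=1500, gc_weight=3.0)
        assert np.allclose(fm2.features[:, -1], 3.0 * fm1.features[:, -1])
        assert np.allclose(fm2.features[:, :-1], fm1.features[:, :-1])

    def test_zero_variance_column_spread_one(self):
        scafs = _scaffolds_from_matrix([[5.0, 1.0], [5.0, 2.0], [5.0, 9.0]])
        fm = build_feature_matrix(scafs, min_len=1000)
        assert np.all(np.isfinite(fm.features))

    def test_length_gate(self, community):
        fm = build_feature_matrix(community["scaffolds"], min_len=5000)
        lengths = {s.scaffold_id: s.length_bp for s in community["scaffolds"]}
        assert all(lengths[sid] > 5000 for sid in fm.scaffold_ids)


class TestProjection:
    def test_rank_one_data(self):
        t = np.linspace(0, 1, 30)
        # coverages chosen so log10(cov + 1) is exactly collinear
        scafs = _scaffolds_from_matrix(
            np.column_stack([10 ** t - 1, 10 ** (2 * t) - 1, 10 ** (0.5 * t) - 1])
        )
        fm = build_feature_matrix(scafs, min_len=1000)
        fm.features[:, -1] = fm.features[:, 0]  # force GC collinear too
        proj = project_top_components(fm, k=3)
        assert proj.explained_variance[1] == pytest.approx(0, abs=1e-9)
        assert proj.explained_variance[2] == pytest.approx(0, abs=1e-9)

    def test_full_dimension_preserves_variance(self, community):
        fm = build_feature_matrix(community["scaffolds"], min_len=1500)
        k = fm.features.shape[1]
        proj = project_top_components(fm, k=k)
        # population-variance bookkeeping: PCA uses n-1 normalisation
        total = fm.features.var(axis=0, ddof=1).sum()
        assert proj.explained_variance.sum() == pytest.approx(total, abs=1e-8)
        assert np.all(np.diff(proj.explained_variance) <= 1e-12)

    def test_components_orthonormal(self, community):
        fm = build_feature_matrix(community["scaffolds"], min_len=1500)
        proj = project_top_components(fm, k=3)
        gram = proj.components @ proj.components.T
        assert np.allclose(gram, np.eye(3), atol=1e-8)

    def test_duplicated_rows_identical_coordinates(self):
        cov = [[10.0, 5.0]] * 2 + [[100.0, 80.0], [3.0, 2.0]]
        scafs = _scaffolds_from_matrix(cov, gcs=[0.4, 0.4, 0.6, 0.5])
        fm = build_feature_matrix(scafs, min_len=1000)
        proj = project_top_components(fm, k=2)
        assert np.allclose(proj.projected[0], proj.projected[1])

    def test_k_too_large_rejected(self, community):
        fm = build_feature_matrix(community["scaffolds"], min_len=1500)
        with pytest.raises(ValueError):
            project_top_components(fm, k=fm.features.shape[1] + 1)


def _two_cloud_projection(n=20, sep=10.0, seed=0, lengths=None):
    rng = np.random.default_rng(seed)
    pts = np.vstack([
        rng.normal(0, 0.1, (n, 3)),
        rng.normal(sep, 0.1, (n, 3)),
    ])
    from galaxybin.features import Projection
    ids = [f"s{i}" for i in range(2 * n)]
    if lengths is None:
        lengths = np.full(2 * n, 8000)
    return Projection(
        scaffold_ids=ids, lengths=np.asarray(lengths),
        components=np.eye(3), explained_variance=np.array([3.0, 2.0, 1.0]),
        projected=pts, fit_min_len=5000,
    )


class TestDbscan:
    def test_two_separated_clouds_two_clusters(self):
        proj = _two_cloud_projection()
        cl = cluster_training_scaffolds(proj, eps=0.5, min_samples=4)
        assert cl.n_clusters == 2
        assert cl.n_noise == 0

    def test_isolated_point_is_noise(self):
        proj = _two_cloud_projection()
        proj.projected[0] = [100.0, 100.0, 100.0]
        cl = cluster_training_scaffolds(proj, eps=0.5, min_samples=4)
        assert cl.labels["s0"] == NOISE

    def test_deterministic(self):
        proj = _two_cloud_projection()
        a = cluster_training_scaffolds(proj, eps=0.5, min_samples=4)
        b = cluster_training_scaffolds(proj, eps=0.5, min_samples=4)
        assert a.labels == b.labels

    def test_labels_numbered_by_descending_size(self):
        proj = _two_cloud_projection()
        # shrink cloud 1 to make cloud 2 the larger
        proj.projected = np.vstack([proj.projected[:5], proj.projected[20:]])
        proj.scaffold_ids = proj.scaffold_ids[:5] + proj.scaffold_ids[20:]
        proj.lengths = np.concatenate([proj.lengths[:5], proj.lengths[20:]])
        cl = cluster_training_scaffolds(proj, eps=0.5, min_samples=4)
        sizes = {lab: sum(1 for v in cl.labels.values() if v == lab)
                 for lab in {1, 2}}
        assert sizes[1] >= sizes[2]

    def test_eps_must_be_positive(self):
        proj = _two_cloud_projection()
        with pytest.raises(ValueError):
            cluster_training_scaffolds(proj, eps=0.0, min_samples=4)


class TestPropagation:
    def test_trained_scaffolds_keep_cluster_label(self):
        proj = _two_cloud_projection()
        cl = cluster_training_scaffolds(proj, eps=0.5, min_samples=4)
        assignment = propagate_bin_labels(cl, proj)
        t = assignment.table.set_index("scaffold_id")
        for sid, lab in cl.labels.items():
            if lab != NOISE:
                assert t.loc[sid, "bin_label"] == f"bin:{lab}"
                assert t.loc[sid, "provenance"] == "trained"

    def test_long_noise_scaffold_goes_to_background(self):
        proj = _two_cloud_projection()
        proj.projected[0] = [100.0, 100.0, 100.0]  # 8 kbp outlier
        cl = cluster_training_scaffolds(proj, eps=0.5, min_samples=4)
        assignment = propagate_bin_labels(cl, proj)
        row = assignment.table.set_index("scaffold_id").loc["s0"]
        assert row["bin_label"] == "background"

    def test_short_scaffolds_propagated(self):
        lengths = np.full(40, 8000)
        lengths[5] = 3000  # below training gate, above classification gate
        proj = _two_cloud_projection(lengths=lengths)
        cl = cluster_training_scaffolds(proj, eps=0.5, min_samples=4)
        assignment = propagate_bin_labels(cl, proj)
        row = assignment.table.set_index("scaffold_id").loc["s5"]
        assert row["provenance"] == "propagated"
        assert row["bin_label"] == "bin:" + str(cl.labels["s0"])

    def test_raising_threshold_never_unbins_fewer(self):
        rng = np.random.default_rng(3)
        lengths = np.full(40, 8000)
        lengths[rng.choice(40, 15, replace=False)] = 3000
        proj = _two_cloud_projection(sep=1.2, lengths=lengths)
        cl = cluster_training_scaffolds(proj, eps=0.6, min_samples=4)
        prev = -1
        for thr in (0.2, 0.5, 0.8, 0.95):
            a = propagate_bin_labels(cl, proj, conf_threshold=thr)
            n_unbinned = int((a.table["bin_label"] == "unbinned").sum())
            assert n_unbinned >= prev
            prev = n_unbinned


class TestTuning:
    def test_single_point_grid_returned(self, community):
        grid = [GridPoint(0.4, 5, 1.0)]
        res = tune_clustering(
            grid, community["scaffolds"], community["marker_hits"], None
        )
        assert res.best == grid[0]

    def test_tie_breaks_toward_smaller_eps(self, community):
        # duplicate point except eps: identical clustering at both radii
        grid = [GridPoint(0.45, 5, 1.0), GridPoint(0.4, 5, 1.0)]
        res = tune_clustering(
            grid, community["scaffolds"], community["marker_hits"], None
        )
        tbl = res.table
        if tbl["objective"].nunique() == 1 and tbl["n_noise"].nunique() == 1:
            assert res.best.eps == 0.4

    def test_recovers_five_genome_community(self):
        from galaxybin import CommunitySpec, simulate_community
        from galaxybin.quality import MarkerUniverse, assess_bin_quality

        spec = CommunitySpec(n_genomes=5, seed=7)
        scaffolds, _, hits, truth = simulate_community(spec)
        universe = MarkerUniverse(frozenset(hits["marker_gene_id"]))
        grid = [GridPoint(e, 5, w) for e in (0.3, 0.5) for w in (1.0, 2.0)]
        res = tune_clustering(grid, scaffolds, hits, universe)
        assignment = res.best_assignment
        assert len(assignment.bin_labels) == 5
        by_id = {s.scaffold_id: s for s in scaffolds}
        for lab in assignment.bin_labels:
            members = [by_id[sid] for sid in assignment.members(lab)]
            q = assess_bin_quality(members, hits, universe, bin_label=lab)
            assert q.completeness >= 0.9
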