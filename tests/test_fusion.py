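import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import cellfuse as cf
from cellfuse.fusion import (
    ImputationParams,
    SmoothingParams,
    impute_cross_modality,
    impute_knn_anchor,
    iterative_fusion,
    jaccard_graph,
    joint_reduce,
    leiden_cluster,
    louvain_cluster,
    markov_matrix,
    restricted_k_partners,
    select_anchors,
    smooth_within_modality,
    spearman_distance,
)
from cellfuse.qcnorm import NormalizedMatrix


def _feature_matrix(values, gene_ids=None, modality="rna_cell"):
    values = np.asarray(values, dtype=float)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[1])]
    return NormalizedMatrix(
        values=values,
        transform="log10_cpm1",
        modality=modality,
        gene_ids=pd.Index(gene_ids),
        cell_ids=pd.Index([f"c{i}" for i in range(values.shape[0])]),
        scale_factors=np.ones(values.shape[0]),
    )


class TestSmoothing:
    def test_p_zero_is_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(40, 8))
        out = smooth_within_modality(x, SmoothingParams(k=5, ka=2, p=0.0))
        assert np.allclose(out, x)

    def test_two_mutual_neighbors_move_toward_average(self):
        """Hand computation: with p=1 and two isolated mutual neighbors,
        M rows put equal weight on self and partner, so both rows become the
        pair average."""
        # two tight cells far from a large background cloud
        rng = np.random.default_rng(1)
        bg = rng.normal(100.0, 0.1, size=(10, 2))
        x = np.vstack([[0.0, 0.0], [1.0, 0.0], bg])
        m = markov_matrix(x, k=1, ka=1, ndim=2).toarray()
        # cell 0's only neighbor is cell 1 (distance 1) and vice versa;
        # sigma = that distance, so weight = exp(-1), self-weight = 1
        w = np.exp(-1.0)
        expect = np.array([1.0 / (1 + w), w / (1 + w)])
        assert np.allclose(m[0, [0, 1]], expect)
        assert np.allclose(m[1, [1, 0]], expect)

    def test_duplicated_cells_stay_identical(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 6))
        x[13] = x[4]
        out = smooth_within_modality(x, SmoothingParams(k=5, ka=2, p=0.7))
        assert np.allclose(out[13], out[4])

    def test_convex_combination_bounds(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(50, 5))
        out = smooth_within_modality(x, SmoothingParams(k=10, ka=3, p=1.0))
        assert (out.min(axis=0) >= x.min(axis=0) - 1e-9).all()
        assert (out.max(axis=0) <= x.max(axis=0) + 1e-9).all()

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            markov_matrix(np.zeros((5, 2)), k=5, ka=2)


class TestSpearmanDistance:
    def test_perfect_anticorrelation_flipped_is_zero(self):
        q = np.array([[1.0, 2.0, 3.0, 4.0]])
        r = np.array([[4.0, 3.0, 2.0, 1.0]])
        d = spearman_distance(q, r, flip=True)
        assert d[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert spearman_distance(q, r, flip=False)[0, 0] == pytest.approx(2.0)

    def test_matches_scipy(self):
        from scipy.stats import spearmanr

        rng = np.random.default_rng(0)
        q = rng.normal(size=(3, 20))
        r = rng.normal(size=(4, 20))
        d = spearman_distance(q, r)
        for i in range(3):
            for j in range(4):
                rho = spearmanr(q[i], r[j]).statistic
                assert d[i, j] == pytest.approx(1.0 - rho, abs=1e-12)


class TestRestrictedKPartners:
    def test_identity_when_query_equals_reference(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 10))
        ref = _feature_matrix(x)
        query = _feature_matrix(x)
        out = impute_cross_modality(ref, query, list(ref.gene_ids),
                                    ImputationParams(k=1, z=1000), flip=False)
        assert np.allclose(out, x)

    def test_quota_contention_resolved_by_distance(self):
        """Brute-force 3-cell instance: two queries compete for one
        reference; the closer query wins, the other takes its next-best."""
        dist = np.array([[0.1, 0.5], [0.2, 0.4]])
        partners = restricted_k_partners(dist, k=1, z=1)
        # quota = 1 * ceil(1*2/2) = 1 per reference cell
        assert partners[0, 0] == 0  # pair (0,0) has the smallest distance
        assert partners[1, 0] == 1  # reference 0 is used up

    def test_usage_quota_never_exceeded(self):
        rng = np.random.default_rng(1)
        dist = rng.random((40, 15))
        k, z = 4, 2
        partners = restricted_k_partners(dist, k=k, z=z)
        quota = z * int(np.ceil(k * 40 / 15))
        usage = np.bincount(partners.ravel(), minlength=15)
        assert (usage <= quota).all()
        assert partners.shape == (40, k)
        assert (partners >= 0).all()
        for row in partners:
            assert len(set(row)) == k  # distinct partners per query

    def test_k_larger_than_reference_rejected(self):
        with pytest.raises(ValueError):
            restricted_k_partners(np.ones((3, 2)), k=3, z=1)

    def test_imputed_is_partner_mean(self):
        ref = _feature_matrix(np.array([[0.0, 0.0], [2.0, 4.0], [10.0, 20.0]]))
        query = _feature_matrix(np.array([[0.5, 1.0]]))
        out = impute_cross_modality(ref, query, list(ref.gene_ids),
                                    ImputationParams(k=2, z=100), flip=False)
        # the two nearest-by-rank partners are averaged
        assert out.shape == (1, 2)
        cand = [np.array([1.0, 2.0]), np.array([5.0, 10.0]), np.array([6.0, 12.0])]
        assert any(np.allclose(out[0], c) for c in cand)


class TestJointReduce:
    def test_rank_two_input(self):
        rng = np.random.default_rng(0)
        basis = rng.normal(size=(2, 10))
        coefs = rng.normal(size=(50, 2))
        x = coefs @ basis
        with pytest.warns(UserWarning):
            pcs = joint_reduce(x, n_pcs=50)
        var = pcs.var(axis=0)
        assert (var[:2] > 1e-8).all() and (var[2:] < 1e-12).all()

    def test_planted_depth_pc_removed(self):
        rng = np.random.default_rng(1)
        lg = rng.normal(size=200)
        x = rng.normal(size=(200, 20)) * 0.01
        x[:, 0] = lg * 10  # dominant PC equal to log2(Ngenes)
        pcs_all = joint_reduce(x, n_pcs=5, ngene_corr_max=1.0, log2_ngenes=lg)
        pcs_filt = joint_reduce(x, n_pcs=5, ngene_corr_max=0.6, log2_ngenes=lg)
        assert pcs_filt.shape[1] < pcs_all.shape[1]
        for j in range(pcs_filt.shape[1]):
            assert abs(np.corrcoef(pcs_filt[:, j], lg)[0, 1]) <= 0.6 + 1e-9


class TestLeiden:
    @staticmethod
    def _blobs(seed=0, n=120, sep=50.0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0, 1, size=(n, 5))
        b = rng.normal(sep, 1, size=(n, 5))
        return np.vstack([a, b])

    def test_two_blobs_two_clusters(self):
        x = self._blobs()
        labels = leiden_cluster(x, k=15, resolution=0.1, seed=0)
        truth = np.repeat([0, 1], 120)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_disconnected_components_never_merge(self):
        x = self._blobs(sep=1e6)
        labels = leiden_cluster(x, k=10, resolution=0.001, seed=0)
        assert len(np.unique(labels)) >= 2

    def test_seed_determinism(self):
        x = self._blobs(seed=3)
        a = leiden_cluster(x, k=15, resolution=1.0, seed=7)
        b = leiden_cluster(x, k=15, resolution=1.0, seed=7)
        assert np.array_equal(a, b)


class TestAnchors:
    def test_cap_formula(self):
        # 10 clusters -> cap = max(100, 500) = 500
        labels = np.repeat(np.arange(10), 600)
        idx = select_anchors(labels, seed=0)
        counts = np.bincount(labels[idx])
        assert (counts == 500).all()
        # 100 clusters -> cap = max(100, 50) = 100
        labels = np.repeat(np.arange(100), 150)
        counts = np.bincount(labels[select_anchors(labels, seed=0)])
        assert (counts == 100).all()

    def test_undersized_cluster_kept_whole(self):
        labels = np.array(["a"] * 30 + ["b"] * 700)
        idx = select_anchors(labels, seed=1)
        assert (labels[idx] == "a").sum() == 30


class TestJaccardBackend:
    def test_jaccard_weights_and_louvain(self, atlas8):
        specs = [
            cf.DatasetSpec("rna_cell", platform="10x", n_cells=200, depth=8000,
                           seed=31, name="a"),
            cf.DatasetSpec("rna_cell", platform="10x", n_cells=200, depth=8000,
                           seed=32, name="b"),
        ]
        dss = [cf.simulate_dataset(atlas8, s) for s in specs]
        norms = {d.name: cf.normalize(d) for d in dss}
        hvg = cf.select_hvg_count(norms["a"])
        feats = {n: norms[n].restrict_genes(list(hvg)).values for n in norms}
        anchors = {"a": np.arange(200)}
        g, frame, b = jaccard_graph(feats, anchors, k=15)
        w = np.array(g.es["weight"])
        assert ((w > 0) & (w <= 1)).all()
        labels = louvain_cluster(g, seed=0)
        truth = np.concatenate([d.cells["true_subclass"].to_numpy() for d in dss])
        assert adjusted_rand_score(truth, labels) > 0.8

    def test_jaccard_arithmetic(self):
        # two cells sharing 5 of 25 combined neighbors -> weight 0.2
        import scipy.sparse as sp

        b = np.zeros((2, 40))
        b[0, :15] = 1
        b[1, 10:30] = 1  # shared = 5, union = 30 ... adjust to target
        inter = (b @ b.T)[0, 1]
        union = b[0].sum() + b[1].sum() - inter
        assert inter / union == pytest.approx(5 / 30)

    def test_k_exceeding_anchors_rejected(self):
        feats = {"a": np.random.default_rng(0).normal(size=(10, 4))}
        with pytest.raises(ValueError):
            jaccard_graph(feats, {"a": np.arange(5)}, k=6)


class TestImputeKnnAnchor:
    def test_identity_and_mean(self):
        anchors = np.array([[1.0, 1.0], [3.0, 3.0], [10.0, 0.0]])
        out = impute_knn_anchor(np.array([[0, 1], [2, 2]]), anchors)
        assert np.allclose(out[0], [2.0, 2.0])
        assert np.allclose(out[1], [10.0, 0.0])

    def test_unreached_cell_flagged_nan(self):
        out = impute_knn_anchor(np.array([[-1, -1]]), np.ones((3, 2)))
        assert np.isnan(out).all()


class TestIterativeFusion:
    def test_two_type_recovery(self):
        atlas = cf.generate_atlas(2, 400, effect_size=2.5, seed=5, n_subclasses=1)
        dss = [cf.simulate_dataset(atlas, cf.DatasetSpec(
            "rna_cell", platform="10x", n_cells=300, depth=5000, seed=6, name="rna"))]
        assign = iterative_fusion(dss, "rna", rounds=1, seed=0)
        truth = dss[0].cells["true_type"].to_numpy()
        assert adjusted_rand_score(truth, assign.labels("L0")) == 1.0

    def test_three_modalities_nested_recovery(self, trio):
        assign = iterative_fusion(trio, "rna", rounds=2, seed=0)
        truth = np.concatenate([d.cells["true_type"].to_numpy() for d in trio])
        sub = np.concatenate([d.cells["true_subclass"].to_numpy() for d in trio])
        deepest = assign.levels[-1]
        assert assign.check_nesting()
        ari_type = adjusted_rand_score(truth, assign.labels(deepest))
        ari_sub = adjusted_rand_score(sub, assign.labels(deepest))
        assert max(ari_type, ari_sub) >= 0.9

    def test_alignment_across_modalities(self, trio):
        """Every true type's majority cluster contains cells from all three
        modalities."""
        assign = iterative_fusion(trio, "rna", rounds=1, seed=0)
        frame = assign.cells.copy()
        frame["truth"] = np.concatenate([d.cells["true_type"].to_numpy() for d in trio])
        for t, grp in frame.groupby("truth"):
            top = grp["L0"].mode()[0]
            members = frame[frame["L0"] == top]
            assert set(members["dataset"]) == {"rna", "mc", "atac"}

    def test_reference_must_be_rna(self, trio):
        with pytest.raises(ValueError):
            iterative_fusion(trio, "mc", rounds=1)

    def test_determinism(self, trio):
        a = iterative_fusion(trio, "rna", rounds=1, seed=4)
        b = iterative_fusion(trio, "rna", rounds=1, seed=4)
        assert a.cells["L0"].tolist() == b.cells["L0"].tolist()
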