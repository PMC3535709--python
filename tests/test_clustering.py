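import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from oracles import exhaustive_kmeans2, pca_eigh_variance_ratios
from tailmark.annotations import BinGeometry
from tailmark.clustering import (
    HierarchicalResult,
    KMeansConfig,
    TailScoreConfig,
    cut_tree,
    hierarchical_cluster,
    kmeans,
    pca,
    select_tail_cluster,
    tail_score,
    two_stage_tail_discovery,
)
from tailmark.coverage import ProfileMatrix

GEOM = BinGeometry(10_000, 20)


class TestKMeans:
    def test_two_well_separated_pairs(self):
        X = np.array([[0, 0], [0, 1], [10, 0], [10, 1]], float)
        res = kmeans(X, KMeansConfig(k=2, repeats=50, seed=0))
        assert res.inertia == pytest.approx(1.0)
        assert res.labels[0] == res.labels[1] != res.labels[2] == res.labels[3]

    def test_k1_centroid_is_column_mean(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(10, 4))
        res = kmeans(X, KMeansConfig(k=1, seed=0))
        np.testing.assert_allclose(res.centroids[0], X.mean(axis=0))
        assert res.inertia == pytest.approx(((X - X.mean(0)) ** 2).sum())

    def test_k_equals_n_distinct_rows_zero_inertia(self):
        X = np.arange(12.0).reshape(4, 3)
        res = kmeans(X, KMeansConfig(k=4, repeats=10, seed=1))
        assert res.inertia == pytest.approx(0.0)
        assert sorted(res.labels.tolist()) == [0, 1, 2, 3]

    def test_rows_fewer_than_k_rejected(self):
        with pytest.raises(ValueError):
            kmeans(np.zeros((2, 3)), KMeansConfig(k=3))

    def test_nonfinite_rejected(self):
        X = np.zeros((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            kmeans(X, KMeansConfig(k=2))

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 5))
        a = kmeans(X, KMeansConfig(k=3, repeats=5, seed=9))
        b = kmeans(X, KMeansConfig(k=3, repeats=5, seed=9))
        assert a.inertia == b.inertia
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_matches_exhaustive_optimum_on_small_instances(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(3, 9))
            X = rng.normal(size=(n, int(rng.integers(1, 4))))
            res = kmeans(X, KMeansConfig(k=2, repeats=50, seed=int(rng.integers(1e6))))
            assert res.inertia == pytest.approx(exhaustive_kmeans2(X), rel=1e-9)

    def test_inertia_is_sum_of_squared_distances_to_assigned_centroid(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(25, 6))
        res = kmeans(X, KMeansConfig(k=4, repeats=10, seed=2))
        manual = sum(
            ((X[i] - res.centroids[res.labels[i]]) ** 2).sum() for i in range(25)
        )
        assert res.inertia == pytest.approx(manual)


def _centroid(body=1.0, base=1.0):
    v = np.full(GEOM.n_bins, base)
    lo, hi = GEOM.bin_range(2_000, 8_000)
    v[lo:hi] = body
    return v


class TestTailScore:
    def test_flat_profile_scores_about_one(self):
        assert tail_score(np.ones(1000), GEOM) == pytest.approx(1.0, rel=2e-3)

    def test_elevated_body_scores_about_its_ratio(self):
        s = tail_score(_centroid(body=5.0), GEOM)
        assert s == pytest.approx(5.0, rel=5e-3)

    def test_all_zero_scores_zero(self):
        assert tail_score(np.zeros(1000), GEOM) == 0.0

    def test_scale_invariance_up_to_epsilon(self):
        v = _centroid(body=4.0)
        assert tail_score(v, GEOM) == pytest.approx(tail_score(123.4 * v, GEOM), rel=1e-6)

    def test_monotone_in_body_mean(self):
        scores = [tail_score(_centroid(body=b), GEOM) for b in (1, 2, 4, 8)]
        assert scores == sorted(scores)

    def test_degenerate_region_rejected(self):
        with pytest.raises(ValueError):
            TailScoreConfig(body_from=5, body_to=5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tail_score(np.ones(10), GEOM)


class TestSelectTailCluster:
    def _result(self, centroids, labels):
        from tailmark.clustering import ClusterResult

        return ClusterResult(
            np.asarray(labels), np.asarray(centroids, float), 0.0, [1], 0,
            [f"r{i}" for i in range(len(labels))],
        )

    def test_selects_elevated_tail(self):
        res = self._result([np.ones(1000), _centroid(5.0)], [0, 0, 1])
        sel, scores = select_tail_cluster(res, GEOM)
        assert sel == 1 and scores[1] > scores[0]

    def test_tie_broken_to_larger_cluster(self):
        res = self._result([_centroid(3.0), _centroid(3.0)], [0, 1, 1])
        sel, _ = select_tail_cluster(res, GEOM)
        assert sel == 1

    def test_single_cluster_returned_with_warning(self, caplog):
        res = self._result([np.ones(1000)], [0, 0])
        with caplog.at_level("WARNING"):
            sel, _ = select_tail_cluster(res, GEOM)
        assert sel == 0 and any("single" in r.message for r in caplog.records)


class TestTwoStage:
    def _planted_matrix(self, seed=0):
        """Coarse-then-refine structure: 6 strong promoter clumps (absorbing
        6 of the 7 stage-1 centroids), and one low-signal lump made of the 15
        tail genes plus 3 weak promoter clumps that stage 2 must resolve."""
        rng = np.random.default_rng(seed)
        rows, ids = [], []
        lo, hi = GEOM.bin_range(2_000, 8_000)
        plo, phi = GEOM.bin_range(-400, 600)
        i = 0
        for _ in range(15):  # tail genes
            r = 1.0 + rng.normal(0, 0.1, GEOM.n_bins)
            r[lo:hi] += 8.0
            r[plo:phi] += 6.0
            rows.append(r); ids.append(f"g{i}"); i += 1
        for peak in (3.0, 6.0, 9.0):  # weak promoter clumps
            for _ in range(8):
                r = 1.0 + rng.normal(0, 0.1, GEOM.n_bins)
                r[plo:phi] += peak
                rows.append(r); ids.append(f"g{i}"); i += 1
        for peak in np.geomspace(25, 400, 45):  # strong promoter continuum
            r = 1.0 + rng.normal(0, 0.1, GEOM.n_bins)
            r[plo:phi] += peak
            rows.append(r); ids.append(f"g{i}"); i += 1
        return ProfileMatrix(np.array(rows), ids), [f"g{j}" for j in range(15)]

    def test_recovers_planted_tail_genes(self):
        m, planted = self._planted_matrix()
        found, s1, s2 = two_stage_tail_discovery(m, seed=4)
        assert set(found) == set(planted)

    def test_same_seed_same_gene_list(self):
        m, _ = self._planted_matrix()
        a, *_ = two_stage_tail_discovery(m, seed=5)
        b, *_ = two_stage_tail_discovery(m, seed=5)
        assert a == b

    def test_degenerate_tiny_selection_reduces_stage2_k(self, caplog):
        # 5 identical silent rows + 3 tail rows: stage-1 tail cluster may be
        # smaller than k2=4; the refinement degrades gracefully
        rng = np.random.default_rng(0)
        lo, hi = GEOM.bin_range(2_000, 8_000)
        rows = [rng.poisson(1.0, 1000).astype(float) for _ in range(5)]
        for _ in range(3):
            r = rng.poisson(1.0, 1000).astype(float)
            r[lo:hi] += 25
            rows.append(r)
        m = ProfileMatrix(np.array(rows), [f"g{i}" for i in range(8)])
        from tailmark.clustering import KMeansConfig

        found, _, _ = two_stage_tail_discovery(
            m, KMeansConfig(k=2, repeats=10), KMeansConfig(k=4, repeats=10), seed=1
        )
        assert set(found) <= {"g5", "g6", "g7"}


class TestHierarchical:
    def _templates(self, n=30, noise=0.01, seed=0):
        rng = np.random.default_rng(seed)
        t = np.array(
            [np.sin(np.linspace(0, 3, 50)),
             np.cos(np.linspace(0, 3, 50)),
             np.linspace(-1, 1, 50)]
        )
        labels = np.repeat([0, 1, 2], n // 3)
        X = t[labels] + rng.normal(0, noise, size=(n, 50))
        return X, labels

    def test_recovers_planted_templates(self):
        X, labels = self._templates()
        res = hierarchical_cluster(X)
        got = cut_tree(res, 3)
        assert adjusted_rand_score(labels, got) == 1.0

    def test_identical_rows_merge_first_at_zero_height(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 20))
        X[3] = X[1]
        res = hierarchical_cluster(X)
        first = res.linkage[0]
        assert {int(first[0]), int(first[1])} == {1, 3}
        assert first[2] == pytest.approx(0.0, abs=1e-12)

    def test_affine_row_transform_leaves_tree_unchanged(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 30))
        Y = X.copy()
        Y[4] = 3.5 * X[4] + 11.0  # Pearson-invariant transform
        a = hierarchical_cluster(X).linkage
        b = hierarchical_cluster(Y).linkage
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_zero_variance_row_rejected_by_name(self):
        X = np.ones((3, 10))
        X[0] = np.arange(10)
        X[1] = np.arange(10)[::-1]
        with pytest.raises(ValueError, match="2"):
            hierarchical_cluster(X, linkage="average")


@pytest.fixture(scope="module")
def tree():
    rng = np.random.default_rng(3)
    return hierarchical_cluster(rng.normal(size=(15, 12)))


class TestCutTree:

    def test_k1_single_group(self, tree):
        assert set(cut_tree(tree, 1).tolist()) == {0}

    def test_kn_singletons(self, tree):
        assert len(set(cut_tree(tree, tree.n).tolist())) == tree.n

    def test_cuts_are_nested(self, tree):
        for k in range(1, tree.n):
            a, b = cut_tree(tree, k), cut_tree(tree, k + 1)
            # every k+1 group maps into exactly one k group
            for g in set(b.tolist()):
                assert len(set(a[b == g].tolist())) == 1

    def test_groups_ordered_by_decreasing_size(self, tree):
        lab = cut_tree(tree, 4)
        sizes = np.bincount(lab)
        assert sorted(sizes.tolist(), reverse=True) == sizes.tolist()

    def test_out_of_range_rejected(self, tree):
        with pytest.raises(ValueError):
            cut_tree(tree, 0)
        with pytest.raises(ValueError):
            cut_tree(tree, tree.n + 1)


class TestPCA:
    def test_collinear_rows_explained_by_pc1(self):
        x = np.linspace(0, 1, 20)
        X = np.c_[x, 2 * x]
        res = pca(X, 2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_loadings_orthonormal(self):
        rng = np.random.default_rng(4)
        res = pca(rng.normal(size=(20, 10)), 5)
        np.testing.assert_allclose(
            res.loadings @ res.loadings.T, np.eye(5), atol=1e-8
        )

    def test_variance_ratios_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(20, 10))
        res = pca(X, 10)
        np.testing.assert_allclose(
            res.explained_variance_ratio, pca_eigh_variance_ratios(X)[:10], atol=1e-8
        )

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(15, 8))
        res = pca(X, 8)
        recon = res.scores @ res.loadings + res.mean
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_nonfinite_rejected(self):
        X = np.zeros((4, 3))
        X[1, 1] = np.inf
        with pytest.raises(ValueError):
            pca(X, 2)
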