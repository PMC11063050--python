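"""Affinity construction, fusion, spectral clustering, silhouette, grid search."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import netstrat as ns
from netstrat.snf_clustering import (
    SNFConfig, cluster_edge_scores, _full_kernel, _knn_kernel,
    similarity_to_dissimilarity,
)


def block_affinity(sizes, within=1.0, between=0.0, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    labels = np.concatenate([np.full(s, i) for i, s in enumerate(sizes)])
    A = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    if noise:
        sym = rng.normal(0, noise, (n, n))
        A += (sym + sym.T) / 2
        A = np.clip(A, 0, None)
    np.fill_diagonal(A, within)
    return A, labels


class TestDistances:
    def test_three_four_five(self):
        D = ns.squared_euclidean_distances(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert D[0, 1] == pytest.approx(25.0)

    def test_identical_rows_zero(self):
        D = ns.squared_euclidean_distances(np.ones((3, 4)))
        assert np.allclose(D, 0)

    def test_double_loop_oracle(self, rng):
        X = rng.random((5, 4))
        D = ns.squared_euclidean_distances(X)
        for i in range(5):
            for j in range(5):
                assert D[i, j] == pytest.approx(
                    sum((X[i, f] - X[j, f]) ** 2 for f in range(4)), abs=1e-12
                )

    def test_nan_error_names_columns(self):
        df = pd.DataFrame({"e1": [0.1, 0.2], "e2": [np.nan, 0.3]})
        with pytest.raises(ValueError, match="e2"):
            ns.squared_euclidean_distances(df)


class TestAffinity:
    def test_four_point_line_hand_oracle(self):
        # points on a line at 0, 1, 2, 10 -> squared distances; K=2, mu=0.5
        x = np.array([[0.0], [1.0], [2.0], [10.0]])
        D = ns.squared_euclidean_distances(x)
        K, mu = 2, 0.5
        W = ns.snf_affinity(D, K, mu)
        # independent evaluation of the kernel formula
        knn = np.array([sorted(D[i][np.arange(4) != i])[:K] for i in range(4)])
        tt = knn.mean(axis=1)
        for i in range(4):
            for j in range(4):
                eps = (tt[i] + tt[j] + D[i, j]) / 3
                w = np.exp(-D[i, j] / (mu * eps))
                expect = (w + np.exp(-D[j, i] / (mu * (tt[j] + tt[i] + D[j, i]) / 3))) / 2
                assert W[i, j] == pytest.approx(expect, abs=1e-12)

    def test_diagonal_is_one_pre_normalization(self, rng):
        D = ns.squared_euclidean_distances(rng.random((6, 3)))
        W = ns.snf_affinity(D, 2, 0.5)
        assert np.allclose(np.diag(W), 1.0)

    def test_mu_monotone(self, rng):
        D = ns.squared_euclidean_distances(rng.random((6, 3)))
        W1 = ns.snf_affinity(D, 2, 0.4)
        W2 = ns.snf_affinity(D, 2, 0.8)
        off = ~np.eye(6, dtype=bool)
        assert (W2[off] > W1[off]).all()

    def test_scale_invariance_of_exp_kernel(self, rng):
        # multiplying features by c rescales D by c^2 but eps too: W unchanged
        X = rng.random((7, 4))
        W1 = ns.snf_affinity(ns.squared_euclidean_distances(X), 3, 0.5)
        W2 = ns.snf_affinity(ns.squared_euclidean_distances(3.7 * X), 3, 0.5)
        assert np.allclose(W1, W2, atol=1e-12)

    def test_zero_distance_pairs_warn_not_crash(self, caplog):
        D = np.zeros((4, 4))
        with caplog.at_level("WARNING"):
            W = ns.snf_affinity(D, 2, 0.5)
        assert np.isfinite(W).all()

    def test_bad_args(self, rng):
        D = ns.squared_euclidean_distances(rng.random((4, 2)))
        with pytest.raises(ValueError):
            ns.snf_affinity(D, 0, 0.5)
        with pytest.raises(ValueError):
            ns.snf_affinity(D, 2, -1.0)
        with pytest.raises(ValueError):
            ns.snf_affinity(D, 2, 0.5, kernel="nope")


def fuse_oracle(views, K, t):
    """Literal re-implementation of the cross-diffusion loop."""
    def full(W):
        P = W.copy().astype(float)
        np.fill_diagonal(P, 0)
        P = P / (2 * P.sum(1, keepdims=True))
        np.fill_diagonal(P, 0.5)
        return P

    def knn(W, K):
        n = W.shape[0]
        S = np.zeros_like(W, dtype=float)
        for i in range(n):
            order = [j for j in np.argsort(-W[i]) if j != i][:K]
            S[i, order] = W[i, order]
        return S / S.sum(1, keepdims=True)

    P = [full(V) for V in views]
    S = [knn(V, K) for V in views]
    m = len(views)
    for _ in range(t):
        P_new = []
        for v in range(m):
            others = sum(P[u] for u in range(m) if u != v) / (m - 1)
            Pv = S[v] @ others @ S[v].T
            P_new.append(full((Pv + Pv.T) / 2))
        P = P_new
    F = sum(P) / m
    return (F + F.T) / 2


class TestFusion:
    def test_single_view_is_normalized_input(self, rng):
        D = ns.squared_euclidean_distances(rng.random((8, 3)))
        W = ns.snf_affinity(D, 3, 0.5)
        F = ns.snf_fuse([W], 3)
        P = _full_kernel(W)
        assert np.allclose(F, (P + P.T) / 2, atol=1e-12)

    def test_identical_ideal_block_views_fixed_point(self):
        A, _ = block_affinity([4, 4])
        F = ns.snf_fuse([A, A], 3, t=20)
        P = _full_kernel(A)
        assert np.allclose(F, (P + P.T) / 2, atol=1e-10)

    def test_two_distinct_views_match_independent_oracle(self, rng):
        X1, X2 = rng.random((8, 4)), rng.random((8, 5))
        W1 = ns.snf_affinity(ns.squared_euclidean_distances(X1), 3, 0.5)
        W2 = ns.snf_affinity(ns.squared_euclidean_distances(X2), 3, 0.5)
        F = ns.snf_fuse([W1, W2], 3, t=20)
        assert np.allclose(F, fuse_oracle([W1, W2], 3, 20), atol=1e-10)

    def test_identical_views_stay_identical_through_diffusion(self, rng):
        # view-symmetry: both views' diffused matrices coincide, so fusing
        # (V, V) equals fusing (V, V, V)
        X = rng.random((8, 4))
        W = ns.snf_affinity(ns.squared_euclidean_distances(X), 3, 0.5)
        assert np.allclose(ns.snf_fuse([W, W], 3), ns.snf_fuse([W, W, W], 3),
                           atol=1e-10)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension|share"):
            ns.snf_fuse([np.eye(4), np.eye(5)], 2)


class TestSpectral:
    @pytest.mark.parametrize("sizes", [[5, 7], [4, 6, 5], [3, 4, 5, 6]])
    def test_block_diagonal_exact(self, sizes):
        A, truth = block_affinity(sizes)
        labels = ns.spectral_clustering(A, len(sizes), seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_noisy_two_block(self, rng):
        n1, n2 = 10, 14
        A = np.empty((24, 24))
        truth = np.array([0] * n1 + [1] * n2)
        for i in range(24):
            for j in range(24):
                base = 0.9 if truth[i] == truth[j] else 0.1
                A[i, j] = base
        A += rng.normal(0, 0.05, A.shape)
        A = np.clip((A + A.T) / 2, 0, None)
        labels = ns.spectral_clustering(A, 2, seed=0)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_permutation_equivariance(self, rng):
        A, truth = block_affinity([4, 5, 6], noise=0.01, seed=3)
        labels = ns.spectral_clustering(A, 3, seed=1)
        perm = rng.permutation(len(truth))
        labels_p = ns.spectral_clustering(A[np.ix_(perm, perm)], 3, seed=1)
        assert adjusted_rand_score(labels[perm], labels_p) == 1.0

    def test_k_bounds(self):
        A, _ = block_affinity([3, 3])
        with pytest.raises(ValueError):
            ns.spectral_clustering(A, 6, seed=0)
        with pytest.raises(ValueError):
            ns.spectral_clustering(A, 1, seed=0)


def brute_similarity_silhouette(A, labels):
    """Straight-from-definition per-sample silhouette on similarities."""
    A = np.asarray(A, float)
    labels = np.asarray(labels)
    vals = []
    for i in range(len(labels)):
        mates = [j for j in range(len(labels))
                 if labels[j] == labels[i] and j != i]
        if not mates:
            vals.append(0.0)
            continue
        a = np.mean([A[i, j] for j in mates])
        b = max(
            np.mean([A[i, j] for j in range(len(labels)) if labels[j] == c])
            for c in set(labels) if c != labels[i]
        )
        vals.append((a - b) / max(a, b) if max(a, b) > 0 else 0.0)
    return float(np.mean(vals))


class TestSilhouette:
    def test_ideal_blocks_score_one(self):
        A, truth = block_affinity([5, 6])
        assert ns.similarity_silhouette(A, truth) == pytest.approx(1.0)

    def test_matches_brute_force_on_random_affinities(self, rng):
        for _ in range(5):
            A = rng.random((12, 12))
            A = (A + A.T) / 2
            labels = rng.integers(0, 3, 12)
            if len(np.unique(labels)) < 2:
                continue
            assert ns.similarity_silhouette(A, labels) == pytest.approx(
                brute_similarity_silhouette(A, labels), abs=1e-12
            )

    def test_random_labels_on_ideal_blocks_near_zero(self, rng):
        A, _ = block_affinity([10, 10])
        labels = rng.integers(0, 2, 20)
        while len(np.unique(labels)) < 2:
            labels = rng.integers(0, 2, 20)
        assert ns.similarity_silhouette(A, labels) < 0.5

    def test_scale_invariance(self, rng):
        A = rng.random((10, 10))
        A = (A + A.T) / 2
        labels = np.array([0] * 5 + [1] * 5)
        s1 = ns.similarity_silhouette(A, labels)
        s2 = ns.similarity_silhouette(4.2 * A, labels)
        assert s1 == pytest.approx(s2, abs=1e-12)

    def test_conversion_variants_agree_with_each_other(self, rng):
        # max-shift and relative conversions differ by a positive scale, so
        # their silhouettes coincide
        A = rng.random((10, 10))
        A = (A + A.T) / 2
        labels = np.array([0] * 5 + [1] * 5)
        s1 = ns.similarity_silhouette(A, labels, method="max_shift")
        s2 = ns.similarity_silhouette(A, labels, method="relative")
        assert s1 == pytest.approx(s2, abs=1e-10)

    def test_single_cluster_rejected(self):
        A, _ = block_affinity([6])
        with pytest.raises(ValueError):
            ns.similarity_silhouette(A, np.zeros(6))


class TestModelSelection:
    def test_single_point_grid(self, small_scores):
        cfg = SNFConfig(mu_grid=(0.5,), cluster_range=(3,), seed=0,
                        kmeans_restarts=10)
        sols = ns.model_selection_grid(small_scores["scores"], cfg)
        assert len(sols) == 1
        assert sols[0].n_clusters == 3 and sols[0].mu == 0.5

    def test_deterministic_given_seed(self, small_scores):
        cfg = SNFConfig(mu_grid=(0.4,), cluster_range=(2, 3), seed=5,
                        kmeans_restarts=10)
        a = ns.model_selection_grid(small_scores["scores"], cfg)
        b = ns.model_selection_grid(small_scores["scores"], cfg)
        for x, y in zip(a, b):
            assert np.array_equal(x.labels, y.labels)
            assert x.silhouette == y.silhouette

    def test_ranked_descending_with_small_k_tiebreak(self, small_scores):
        cfg = SNFConfig(mu_grid=(0.3, 0.5), cluster_range=(2, 3, 4), seed=0,
                        kmeans_restarts=10)
        sols = ns.model_selection_grid(small_scores["scores"], cfg)
        sils = [s.silhouette for s in sols]
        assert sils == sorted(sils, reverse=True)

    def test_empty_grid_rejected(self, small_scores):
        with pytest.raises(ValueError):
            ns.model_selection_grid(
                small_scores["scores"], SNFConfig(mu_grid=(), seed=0)
            )

    def test_default_K_rule_is_n_over_ten(self):
        assert SNFConfig().resolve_K(728) == 73
        assert SNFConfig(K=70).resolve_K(728) == 70


class TestPlantedRecovery:
    def test_cohort_scale_recovery(self):
        """At the default cohort scale the planted clusters are recovered
        nearly perfectly at k=3 for any mu in the grid."""
        cfg = ns.SimulationConfig(seed=1)
        bundle = ns.generate_all(cfg)
        from netstrat.synthetic_cohort import NEURODEGENERATION_CUIS
        selected = ns.filter_vda_by_disease(
            bundle["annotations"], set(NEURODEGENERATION_CUIS))
        gm = ns.build_variant_gene_map(selected, bundle["genotypes"])
        subnet = ns.induce_brain_subnetwork(bundle["ppi"], gm, selected)
        scores = ns.build_edge_score_matrix(bundle["genotypes"], subnet, gm)
        sol = cluster_edge_scores(scores, k=3, mu=0.5, K=70, seed=0,
                                  restarts=20)
        assert adjusted_rand_score(bundle["truth"].labels, sol.labels) >= 0.9
        assert sol.silhouette > 0.7

    def test_grid_ranks_three_clusters_high_at_cohort_scale(self):
        cfg = ns.SimulationConfig(seed=2)
        bundle = ns.generate_all(cfg)
        from netstrat.synthetic_cohort import NEURODEGENERATION_CUIS
        selected = ns.filter_vda_by_disease(
            bundle["annotations"], set(NEURODEGENERATION_CUIS))
        gm = ns.build_variant_gene_map(selected, bundle["genotypes"])
        subnet = ns.induce_brain_subnetwork(bundle["ppi"], gm, selected)
        scores = ns.build_edge_score_matrix(bundle["genotypes"], subnet, gm)
        cfg_snf = SNFConfig(K=70, mu_grid=(0.3, 0.5), cluster_range=(2, 3, 4, 5),
                            seed=0, kmeans_restarts=10)
        sols = ns.model_selection_grid(scores, cfg_snf)
        per_k = ns.best_per_cluster_count(sols)
        top2 = {s.n_clusters for s in per_k[:2]}
        best3 = next(s for s in per_k if s.n_clusters == 3)
        assert 3 in top2
        assert best3.silhouette > 0.7
        assert adjusted_rand_score(bundle["truth"].labels, best3.labels) >= 0.9
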