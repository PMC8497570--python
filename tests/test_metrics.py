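import numpy as np
import pandas as pd
import pytest
from scipy.stats import special_ortho_group, spearmanr

import atlasmap as am
from atlasmap.preprocess import ExpressionMatrix

from conftest import hard_memberships, make_embedding_reference


class TestMahalanobis:
    def test_identity_covariance_is_euclidean(self):
        x = np.array([3.0, 4.0])
        d = am.mahalanobis(x, np.zeros(2), np.eye(2))
        assert d == pytest.approx(5.0, abs=1e-5)

    def test_zero_at_mean(self):
        mu = np.array([1.0, -2.0, 3.0])
        assert am.mahalanobis(mu, mu, np.eye(3)) == 0.0

    def test_one_dimensional_z_score(self):
        assert am.mahalanobis([2.0], [0.0], [[4.0]]) == pytest.approx(1.0, abs=1e-6)

    def test_asymmetric_covariance_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            am.mahalanobis([0.0, 0.0], [0.0, 0.0], [[1.0, 0.5], [0.0, 1.0]])


class TestPerCellMetric:
    def test_cell_at_weighted_mean_scores_zero(self):
        rng = np.random.default_rng(0)
        Z_r = rng.standard_normal((3, 60))
        R_r = np.ones((1, 60))
        stats = am.compute_cluster_stats(Z_r, R_r)
        mapped = am.MappedQuery(
            Z_q=stats.mean[0][:, None], R_q=np.ones((1, 1)),
            B_q=np.zeros((1, 1, 3)), Z_hat_q=stats.mean[0][:, None],
        )
        score = am.per_cell_mapping_metric(mapped, stats)
        assert score[0] == pytest.approx(0.0, abs=1e-6)

    def test_in_distribution_low_out_of_distribution_high(self):
        rng = np.random.default_rng(1)
        d, n = 5, 3000
        Z_r = rng.standard_normal((d, n))
        stats = am.compute_cluster_stats(Z_r, np.ones((1, n)))
        Z_in = rng.standard_normal((d, 200))
        Z_out = Z_in + 10.0  # ten within-cluster SDs away in every coordinate
        def score(Z):
            mapped = am.MappedQuery(Z_q=Z, R_q=np.ones((1, Z.shape[1])),
                                    B_q=np.zeros((1, 1, d)), Z_hat_q=Z)
            return am.per_cell_mapping_metric(mapped, stats)
        s_in, s_out = score(Z_in), score(Z_out)
        assert np.median(s_in) < 10.0  # well-represented states score low
        assert np.median(s_out) >= 5 * np.median(s_in)

    def test_missing_stats_raises(self):
        mapped = am.MappedQuery(Z_q=np.zeros((2, 1)), R_q=np.ones((1, 1)),
                                B_q=np.zeros((1, 1, 2)), Z_hat_q=np.zeros((2, 1)))
        with pytest.raises(ValueError, match="ClusterStats absent"):
            am.per_cell_mapping_metric(mapped, None)


class TestPerClusterMetric:
    def test_cluster_centered_on_centroid_scores_zero(self):
        rng = np.random.default_rng(2)
        d = 3
        pts = rng.standard_normal((d, 100))
        pts -= pts.mean(axis=1, keepdims=True)
        cents = np.vstack([np.zeros(d), np.full(d, 50.0)])
        scores = am.per_cluster_mapping_metric(pts, np.zeros(100, int), cents)
        assert scores[0] == pytest.approx(0.0, abs=1e-8)

    def test_small_cluster_returns_na(self):
        d = 4
        rng = np.random.default_rng(3)
        n_small = 2 * d - 1
        pts = rng.standard_normal((d, n_small + 50))
        labels = np.array(["small"] * n_small + ["big"] * 50)
        scores = am.per_cluster_mapping_metric(pts, labels, np.zeros((1, d)))
        assert np.isnan(scores["small"])
        assert np.isfinite(scores["big"])

    def test_matches_direct_computation(self):
        rng = np.random.default_rng(4)
        d = 3
        pts = rng.standard_normal((d, 80)) + 2
        cents = rng.standard_normal((5, d))
        scores = am.per_cluster_mapping_metric(pts, np.zeros(80, int), cents)
        mean = pts.mean(axis=1)
        cov = np.cov(pts)
        nearest = cents[np.argmin(((cents - mean) ** 2).sum(axis=1))]
        expected = am.mahalanobis(nearest, mean, cov)
        assert scores[0] == pytest.approx(expected, abs=1e-8)

    def test_identical_scores_within_cluster_when_broadcast(self):
        rng = np.random.default_rng(5)
        pts = rng.standard_normal((2, 60))
        labels = np.repeat(["a", "b"], 30)
        scores = am.per_cluster_mapping_metric(pts, labels, np.zeros((1, 2)))
        per_cell = scores.loc[labels]
        assert per_cell[labels == "a"].nunique() == 1


class TestKnnCorr:
    def test_identical_embeddings_score_one(self):
        rng = np.random.default_rng(6)
        Z = rng.standard_normal((4, 100))
        kc = am.knn_corr(Z, Z, np.arange(80, 100), np.arange(80), k=20)
        np.testing.assert_allclose(kc, 1.0)

    def test_uniform_scaling_preserves_ranks(self):
        rng = np.random.default_rng(7)
        Z = rng.standard_normal((3, 90))
        kc = am.knn_corr(Z, 2.0 * Z, np.arange(70, 90), np.arange(70), k=15)
        np.testing.assert_allclose(kc, 1.0)

    def test_hand_case_with_one_swapped_pair(self):
        # gold distances 1..5; alt swaps the two nearest neighbors
        gold = np.zeros((1, 6))
        gold[0] = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0]
        alt = gold.copy()
        alt[0, 1], alt[0, 2] = 2.0, 1.0
        kc = am.knn_corr(gold, alt, np.array([0]), np.arange(1, 6), k=5)
        # rank formula oracle: 1 - 6*sum(d^2)/(n(n^2-1)) with d = (1,1,0,0,0)
        expected = 1 - 6 * 2 / (5 * 24)
        assert kc[0] == pytest.approx(expected, abs=1e-12)
        assert kc[0] == pytest.approx(0.9, abs=1e-12)

    def test_k_exceeding_reference_raises(self):
        Z = np.zeros((2, 10))
        with pytest.raises(ValueError, match="exceeds"):
            am.knn_corr(Z, Z, np.arange(5), np.arange(5, 10), k=9)


class TestWiqKnnCorr:
    def _query_counts(self, seed=8, n=150):
        spec = am.SimulationSpec(cells_per_batch=(n,), n_genes=100, d_latent=5,
                                 centroid_separation=6.0, seed=seed,
                                 structure_seed=3)
        em, meta, _ = am.simulate_counts(spec)
        return em, meta

    def _per_batch_pca(self, em, d_pca, n_vargenes):
        ln = am.normalize_log_cp10k(em)
        genes = am.select_variable_genes_vst(
            ln, np.zeros(em.n_cells, int), n_vargenes)
        scaled, _ = am.scale_genes(ln, genes)
        _, Z = am.run_svd_embedding(scaled, d_pca)
        return Z

    def test_rigid_rotation_scores_one(self):
        em, meta = self._query_counts()
        Z = self._per_batch_pca(em, 5, 80)
        Q = special_ortho_group.rvs(5, random_state=9)
        out = am.wiq_knn_corr(em, np.zeros(em.n_cells, int), Q @ Z, k=20,
                              d_pca=5, n_vargenes=80)
        np.testing.assert_allclose(out, 1.0, atol=1e-8)

    def test_per_batch_pca_itself_scores_one(self):
        em, meta = self._query_counts(seed=10)
        Z = self._per_batch_pca(em, 5, 80)
        out = am.wiq_knn_corr(em, np.zeros(em.n_cells, int), Z, k=20,
                              d_pca=5, n_vargenes=80)
        np.testing.assert_allclose(out, 1.0, atol=1e-8)

    def test_random_shuffle_destroys_correlation(self):
        em, meta = self._query_counts(seed=11, n=400)
        Z = self._per_batch_pca(em, 5, 80)
        rng = np.random.default_rng(12)
        shuffled = Z[:, rng.permutation(Z.shape[1])]
        out = am.wiq_knn_corr(em, np.zeros(em.n_cells, int), shuffled, k=50,
                              d_pca=5, n_vargenes=80)
        assert abs(np.nanmean(out)) < 0.05

    def test_small_batch_truncates_k_with_warning(self):
        em, meta = self._query_counts(seed=13, n=40)
        Z = self._per_batch_pca(em, 4, 60)
        with pytest.warns(UserWarning, match="truncated"):
            out = am.wiq_knn_corr(em, np.zeros(em.n_cells, int), Z, k=100,
                                  d_pca=4, n_vargenes=60)
        np.testing.assert_allclose(out, 1.0, atol=1e-8)


class TestLisi:
    def test_single_category_scores_one(self):
        rng = np.random.default_rng(14)
        Z = rng.standard_normal((2, 120))
        out = am.lisi(Z, np.zeros(120, int), perplexity=20)
        np.testing.assert_allclose(out, 1.0, atol=1e-8)

    def test_perfectly_interleaved_pair_approaches_two(self):
        n = 600
        Z = np.arange(n, dtype=float)[None, :]
        cats = np.arange(n) % 2
        out = am.lisi(Z, cats, perplexity=30)
        interior = out[100:-100]
        assert np.all(interior > 1.9)

    def test_matches_independent_inverse_simpson_oracle(self):
        rng = np.random.default_rng(15)
        n, d, perplexity = 60, 3, 10
        Z = rng.standard_normal((d, n))
        cats = rng.integers(0, 3, n)
        out = am.lisi(Z, cats, perplexity=perplexity)
        # brute-force oracle: loops, explicit bisection on Shannon entropy
        D = np.linalg.norm(Z[:, :, None] - Z[:, None, :], axis=0)
        nn = min(3 * perplexity, n - 1)
        expected = np.empty(n)
        for i in range(n):
            order = np.argsort(D[i])
            nbrs = order[order != i][:nn]
            d2 = D[i, nbrs] ** 2
            d2 = d2 - d2.min()
            lo, hi = 0.0, 1.0
            target = np.log(perplexity)
            def H(beta):
                w = np.exp(-beta * d2)
                p = w / w.sum()
                return float(-(p[p > 0] * np.log(p[p > 0])).sum())
            while H(hi) > target:
                hi *= 2
            for _ in range(200):
                mid = (lo + hi) / 2
                if H(mid) > target:
                    lo = mid
                else:
                    hi = mid
            w = np.exp(-mid * d2)
            p = w / w.sum()
            probs = np.zeros(3)
            for j, nb in enumerate(nbrs):
                probs[cats[nb]] += p[j]
            expected[i] = 1.0 / (probs ** 2).sum()
        np.testing.assert_allclose(out, expected, atol=1e-4)

    def test_scores_bounded_by_category_count(self):
        rng = np.random.default_rng(16)
        Z = rng.standard_normal((3, 200))
        cats = rng.integers(0, 4, 200)
        out = am.lisi(Z, cats, perplexity=15)
        assert np.all(out >= 1.0 - 1e-9) and np.all(out <= 4.0 + 1e-9)


class TestCellTypeF1:
    def test_perfect_predictions(self):
        t = ["a", "b", "a", "c"]
        res = am.cell_type_f1(t, t)
        assert res["accuracy"] == 1.0
        assert (res["per_type"]["f1"] == 1.0).all()

    def test_formula_example(self):
        # type "x": TP=8, FP=2, FN=2
        truth = ["x"] * 10 + ["y"] * 10
        pred = ["x"] * 8 + ["y"] * 2 + ["x"] * 2 + ["y"] * 8
        res = am.cell_type_f1(truth, pred)
        row = res["per_type"].loc["x"]
        assert row["precision"] == pytest.approx(0.8)
        assert row["recall"] == pytest.approx(0.8)
        assert row["f1"] == pytest.approx(0.8)

    def test_never_predicted_type_gets_zero_f1(self):
        res = am.cell_type_f1(["a", "a", "b"], ["a", "a", "a"])
        assert res["per_type"].loc["b", "f1"] == 0.0

    def test_unassigned_excluded_and_reported(self):
        truth = ["a", "a", "b", "b"]
        pred = ["a", "b", "b", "b"]
        assigned = np.array([True, False, True, True])
        res = am.cell_type_f1(truth, pred, assigned)
        assert res["unassigned_fraction"] == pytest.approx(0.25)
        assert res["accuracy"] == 1.0

    def test_agrees_with_sklearn(self):
        rng = np.random.default_rng(17)
        truth = rng.choice(["a", "b", "c"], 200)
        pred = np.where(rng.random(200) < 0.8, truth,
                        rng.choice(["a", "b", "c"], 200))
        res = am.cell_type_f1(truth, pred)
        from sklearn.metrics import f1_score
        for i, t in enumerate(["a", "b", "c"]):
            skl = f1_score(truth, pred, labels=[t], average="macro")
            assert res["per_type"].loc[t, "f1"] == pytest.approx(skl, abs=1e-12)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            am.cell_type_f1([], [])
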