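import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from multiweave import (
    NeighborGraph,
    add_modality_noise,
    build_knn,
    cluster_graph,
    cross_cluster_edges,
    jaccard_snn,
    neighbor_prediction_correlation,
    neighborhood_variable_genes,
    perturbation_score,
    select_marker_panel,
)


class TestClusterGraph:
    def test_two_disconnected_cliques(self):
        # neighbor lists wired entirely within each clique
        idx_a = np.array([[(i + j) % 5 for j in range(1, 4)] for i in range(5)])
        idx_b = idx_a + 5
        indices = np.vstack([idx_a, idx_b])
        snn = jaccard_snn(indices)
        for res in (0.1, 0.5, 1.0):
            labels = cluster_graph(snn, resolution=res, seed=0)
            assert len(set(labels)) == 2
            assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1

    def test_recovers_synthetic_clusters(self, small_fixture):
        res, _, out = small_fixture
        labels = cluster_graph(out.graph.snn(), resolution=0.8, seed=0)
        assert adjusted_rand_score(res.labels, labels) >= 0.95

    def test_resolution_monotonicity(self, small_fixture):
        _, _, out = small_fixture
        snn = out.graph.snn()
        counts = [
            len(set(cluster_graph(snn, resolution=r, seed=0)))
            for r in (0.1, 0.5, 1.0, 2.0)
        ]
        assert counts == sorted(counts)


class TestNoise:
    def test_sd_zero_identity_and_seeded_determinism(self):
        X = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(add_modality_noise(X, 0.0), X)
        a = add_modality_noise(X, 1.5, seed=3)
        b = add_modality_noise(X, 1.5, seed=3)
        assert np.array_equal(a, b)

    def test_realized_sd_close_to_requested(self):
        X = np.zeros((200, 300))
        noisy = add_modality_noise(X, 2.0, seed=4)
        assert abs(noisy.std() - 2.0) / 2.0 < 0.05


class TestCrossClusterEdges:
    def test_complete_bipartite_toy(self):
        # 3 a-cells each pointing at 2 b-cells and vice versa: 6 + 6 directed
        # a->b edges... restrict to k=2 so each cell contributes 2
        indices = np.array([[3, 4], [4, 5], [3, 5], [0, 1], [1, 2], [0, 2]])
        labels = np.array(["a"] * 3 + ["b"] * 3, dtype=object)
        g = NeighborGraph(indices=indices, distances=np.zeros((6, 2)), k=2)
        assert cross_cluster_edges(g, labels, "a", "b") == 12
        assert cross_cluster_edges(g, labels, "a", "b", directed=False) == 9

    def test_separated_clusters_have_zero(self):
        rng = np.random.default_rng(0)
        emb = np.vstack(
            [rng.normal(0, 0.1, (20, 3)), rng.normal(0, 0.1, (20, 3)) + 50]
        )
        labels = np.array(["a"] * 20 + ["b"] * 20, dtype=object)
        g = build_knn(emb, k=5)
        assert cross_cluster_edges(g, labels, "a", "b") == 0

    def test_unknown_label_errors(self):
        g = NeighborGraph(np.array([[1], [0]]), np.zeros((2, 1)), k=1)
        with pytest.raises(ValueError, match="unknown"):
            cross_cluster_edges(g, np.array(["a", "b"]), "a", "zz")


class TestNeighborPredictionCorrelation:
    def test_clique_constant_feature_correlates_perfectly(self):
        idx_a = np.array([[(i + j) % 5 for j in range(1, 4)] for i in range(5)])
        indices = np.vstack([idx_a, idx_a + 5])
        feat = np.array([[1.0] * 5 + [5.0] * 5])
        out = neighbor_prediction_correlation(indices, feat)
        assert np.isclose(out["pearson"].iloc[0], 1.0)

    def test_ten_cell_hand_computation(self):
        rng = np.random.default_rng(1)
        emb = rng.normal(size=(10, 2))
        g = build_knn(emb, k=3)
        feat = rng.normal(size=(2, 10))
        out = neighbor_prediction_correlation(g, feat)
        for f in range(2):
            pred = np.array([feat[f, g.indices[i]].mean() for i in range(10)])
            expected = np.corrcoef(feat[f], pred)[0, 1]
            assert np.isclose(out["pearson"].iloc[f], expected)

    def test_pure_noise_feature_near_zero(self):
        rng = np.random.default_rng(2)
        emb = rng.normal(size=(2000, 4))
        g = build_knn(emb, k=20)
        noise = rng.normal(size=(1, 2000))
        out = neighbor_prediction_correlation(g, noise)
        assert abs(out["pearson"].iloc[0]) < 0.1

    def test_zero_variance_feature_reported_missing(self):
        g = build_knn(np.random.default_rng(3).normal(size=(10, 2)), k=2)
        out = neighbor_prediction_correlation(g, np.ones((1, 10)))
        assert np.isnan(out["pearson"].iloc[0])


class TestVariableGenes:
    def test_homogeneous_population_few_false_positives(self):
        rng = np.random.default_rng(4)
        X = rng.poisson(np.linspace(0.2, 5, 300)[:, None], size=(300, 400)).astype(float)
        out = neighborhood_variable_genes(X, mode="dropout")
        assert out["variable"].mean() <= 0.01

    def test_planted_de_genes_recovered(self):
        rng = np.random.default_rng(5)
        n_genes, n = 350, 400
        # background genes span a range of means so the trend is anchored
        lam = np.tile(np.linspace(0.2, 6, n_genes)[:, None], (1, n))
        lam[:50] = 0.5
        lam[:50, : n // 2] = 8.0  # 50 genes shifted in half the cells
        X = rng.poisson(lam).astype(float)
        out = neighborhood_variable_genes(X, mode="sd", threshold=0.5)
        recall = out["variable"].to_numpy()[:50].mean()
        assert recall >= 0.8
        false_pos = out["variable"].to_numpy()[50:].mean()
        assert false_pos < 0.2

    def test_on_trend_gene_not_variable(self):
        rng = np.random.default_rng(6)
        X = rng.poisson(2.0, size=(100, 200)).astype(float)
        out = neighborhood_variable_genes(X, mode="sd")
        # iid genes: residuals hover near 0, none exceed the 0.5 threshold
        assert np.abs(out["residual"]).median() < 0.1

    def test_small_subset_rejected(self):
        with pytest.raises(ValueError, match="50"):
            neighborhood_variable_genes(np.ones((10, 20)), mode="sd")


class TestPerturbationScore:
    def _data(self, effect=1.0, n=200, n_genes=150, seed=7):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, size=(n_genes, n))
        cond = np.array(["day0"] * (n // 2) + ["day3"] * (n // 2), dtype=object)
        X[:62, cond == "day3"] += effect  # planted 62-gene response
        ct = np.array(["T"] * n, dtype=object)
        return X, cond, ct

    def test_null_permutation_finds_no_response(self):
        X, cond, ct = self._data(effect=0.0)
        out = perturbation_score(X, cond, ct, "T")
        assert out.status == "no response detected"
        assert np.allclose(out.cell_scores, 0)

    def test_planted_shift_separates_conditions(self):
        X, cond, ct = self._data(effect=1.0)
        out = perturbation_score(X, cond, ct, "T")
        assert out.status == "ok"
        a = out.cell_scores[cond == "day0"]
        b = out.cell_scores[cond == "day3"]
        pooled_sd = np.sqrt((a.var() + b.var()) / 2)
        assert (b.mean() - a.mean()) / pooled_sd > 3

    def test_pseudobulk_projection_arithmetic(self):
        X, cond, ct = self._data(effect=1.5)
        out = perturbation_score(X, cond, ct, "T")
        keep = np.isin(np.arange(X.shape[0]), out.genes)
        mu_a = X[keep][:, cond == "day0"].mean(axis=1)
        mu_b = X[keep][:, cond == "day3"].mean(axis=1)
        delta = mu_b - mu_a
        # a hypothetical cell at each pseudobulk: score gap equals ||delta||
        gap = (mu_b @ out.vector) - (mu_a @ out.vector)
        assert np.isclose(gap, np.linalg.norm(delta))
        assert np.isclose(np.linalg.norm(out.vector), 1.0)

    def test_too_few_cells_errors(self):
        X, cond, ct = self._data(n=30)
        with pytest.raises(ValueError, match="cells each"):
            perturbation_score(X, cond, ct, "T")


class TestMarkerPanel:
    def _toy(self, seed=8, n=600):
        rng = np.random.default_rng(seed)
        labels = np.array(
            ["target"] * (n // 10) + ["restA"] * (n // 2) + ["restB"] * (n - n // 10 - n // 2),
            dtype=object,
        )
        X = rng.normal(0, 1, size=(8, n))
        X[0, labels == "target"] += 6.0  # perfectly separating protein
        return X, labels

    def test_separating_protein_chosen_first_with_full_enrichment(self):
        X, labels = self._toy()
        panel = select_marker_panel(X, labels, "target", max_size=3, seed=0)
        assert panel.markers[0] == "p0"
        first = panel.metrics.iloc[0]
        assert first["precision"] > 0.95 and first["recall"] > 0.95
        # after downsampling the three clusters are capped equally, so the
        # maximal enrichment is 1/prevalence = 3
        assert first["enrichment"] > 2.5

    def test_greedy_picks_best_candidate_each_round(self):
        X, labels = self._toy()
        panel = select_marker_panel(X, labels, "target", max_size=4, seed=0)
        assert len(panel.markers) == 4
        assert len(set(panel.markers)) == 4

    def test_all_noise_enrichment_near_one(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(6, 500))
        labels = np.array(["t"] * 50 + ["o"] * 450, dtype=object)
        panel = select_marker_panel(X, labels, "t", max_size=2, seed=0)
        assert panel.metrics["enrichment"].iloc[-1] < 3.0

    def test_first_markers_positive(self):
        X, labels = self._toy()
        panel = select_marker_panel(X, labels, "target", max_size=6, seed=0)
        assert all(panel.positive[: min(5, len(panel.markers))])
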