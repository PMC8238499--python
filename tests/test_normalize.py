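import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from multiweave import (
    CountsMatrix,
    RankError,
    ZeroLibraryError,
    build_knn,
    clr_normalize,
    flag_intra_sample_doublets,
    log_normalize,
    lsi_embed,
    pca_embed,
    tfidf,
    view_from_scores,
)

counts_matrices = hnp.arrays(
    float,
    st.tuples(st.integers(2, 8), st.integers(2, 8)),
    elements=st.integers(0, 50).map(float),
)


class TestLogNormalize:
    def test_hand_evaluated_entry(self):
        # one cell, counts (5, 5), scale 10: both entries ln(1 + 10*5/10)
        out = log_normalize(np.array([[5.0], [5.0]]), scale_factor=10)
        assert np.allclose(out, np.log(1 + 5))

    def test_zero_rows_stay_zero_and_sparse_dense_agree(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(2.0, size=(20, 15)).astype(float)
        x[3] = 0.0
        x[:, 4] = 0.0
        x[0, 4] = 1.0  # avoid a zero library
        dense = log_normalize(x)
        sparse = log_normalize(sp.csr_matrix(x))
        assert np.allclose(dense, sparse.toarray())
        assert np.all(dense[3] == 0)

    def test_zero_library_cell_rejected(self):
        x = np.array([[1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ZeroLibraryError):
            log_normalize(x)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(counts_matrices)
    def test_invariant_to_per_cell_rescaling(self, x):
        x = x + 1  # avoid zero libraries; keeps counts positive
        scaled = x * np.arange(2, x.shape[1] + 2)[None, :]
        assert np.allclose(log_normalize(x), log_normalize(scaled))


class TestClr:
    def test_constant_column_maps_to_zero(self):
        out = clr_normalize(np.full((4, 3), 7.0))
        assert np.allclose(out, 0.0)

    def test_hand_evaluated_column(self):
        # column (0, e-1): ln1=0, ln e=1, mean 0.5 -> (-0.5, +0.5)
        out = clr_normalize(np.array([[0.0], [np.e - 1]]))
        assert np.allclose(out.ravel(), [-0.5, 0.5])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(counts_matrices)
    def test_columns_sum_to_zero(self, x):
        out = clr_normalize(x)
        assert np.all(np.abs(out.sum(axis=0)) < 1e-9)

    def test_feature_margin_centers_rows(self):
        rng = np.random.default_rng(0)
        out = clr_normalize(rng.poisson(3, (5, 9)).astype(float), margin="feature")
        assert np.all(np.abs(out.sum(axis=1)) < 1e-9)


class TestTfidf:
    def test_single_entry_formula(self):
        out, keep = tfidf(np.array([[1.0]]))
        assert keep.all()
        assert np.allclose(out.toarray(), np.log(1 + 1e4))

    def test_zero_entries_stay_zero_and_cell_scaling_invariance(self):
        rng = np.random.default_rng(2)
        dense = rng.integers(0, 4, size=(30, 20)).astype(float)
        dense[np.arange(20) % 30, np.arange(20)] += 1  # no zero libraries
        x = sp.csr_matrix(dense)
        out, _ = tfidf(x)
        assert np.array_equal(out.toarray() != 0, dense != 0)
        # per-cell rescaling invariance holds under the binary (document
        # frequency) IDF dialect, where scaling cannot change detection
        out_b, _ = tfidf(x, idf="binary")
        dense2 = dense.copy()
        dense2[:, 0] *= 3.0
        out2_b, _ = tfidf(sp.csr_matrix(dense2), idf="binary")
        assert np.allclose(out2_b.toarray(), out_b.toarray())
        # under the default total-count IDF, the scaled cell's TF is
        # unchanged and only the global IDF shifts
        tf0 = dense[:, 0] / dense[:, 0].sum()
        tf0_scaled = dense2[:, 0] / dense2[:, 0].sum()
        assert np.allclose(tf0, tf0_scaled)

    def test_zero_peak_dropped_with_warning(self):
        x = np.array([[1.0, 2.0], [0.0, 0.0], [3.0, 1.0]])
        with pytest.warns(UserWarning, match="zero total accessibility"):
            out, keep = tfidf(x)
        assert keep.tolist() == [True, False, True]
        assert out.shape == (2, 2)


class TestPcaEmbed:
    def test_matches_dense_svd_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 10))  # features x cells
        view = pca_embed(X, d=5, center_scale=False)
        Z = X.T - X.T.mean(axis=0)
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
        oracle = U[:, :5] * S[:5]
        # agreement up to per-component sign
        for j in range(5):
            col, ref = view.scores[:, j], oracle[:, j]
            assert min(np.abs(col - ref).max(), np.abs(col + ref).max()) < 1e-8

    def test_embedding_rows_unit_norm(self):
        rng = np.random.default_rng(5)
        view = pca_embed(rng.normal(size=(15, 40)), d=4)
        norms = np.linalg.norm(view.embedding, axis=1)
        assert np.all(np.abs(norms - 1) < 1e-9)

    def test_rank_deficient_request_errors(self):
        # 3 distinct centroids, no noise: rank 2 after centering
        C = np.array([[0.0, 0], [5, 0], [0, 5]])
        X = C[np.repeat(np.arange(3), 10)].T  # 2 features x 30 cells... need more features
        X = np.vstack([X, X, X])  # 6 x 30, still rank 2 after centering
        with pytest.raises(RankError, match="rank"):
            pca_embed(X, d=5, center_scale=False)


class TestLsiEmbed:
    def test_components_standardized_and_drop_first(self):
        rng = np.random.default_rng(6)
        x = np.abs(rng.normal(size=(40, 25))) + 0.1
        out, _ = tfidf(x)
        view = lsi_embed(out, d=5, drop_first=True)
        assert view.scores.shape == (25, 5)
        assert np.allclose(view.scores.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(view.scores.std(axis=0), 1, atol=1e-9)

    def test_full_rank_no_drop_matches_svd_oracle(self):
        rng = np.random.default_rng(7)
        Z = rng.normal(size=(12, 8))  # features x cells, rank 8
        view = lsi_embed(Z, d=8, drop_first=False)
        U, S, Vt = np.linalg.svd(Z.T, full_matrices=False)
        oracle = U * S
        oracle = (oracle - oracle.mean(0)) / oracle.std(0)
        for j in range(8):
            col, ref = view.scores[:, j], oracle[:, j]
            assert min(np.abs(col - ref).max(), np.abs(col + ref).max()) < 1e-6

    def test_depth_confound_removed(self):
        # first singular direction tracks per-cell depth; retained components
        # should be near-uncorrelated with depth
        rng = np.random.default_rng(8)
        n = 120
        depth = rng.uniform(0.5, 3.0, n)
        base = np.abs(rng.normal(1, 0.3, size=(50, n)))
        signal = np.zeros((50, n))
        signal[:10, : n // 2] += 0.8
        X = (base + signal) * depth[None, :] * 20
        out, _ = tfidf(X)
        view = lsi_embed(out, d=4, drop_first=True)
        for j in range(4):
            r = np.corrcoef(view.scores[:, j], depth)[0, 1]
            assert abs(r) < 0.2


class TestDoubletFlagging:
    def _graph(self):
        rng = np.random.default_rng(9)
        emb = view_from_scores(rng.normal(size=(50, 3)))
        return build_knn(emb, k=20)

    def test_no_known_doublets_no_flags(self):
        g = self._graph()
        known = np.zeros(50, dtype=bool)
        assert not flag_intra_sample_doublets(g, known).any()

    def test_strict_threshold_arithmetic(self):
        # hand-built neighbor lists: k=20, cell 0 has 5 doublet neighbors
        # (25% -> flagged), cell 1 has 4 (20% -> not flagged)
        from multiweave import NeighborGraph

        n, k = 30, 20
        pool = np.arange(2, 2 + k + 1)  # one spare to dodge self edges
        indices = np.array([pool[pool != i][:k] for i in range(n)])
        known = np.zeros(n, dtype=bool)
        known[2:7] = True  # 5 of cell 0's neighbors
        g = NeighborGraph(indices=indices, distances=np.zeros((n, k)), k=k)
        flags = flag_intra_sample_doublets(g, known, threshold=0.20)
        assert flags[0]
        known4 = np.zeros(n, dtype=bool)
        known4[2:6] = True
        flags4 = flag_intra_sample_doublets(g, known4, threshold=0.20)
        assert not flags4[1]

    def test_monotone_in_threshold_and_bounds(self):
        g = self._graph()
        rng = np.random.default_rng(10)
        known = rng.random(50) < 0.3
        prev = None
        for t in (0.05, 0.2, 0.5, 0.9):
            f = flag_intra_sample_doublets(g, known, threshold=t)
            assert f[known].all()
            if prev is not None:
                assert f.sum() <= prev
            prev = f.sum()
        with pytest.raises(ValueError):
            flag_intra_sample_doublets(g, known, threshold=1.5)


def test_counts_matrix_validation():
    with pytest.raises(ValueError, match="non-negative"):
        CountsMatrix(np.array([[-1.0]]), ["f"], ["c"])
    with pytest.raises(ValueError, match="unique"):
        CountsMatrix(np.ones((1, 2)), ["f"], ["c", "c"])
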