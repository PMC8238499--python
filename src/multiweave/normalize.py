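"""Per-modality normalization and dimensional reduction.

Each modality is normalized by the convention standard for its data type —
library-size log-normalization for transcriptomes, the centered log-ratio
(CLR) transform for antibody-derived-tag panels, and TF-IDF for chromatin
accessibility peak matrices — then reduced with PCA (RNA/protein) or LSI
(ATAC) and L2-normalized row-wise into a :class:`ModalityView`.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp

from ._errors import RankError, ZeroLibraryError
from .containers import CountsMatrix, ModalityView, as_dense, l2_normalize_rows

__all__ = [
    "log_normalize",
    "clr_normalize",
    "tfidf",
    "pca_embed",
    "lsi_embed",
    "flag_intra_sample_doublets",
]


def _values(counts):
    return counts.values if isinstance(counts, CountsMatrix) else counts


def _colsums(x) -> np.ndarray:
    if sp.issparse(x):
        return np.asarray(x.sum(axis=0)).ravel()
    return np.asarray(x, dtype=float).sum(axis=0)


def log_normalize(counts, scale_factor: float = 1e4):
    """Library-size normalize and log-transform counts.

    Each entry becomes ``ln(1 + scale_factor * x / library_size)`` where the
    library size is the cell's column sum. Zero counts map to zero, so the
    sparsity pattern is preserved.

    Raises
    ------
    ZeroLibraryError
        If any cell has a zero library size. QC filtering is the caller's
        responsibility; all-zero cells are never dropped silently.
    """
    x = _values(counts)
    libs = _colsums(x)
    if np.any(libs == 0):
        bad = np.flatnonzero(libs == 0)
        raise ZeroLibraryError(
            f"{bad.size} cell(s) have zero total counts (first: index {bad[0]})"
        )
    if sp.issparse(x):
        out = x.tocsc(copy=True).astype(float)
        # scale each column by scale_factor / library, then log1p on the data
        out = out @ sp.diags(scale_factor / libs)
        out.data = np.log1p(out.data)
        return out.tocsr()
    x = np.asarray(x, dtype=float)
    return np.log1p(scale_factor * x / libs[None, :])


def clr_normalize(counts, margin: str = "cell"):
    """Centered log-ratio transform.

    The dialect implemented is: within each cell, ``ln(x + 1)`` centered by
    the mean of ``ln(x + 1)`` over features, using the natural log and a
    pseudocount of 1 (so zeros need no special handling). Output columns sum
    to zero. ``margin="feature"`` centers within each feature instead, for
    workflows that prefer the across-cell dialect.
    """
    x = as_dense(_values(counts))
    lx = np.log1p(x)
    if margin == "cell":
        return lx - lx.mean(axis=0, keepdims=True)
    if margin == "feature":
        return lx - lx.mean(axis=1, keepdims=True)
    raise ValueError("margin must be 'cell' or 'feature'")


def tfidf(counts, scale_factor: float = 1e4, idf: str = "total"):
    """TF-IDF reweighting of a peak accessibility matrix.

    TF is each peak's count divided by the cell's total accessibility. Two
    IDF dialects are offered: ``total`` (default) divides the number of
    cells by the peak's total count across cells, and ``binary`` divides by
    the number of cells in which the peak is detected (the classic document
    frequency; invariant to per-cell count rescaling). The product is scaled
    by ``scale_factor`` and log1p-transformed, preserving the sparsity
    pattern. Peaks with zero total accessibility (undefined IDF) are dropped
    with a warning.

    Returns (tfidf_matrix, kept_row_mask).
    """
    if idf not in ("total", "binary"):
        raise ValueError("idf must be 'total' or 'binary'")
    x = _values(counts)
    x = sp.csr_matrix(x, dtype=float)
    libs = _colsums(x)
    if np.any(libs == 0):
        bad = np.flatnonzero(libs == 0)
        raise ZeroLibraryError(
            f"{bad.size} cell(s) have zero total accessibility (first: index {bad[0]})"
        )
    row_tot = np.asarray(x.sum(axis=1)).ravel()
    keep = row_tot > 0
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} peak(s) with zero total accessibility"
        )
        x = x[keep]
        row_tot = row_tot[keep]
    n_cells = x.shape[1]
    if idf == "total":
        idf_vec = n_cells / row_tot
    else:
        n_detected = np.asarray((x > 0).sum(axis=1)).ravel()
        idf_vec = n_cells / n_detected
    out = sp.diags(idf_vec) @ x @ sp.diags(1.0 / libs)
    out = out.tocsr()
    out.data = np.log1p(scale_factor * out.data)
    return out, keep


def _svd_scores(Z: np.ndarray, n_comp: int, seed: int):
    """Top components of a (cells x features) matrix; deterministic signs.

    Full LAPACK SVD below 1,000 in the smaller dimension, seeded truncated
    SVD beyond. Returns (scores cells x n_comp, singular values).
    """
    if min(Z.shape) <= 1000:
        U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    else:
        from scipy.sparse.linalg import svds

        rng = np.random.default_rng(seed)
        v0 = rng.standard_normal(min(Z.shape))
        U, S, Vt = svds(Z, k=n_comp, v0=v0)
        order = np.argsort(S)[::-1]
        U, S, Vt = U[:, order], S[order], Vt[order]
    U, S, Vt = U[:, :n_comp], S[:n_comp], Vt[:n_comp]
    # sign convention: largest-magnitude loading of each component positive
    flips = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    flips[flips == 0] = 1.0
    return U * (S * flips)[None, :], S


def pca_embed(
    normalized,
    d: int,
    center_scale: bool = True,
    modality_tag: str = "other",
    seed: int = 42,
) -> ModalityView:
    """PCA on a normalized features x cells matrix, L2-normalized scores.

    Features are centered and (by default) scaled to unit variance before the
    decomposition; constant features are left unscaled. The top-``d`` cell
    scores are then row-L2-normalized into the embedding.
    """
    X = as_dense(normalized)
    n_feat, n_cells = X.shape
    if d >= min(n_feat, n_cells):
        raise RankError(
            f"d={d} must be below min(features, cells)={min(n_feat, n_cells)}"
        )
    Z = X.T - X.mean(axis=1)[None, :]
    if center_scale:
        sd = Z.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Z = Z / sd
    scores, S = _svd_scores(Z, d, seed)
    rank = int(np.sum(S > max(Z.shape) * np.finfo(float).eps * (S[0] if S.size else 1)))
    if d > rank:
        raise RankError(f"requested d={d} components but attainable rank is {rank}")
    emb, zero = l2_normalize_rows(scores)
    return ModalityView(
        embedding=emb,
        d=d,
        reduction_tag="pca",
        normalized=normalized,
        scores=scores,
        modality_tag=modality_tag,
        zero_rows=zero,
    )


def lsi_embed(
    tfidf_matrix,
    d: int,
    drop_first: bool = True,
    modality_tag: str = "atac",
    seed: int = 42,
) -> ModalityView:
    """Latent semantic indexing of a TF-IDF matrix.

    Decomposes the features x cells TF-IDF matrix by SVD, standardizes each
    retained component's cell scores to mean 0 / sd 1, and (by default) drops
    the first component, which typically tracks per-cell sequencing depth.
    ``d`` counts the components retained after the drop.
    """
    X = tfidf_matrix
    Z = as_dense(X).T  # cells x features; no centering for LSI
    n_comp = d + (1 if drop_first else 0)
    if n_comp > min(Z.shape):
        raise RankError(
            f"need {n_comp} components but min(features, cells)={min(Z.shape)}"
        )
    scores, S = _svd_scores(Z, n_comp, seed)
    tol = max(Z.shape) * np.finfo(float).eps * (S[0] if S.size else 1.0)
    if np.sum(S > tol) < n_comp:
        raise RankError(
            f"requested {n_comp} components but attainable rank is {int(np.sum(S > tol))}"
        )
    if drop_first:
        scores = scores[:, 1:]
    sd = scores.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise RankError("constant LSI component (sd 0); reduce d")
    scores = (scores - scores.mean(axis=0)) / sd
    emb, zero = l2_normalize_rows(scores)
    return ModalityView(
        embedding=emb,
        d=d,
        reduction_tag="lsi",
        normalized=tfidf_matrix,
        scores=scores,
        modality_tag=modality_tag,
        zero_rows=zero,
    )


def flag_intra_sample_doublets(graph, known_doublet, threshold: float = 0.20):
    """Flag cells whose neighborhoods are dominated by verified doublets.

    A cell is flagged when the fraction of its k nearest neighbors (on the
    protein embedding, by convention) that are verified doublets strictly
    exceeds ``threshold``. Verified doublets remain flagged.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    known = np.asarray(known_doublet, dtype=bool)
    frac = known[graph.indices].mean(axis=1)
    return known | (frac > threshold)
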