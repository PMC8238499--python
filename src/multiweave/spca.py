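"""Supervised PCA against a cell-cell similarity kernel.

Ordinary PCA finds the directions of maximal variance in the expression
matrix; supervised PCA instead finds orthonormal feature loadings U that
maximize the Hilbert-Schmidt Independence Criterion between the kernel of
the projected data and a response kernel L,

    argmax_U  tr(U^T X H L H X^T U)   subject to  U^T U = I,

where H = I - n^-1 e e^T centers over cells. The closed-form solution is
the top-d eigenvectors of X H L H X^T. Setting L to the Jaccard SNN matrix
of a WNN graph makes the learned transcriptomic components those that best
reproduce the multimodal neighborhood structure, and the fitted loadings
project any expression-only query into the same space.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

from ._errors import RankError
from .containers import as_dense, l2_normalize_rows

__all__ = ["SpcaModel", "spca_fit", "spca_project", "select_variable_features"]


@dataclass
class SpcaModel:
    """Fitted supervised-PCA transformation.

    U has orthonormal columns (features x d); eigenvalues are descending.
    ``centering_means`` are the per-feature means of the training matrix and
    are subtracted before projection.
    """

    U: np.ndarray
    eigenvalues: np.ndarray
    feature_ids: list
    centering_means: np.ndarray
    trained_on: dict

    @property
    def d(self) -> int:
        return self.U.shape[1]

    def reference_embedding(self) -> np.ndarray:
        """Training-cell scores (cells x d), rows L2-normalized."""
        return self.trained_on["embedding"]


def spca_fit(X, L, d: int, feature_ids: Optional[Sequence[str]] = None) -> SpcaModel:
    """Fit supervised PCA of a features x cells matrix against kernel L.

    L (cells x cells, typically the WNN Jaccard SNN matrix) is symmetrized
    if needed and kept sparse; the eigenproblem is solved on the
    features x features matrix Xc L Xc^T where Xc is the per-feature
    cell-centered data, so no dense n x n product is formed.
    """
    X = as_dense(X)
    n_feat, n_cells = X.shape
    if L.shape != (n_cells, n_cells):
        raise ValueError(f"kernel is {L.shape}, expected ({n_cells}, {n_cells})")
    if d > n_feat:
        raise RankError(f"d={d} exceeds the number of features ({n_feat})")
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(n_feat)]
    if len(feature_ids) != n_feat:
        raise ValueError("feature_ids length mismatch")
    Lx = sp.csr_matrix(L) if not sp.issparse(L) else L.tocsr()
    Lx = (Lx + Lx.T) * 0.5
    means = X.mean(axis=1)
    Xc = X - means[:, None]
    # Xc already absorbs one H; the second H acts on L's other side:
    # Xc L Xc^T == (XH) L (XH)^T because H is symmetric and idempotent here
    M = Xc @ (Lx @ Xc.T)
    M = (M + M.T) * 0.5
    evals, evecs = np.linalg.eigh(M)
    evals, evecs = evals[::-1], evecs[:, ::-1]
    tol = n_feat * np.finfo(float).eps * max(abs(evals[0]), 1.0)
    attainable = int(np.sum(evals > tol))
    if d > attainable:
        raise RankError(
            f"requested d={d} components but the numerical rank of XHLHX^T is {attainable}"
        )
    U = evecs[:, :d]
    # deterministic sign: largest-magnitude entry of each loading positive
    flips = np.sign(U[np.abs(U).argmax(axis=0), np.arange(d)])
    flips[flips == 0] = 1.0
    U = U * flips[None, :]
    scores = (U.T @ Xc).T
    emb, _ = l2_normalize_rows(scores)
    fingerprint = {
        "n_features": n_feat,
        "n_cells": n_cells,
        "sum": float(X.sum()),
        "embedding": emb,
        "scores": scores,
    }
    return SpcaModel(
        U=U,
        eigenvalues=evals[:d],
        feature_ids=list(feature_ids),
        centering_means=means,
        trained_on=fingerprint,
    )


def spca_project(
    model: SpcaModel,
    X_query,
    query_feature_ids: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Project a query expression matrix into the fitted sPCA space.

    Query features are matched to the model's by id; features missing from
    the query contribute 0 after centering. Returns cells x d scores with
    L2-normalized rows.
    """
    Xq = as_dense(X_query)
    if query_feature_ids is None:
        if Xq.shape[0] != len(model.feature_ids):
            raise ValueError(
                "query has a different feature count and no feature ids were given"
            )
        query_feature_ids = model.feature_ids
    pos = {f: i for i, f in enumerate(query_feature_ids)}
    hits = [(j, pos[f]) for j, f in enumerate(model.feature_ids) if f in pos]
    if not hits:
        raise ValueError("no overlap between query and model features")
    overlap = len(hits) / len(model.feature_ids)
    if overlap < 0.5:
        warnings.warn(f"only {overlap:.0%} of model features found in the query")
    rows_model, rows_query = map(np.array, zip(*hits))
    n_q = Xq.shape[1]
    aligned = np.zeros((len(model.feature_ids), n_q))
    aligned[rows_model] = Xq[rows_query] - model.centering_means[rows_model, None]
    scores = (model.U.T @ aligned).T
    emb, _ = l2_normalize_rows(scores)
    return emb


def select_variable_features(X, n_top: int = 2000, feature_ids=None):
    """Top features by standardized dispersion (variance / mean z-scored
    within 20 mean-abundance bins), the standard variable-gene heuristic.

    Returns (row indices, ids or None).
    """
    X = as_dense(X)
    mean = X.mean(axis=1)
    var = X.var(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    order = np.argsort(mean)
    bins = np.array_split(order, 20)
    z = np.zeros_like(disp)
    for b in bins:
        if b.size == 0:
            continue
        mu, sd = disp[b].mean(), disp[b].std()
        z[b] = (disp[b] - mu) / (sd if sd > 0 else 1.0)
    top = np.argsort(z)[::-1][: min(n_top, X.shape[0])]
    top = np.sort(top)
    ids = [feature_ids[i] for i in top] if feature_ids is not None else None
    return top, ids
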