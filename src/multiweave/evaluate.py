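"""Evaluation and downstream procedures built on the integrated graph:
graph clustering, noise-robustness simulation, cross-cluster edge counts,
neighbor-prediction benchmarking, neighborhood-homogeneity metrics, the
perturbation score, and targeted marker-panel selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .containers import as_dense
from .neighbors import NeighborGraph
from .wnn import WnnGraph

__all__ = [
    "cluster_graph",
    "add_modality_noise",
    "cross_cluster_edges",
    "neighbor_prediction_correlation",
    "neighborhood_variable_genes",
    "PerturbationResult",
    "perturbation_score",
    "PanelResult",
    "select_marker_panel",
]


def cluster_graph(snn: sp.spmatrix, resolution: float = 1.0, seed: int = 0) -> np.ndarray:
    """Community detection on a Jaccard-weighted SNN graph.

    Delegated to the Leiden algorithm (RBConfiguration modularity partition),
    the modern successor of smart local moving. Deterministic given a seed.
    """
    import igraph
    import leidenalg

    snn = sp.csr_matrix(snn)
    if snn.shape[0] == 0:
        raise ValueError("empty graph")
    upper = sp.triu(snn, k=1).tocoo()
    g = igraph.Graph(
        n=snn.shape[0],
        edges=list(zip(upper.row.tolist(), upper.col.tolist())),
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=upper.data.tolist(),
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership, dtype=int)


def add_modality_noise(matrix, sd: float, seed: int = 0):
    """Add element-wise independent N(0, sd^2) noise; sd=0 returns the input."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    X = as_dense(matrix)
    if sd == 0:
        return X.copy()
    rng = np.random.default_rng(seed)
    return X + rng.normal(0.0, sd, size=X.shape)


def cross_cluster_edges(graph, labels, a, b, directed: bool = True) -> int:
    """Count graph edges connecting cluster ``a`` to cluster ``b``.

    KNN rows are directed (i -> its neighbors); by default each direction
    counts separately. With ``directed=False`` an i<->j pair present in both
    directions counts once.
    """
    if isinstance(graph, WnnGraph):
        indices = graph.indices
    elif isinstance(graph, NeighborGraph):
        indices = graph.indices
    else:
        indices = np.asarray(graph)
    labels = np.asarray(labels, dtype=object)
    if indices.shape[0] != labels.size:
        raise ValueError("labels do not cover all cells")
    present = set(labels)
    for lab in (a, b):
        if lab not in present:
            raise ValueError(f"unknown label {lab!r}")
    src = np.repeat(labels, indices.shape[1])
    dst = labels[indices.ravel()]
    hit = ((src == a) & (dst == b)) | ((src == b) & (dst == a))
    if directed:
        return int(hit.sum())
    rows = np.repeat(np.arange(indices.shape[0]), indices.shape[1])
    pairs = {
        (min(i, j), max(i, j))
        for i, j in zip(rows[hit], indices.ravel()[hit])
    }
    return len(pairs)


def neighbor_prediction_correlation(graph, features, feature_ids=None) -> pd.DataFrame:
    """Correlation between measured features and their neighbor-average
    predictions — the standard benchmark of how well a graph's neighborhoods
    reflect a feature's structure.

    ``features`` is features x cells; each cell's prediction is the mean of
    the feature over its graph neighbors. Returns a DataFrame with Pearson
    and Spearman correlations per feature; zero-variance features (on either
    side) yield NaN.
    """
    indices = graph.indices if hasattr(graph, "indices") else np.asarray(graph)
    F = as_dense(features)
    if F.shape[1] != indices.shape[0]:
        raise ValueError("features and graph disagree on the cell count")
    pred = F[:, indices.ravel()].reshape(F.shape[0], *indices.shape).mean(axis=2)
    rows = []
    for f in range(F.shape[0]):
        x, y = F[f], pred[f]
        if x.std() == 0 or y.std() == 0:
            rows.append((np.nan, np.nan))
            continue
        rows.append((stats.pearsonr(x, y)[0], stats.spearmanr(x, y)[0]))
    idx = feature_ids if feature_ids is not None else np.arange(F.shape[0])
    return pd.DataFrame(rows, columns=["pearson", "spearman"], index=idx)


def _gaussian_ksmooth(x: np.ndarray, y: np.ndarray, x_eval: np.ndarray, bandwidth: Optional[float]) -> np.ndarray:
    """Local-linear regression with a Gaussian kernel.

    Default bandwidth is Silverman's rule on x. The local-linear form avoids
    the boundary and slope bias of a plain kernel average, which matters on
    the steep part of a dropout curve; where the local fit is singular it
    falls back to the kernel-weighted mean.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if bandwidth is None:
        sd = x.std(ddof=1) if x.size > 1 else 1.0
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        a = min(sd, iqr / 1.349) if iqr > 0 else sd
        bandwidth = 0.9 * max(a, 1e-12) * x.size ** (-1 / 5)
    w = np.exp(-0.5 * ((x_eval[:, None] - x[None, :]) / bandwidth) ** 2)
    s0 = w.sum(axis=1)
    dx = x[None, :] - x_eval[:, None]
    s1 = (w * dx).sum(axis=1)
    s2 = (w * dx**2).sum(axis=1)
    b0 = (w * y[None, :]).sum(axis=1)
    b1 = (w * dx * y[None, :]).sum(axis=1)
    det = s0 * s2 - s1**2
    out = np.full(x_eval.size, y.mean())
    ok = s0 > 0
    out[ok] = b0[ok] / s0[ok]  # kernel-mean fallback
    good = det > 1e-12 * np.maximum(s0 * s2, 1e-300)
    out[good] = (s2[good] * b0[good] - s1[good] * b1[good]) / det[good]
    return out


def neighborhood_variable_genes(
    expr,
    cell_subset=None,
    mode: str = "dropout",
    threshold: Optional[float] = None,
    bandwidth: Optional[float] = None,
    feature_ids=None,
) -> pd.DataFrame:
    """Variable genes within a neighborhood, by excess dropout or excess sd.

    Fits a Gaussian-kernel trend of the per-gene dropout rate (``dropout``
    mode) or per-gene sd (``sd`` mode) against pseudobulk mean expression and
    flags genes whose residual exceeds the threshold (0.1 for dropout, 0.5
    for sd by default). Fewer variable genes means a more homogeneous
    neighborhood. All-zero genes are excluded.
    """
    X = as_dense(expr)
    if cell_subset is not None:
        X = X[:, np.asarray(cell_subset)]
    if X.shape[1] < 50:
        raise ValueError(f"need at least 50 cells, got {X.shape[1]}")
    if mode not in ("dropout", "sd"):
        raise ValueError("mode must be 'dropout' or 'sd'")
    if threshold is None:
        threshold = 0.1 if mode == "dropout" else 0.5
    nonzero = X.sum(axis=1) > 0
    if not nonzero.all():
        warnings.warn(f"excluding {int((~nonzero).sum())} all-zero gene(s)")
    ids = (
        np.asarray(feature_ids, dtype=object)[nonzero]
        if feature_ids is not None
        else np.flatnonzero(nonzero)
    )
    X = X[nonzero]
    mean = X.mean(axis=1)
    metric = (X == 0).mean(axis=1) if mode == "dropout" else X.std(axis=1, ddof=0)
    trend = _gaussian_ksmooth(mean, metric, mean, bandwidth)
    resid = metric - trend
    return pd.DataFrame(
        {
            "mean": mean,
            "metric": metric,
            "trend": trend,
            "residual": resid,
            "variable": resid > threshold,
        },
        index=ids,
    )


@dataclass
class PerturbationResult:
    """Outcome of a perturbation-score computation for one cell type."""

    genes: list
    vector: np.ndarray  # unit norm over the kept genes (empty if no response)
    cell_scores: np.ndarray  # projection magnitude per target-type cell
    cell_index: np.ndarray  # positions of the target-type cells
    summary: pd.DataFrame  # mean score per condition
    status: str  # "ok" or "no response detected"


def perturbation_score(
    expr,
    condition,
    celltype,
    target_type,
    p_thresh: float = 0.1,
    min_cells: int = 20,
    feature_ids=None,
) -> PerturbationResult:
    """Magnitude of a condition response within one cell type.

    Within the target cell type, each gene is tested across the two
    conditions with the Wilcoxon rank-sum test; genes at BH-adjusted
    p < ``p_thresh`` form the candidate set. The perturbation vector is the
    unit-normalized difference of the two conditions' pseudobulk means over
    those genes, and each cell's score is the projection of its expression
    onto that vector. An empty candidate set yields a defined zero result
    with status "no response detected".
    """
    from statsmodels.stats.multitest import multipletests

    X = as_dense(expr)
    condition = np.asarray(condition, dtype=object)
    celltype = np.asarray(celltype, dtype=object)
    sel = np.flatnonzero(celltype == target_type)
    if sel.size == 0:
        raise ValueError(f"no cells of type {target_type!r}")
    conds = sorted(set(condition[sel]))
    if len(conds) != 2:
        raise ValueError(f"need exactly two conditions in the target type, got {conds}")
    ca, cb = conds
    ia = sel[condition[sel] == ca]
    ib = sel[condition[sel] == cb]
    if min(ia.size, ib.size) < min_cells:
        raise ValueError(
            f"conditions need >= {min_cells} cells each ({ca}: {ia.size}, {cb}: {ib.size})"
        )
    ids = (
        np.asarray(feature_ids, dtype=object)
        if feature_ids is not None
        else np.arange(X.shape[0])
    )
    pvals = np.ones(X.shape[0])
    for g in range(X.shape[0]):
        xa, xb = X[g, ia], X[g, ib]
        if xa.std() == 0 and xb.std() == 0 and xa.mean() == xb.mean():
            continue
        pvals[g] = stats.ranksums(xa, xb).pvalue
    adj = multipletests(pvals, method="fdr_bh")[1]
    keep = np.flatnonzero(adj < p_thresh)
    conds_df_index = [ca, cb]
    if keep.size == 0:
        zero = np.zeros(sel.size)
        return PerturbationResult(
            genes=[],
            vector=np.zeros(0),
            cell_scores=zero,
            cell_index=sel,
            summary=pd.DataFrame({"mean_score": [0.0, 0.0]}, index=conds_df_index),
            status="no response detected",
        )
    delta = X[keep][:, ib].mean(axis=1) - X[keep][:, ia].mean(axis=1)
    vec = delta / np.linalg.norm(delta)
    scores = X[keep][:, sel].T @ vec
    summary = pd.DataFrame(
        {
            "mean_score": [
                scores[condition[sel] == ca].mean(),
                scores[condition[sel] == cb].mean(),
            ]
        },
        index=conds_df_index,
    )
    return PerturbationResult(
        genes=[ids[g] for g in keep],
        vector=vec,
        cell_scores=scores,
        cell_index=sel,
        summary=summary,
        status="ok",
    )


@dataclass
class PanelResult:
    """Forward-selected marker panel for one target cluster."""

    cluster_id: object
    markers: list  # ordered, best-first
    positive: list  # bool per marker: higher mean in the target cluster
    metrics: pd.DataFrame  # per panel size: cv_score, enrichment, precision, recall
    coefficients: np.ndarray  # fitted coefficients of the full panel model


def _panel_metrics(clf, Z, y, prevalence):
    pred = clf.predict_proba(Z)[:, 1] >= 0.5
    tp = int(np.sum(pred & (y == 1)))
    precision = tp / pred.sum() if pred.sum() else 0.0
    recall = tp / (y == 1).sum()
    enrichment = precision / prevalence if prevalence > 0 else np.nan
    return precision, recall, enrichment


def select_marker_panel(
    adt,
    labels,
    target,
    max_size: int = 10,
    n_positive_required: int = 5,
    max_cluster_frac: float = 0.05,
    cv_folds: int = 5,
    seed: int = 0,
    feature_ids=None,
) -> PanelResult:
    """Greedy forward selection of an immunophenotype gating panel.

    Abundant clusters are first downsampled so no cluster exceeds
    ``max_cluster_frac`` of the retained cells (never below 50 cells per
    cluster). Markers are added one at a time, each round keeping the marker
    that maximizes the cross-validated balanced accuracy of an L2-regularized
    balanced logistic regression; the first ``n_positive_required`` rounds
    consider only positive markers (higher mean in the target cluster). At
    each panel size, an in-silico gate at probability 0.5 yields precision,
    recall, and enrichment (precision divided by target prevalence).
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.model_selection import StratifiedKFold, cross_val_score

    X = as_dense(adt)
    labels = np.asarray(labels, dtype=object)
    if target not in set(labels):
        raise ValueError(f"target label {target!r} not present")
    if len(set(labels)) < 2:
        raise ValueError("need at least two labels")
    ids = (
        list(feature_ids)
        if feature_ids is not None
        else [f"p{j}" for j in range(X.shape[0])]
    )
    rng = np.random.default_rng(seed)
    # downsample abundant clusters
    n = labels.size
    cap = max(int(np.floor(max_cluster_frac * n)), 50)
    keep = []
    for lab in sorted(set(labels)):
        pos = np.flatnonzero(labels == lab)
        if pos.size > cap:
            pos = rng.choice(pos, size=cap, replace=False)
        keep.append(np.sort(pos))
    keep = np.concatenate(keep)
    Xd, y = X[:, keep].T, (labels[keep] == target).astype(int)
    prevalence = y.mean()
    pos_marker = Xd[y == 1].mean(axis=0) > Xd[y == 0].mean(axis=0)

    def cv_score(cols):
        clf = LogisticRegression(class_weight="balanced", C=1.0, max_iter=2000)
        folds = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        return cross_val_score(
            clf, Xd[:, cols], y, cv=folds, scoring="balanced_accuracy"
        ).mean()

    selected: list = []
    rows = []
    for step in range(min(max_size, Xd.shape[1])):
        candidates = [
            j
            for j in range(Xd.shape[1])
            if j not in selected and (step >= n_positive_required or pos_marker[j])
        ]
        if not candidates:
            break
        scored = [(cv_score(selected + [j]), -j) for j in candidates]
        best_score, neg_j = max(scored)
        selected.append(-neg_j)
        clf = LogisticRegression(class_weight="balanced", C=1.0, max_iter=2000)
        clf.fit(Xd[:, selected], y)
        precision, recall, enrichment = _panel_metrics(
            clf, Xd[:, selected], y, prevalence
        )
        rows.append(
            {
                "size": step + 1,
                "marker": ids[selected[-1]],
                "cv_score": best_score,
                "enrichment": enrichment,
                "precision": precision,
                "recall": recall,
            }
        )
    clf = LogisticRegression(class_weight="balanced", C=1.0, max_iter=2000)
    clf.fit(Xd[:, selected], y)
    return PanelResult(
        cluster_id=target,
        markers=[ids[j] for j in selected],
        positive=[bool(pos_marker[j]) for j in selected],
        metrics=pd.DataFrame(rows).set_index("size"),
        coefficients=clf.coef_.ravel(),
    )
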