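"""Weighted-nearest-neighbor integration of simultaneously measured
modalities.

For each cell the procedure asks, per modality: how well does the local
neighborhood defined by *this* modality predict the cell's profile, compared
to the neighborhood defined by each *other* modality? Predictions are simple
neighbor averages in the L2-normalized embedding; prediction errors are
converted to affinities with the exponential kernel used by UMAP (local
connectivity subtracted, cell-specific bandwidth); the within/cross affinity
ratios are softmax-normalized into per-cell modality weights; and a KNN
graph is built under the weighted similarity

    theta_weighted(i, j) = sum_m w_m(i) * theta_m(i, j).

The two-modality functions are thin wrappers over the general M >= 2 path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import scipy.sparse as sp

from .containers import ModalityView
from .neighbors import BandwidthSet, NeighborGraph, build_knn, jaccard_snn

__all__ = [
    "PredictionSet",
    "WeightSet",
    "WnnGraph",
    "modality_predictions",
    "prediction_affinity",
    "modality_weights",
    "wnn_graph",
    "wnn_multi",
]

#: ridge added to the cross-modality affinity in the ratio denominator
EPSILON = 1e-4

#: per-modality candidate-list width for the weighted KNN search
CANDIDATE_WIDTH = 200


@dataclass
class PredictionSet:
    """Neighbor-average predictions of each modality's embedding.

    ``within[m]`` predicts modality m from its own neighbors; ``cross[(m, n)]``
    predicts modality m from modality n's neighbors. Every prediction is the
    arithmetic mean of exactly k neighbor embedding vectors.
    """

    within: List[np.ndarray]
    cross: Dict[Tuple[int, int], np.ndarray]


@dataclass
class WeightSet:
    """Per-cell modality weights plus the intermediate affinities/ratios."""

    weights: np.ndarray  # cells x M, rows sum to 1
    theta_within: np.ndarray  # cells x M
    theta_cross: Dict[Tuple[int, int], np.ndarray]  # (m, n) -> affinity of m via n's knn
    ratios: Dict[Tuple[int, int], np.ndarray]
    epsilon: float = EPSILON
    modality_names: Optional[Sequence[str]] = None

    @property
    def n_modalities(self) -> int:
        return self.weights.shape[1]


@dataclass
class WnnGraph:
    """Weighted-nearest-neighbor graph: top-k cells by weighted similarity.

    Similarities lie in (0, 1] and are non-increasing along each row; the
    neighbors of cell i are drawn only from the union of its per-modality
    candidate lists. ``distance = 1 - similarity`` for consumers that want a
    distance graph.
    """

    indices: np.ndarray  # cells x k
    similarities: np.ndarray  # cells x k, descending
    k: int
    candidate_width: int

    def snn(self, prune: float = 0.0, include_self: bool = True) -> sp.csr_matrix:
        """Jaccard shared-neighbor matrix of the weighted graph."""
        return jaccard_snn(self.indices, prune=prune, include_self=include_self)

    def as_neighbor_graph(self) -> NeighborGraph:
        """The weighted graph with 1 - similarity as the distance."""
        return NeighborGraph(
            indices=self.indices, distances=1.0 - self.similarities, k=self.k
        )


def _check_cells(views: Sequence[ModalityView], graphs: Sequence[NeighborGraph]):
    ns = {v.n_cells for v in views} | {g.n_cells for g in graphs}
    if len(ns) != 1:
        raise ValueError(f"modalities disagree on the cell set: sizes {sorted(ns)}")
    ks = {g.k for g in graphs}
    if len(ks) != 1:
        raise ValueError(f"neighbor graphs disagree on k: {sorted(ks)}")


def modality_predictions(
    views: Sequence[ModalityView], graphs: Sequence[NeighborGraph]
) -> PredictionSet:
    """Within- and cross-modality neighbor-average predictions."""
    _check_cells(views, graphs)
    M = len(views)
    within = [views[m].embedding[graphs[m].indices].mean(axis=1) for m in range(M)]
    cross = {
        (m, n): views[m].embedding[graphs[n].indices].mean(axis=1)
        for m in range(M)
        for n in range(M)
        if m != n
    }
    return PredictionSet(within=within, cross=cross)


def prediction_affinity(
    view: ModalityView, predictions: np.ndarray, bandwidths: BandwidthSet
) -> np.ndarray:
    """Exponential-kernel affinity between cells and their predicted profiles.

    theta_i = exp(-max(d(x_i, xhat_i) - d_first_i, 0) / (sigma_i - d_first_i)).
    The local-connectivity offset d_first_i (distance to the first neighbor)
    clamps the affinity to 1 whenever the prediction error does not exceed it.
    """
    d = np.linalg.norm(view.embedding - predictions, axis=1)
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite prediction distances")
    num = np.maximum(d - bandwidths.d_first, 0.0)
    return np.exp(-num / (bandwidths.sigma - bandwidths.d_first))


def _weights(
    views: Sequence[ModalityView],
    graphs: Sequence[NeighborGraph],
    bandwidths: Sequence[BandwidthSet],
    eps: float = EPSILON,
    modality_names: Optional[Sequence[str]] = None,
) -> WeightSet:
    """Softmax modality weights for M >= 2 modalities."""
    _check_cells(views, graphs)
    M = len(views)
    if M < 2:
        raise ValueError("need at least two modalities")
    preds = modality_predictions(views, graphs)
    n = views[0].n_cells
    theta_within = np.column_stack(
        [prediction_affinity(views[m], preds.within[m], bandwidths[m]) for m in range(M)]
    )
    theta_cross = {
        (m, nn): prediction_affinity(views[m], preds.cross[(m, nn)], bandwidths[m])
        for m in range(M)
        for nn in range(M)
        if m != nn
    }
    ratios = {
        key: theta_within[:, key[0]] / (theta_cross[key] + eps) for key in theta_cross
    }
    # softmax over all (m, n) pairs, grouped by m; stabilized per cell
    pair_keys = sorted(ratios)
    S = np.column_stack([ratios[key] for key in pair_keys])
    S = np.exp(S - S.max(axis=1, keepdims=True))
    weights = np.zeros((n, M))
    for j, (m, _) in enumerate(pair_keys):
        weights[:, m] += S[:, j]
    weights /= weights.sum(axis=1, keepdims=True)
    return WeightSet(
        weights=weights,
        theta_within=theta_within,
        theta_cross=theta_cross,
        ratios=ratios,
        epsilon=eps,
        modality_names=modality_names,
    )


def modality_weights(
    views: Sequence[ModalityView],
    graphs: Sequence[NeighborGraph],
    bandwidths: Sequence[BandwidthSet],
    eps: float = EPSILON,
    modality_names: Optional[Sequence[str]] = None,
) -> WeightSet:
    """Per-cell modality weights for two modalities.

    s_m(i) = theta_within,m(i) / (theta_cross,m(i) + eps), softmax-normalized
    so the weights are non-negative and sum to 1 per cell.
    """
    if len(views) != 2:
        raise ValueError("modality_weights is the two-modality path; use wnn_multi")
    return _weights(views, graphs, bandwidths, eps=eps, modality_names=modality_names)


def _candidate_lists(
    views: Sequence[ModalityView], candidate_width: int, seed: int
) -> List[np.ndarray]:
    n = views[0].n_cells
    width = candidate_width
    if width > n - 1:
        warnings.warn(f"candidate_width {width} clamped to n-1={n - 1}")
        width = n - 1
    return [build_knn(v, k=width, seed=seed).indices for v in views]


def wnn_graph(
    views: Sequence[ModalityView],
    weights: WeightSet,
    bandwidths: Sequence[BandwidthSet],
    k: int = 20,
    candidate_width: int = CANDIDATE_WIDTH,
    seed: int = 42,
) -> WnnGraph:
    """KNN graph under the per-cell weighted similarity metric.

    For each cell i, every candidate j in the union of the per-modality
    ``candidate_width``-NN lists is scored with
    theta_weighted(i, j) = sum_m w_m(i) * theta_m(i, j), where theta_m reuses
    the exponential kernel with cell i's bandwidth and local-connectivity
    offset. The similarity is asymmetric in i and j by construction (it uses
    i's weights and kernels); the graph keeps each cell's top-k candidates.
    """
    M = len(views)
    if weights.weights.shape[1] != M:
        raise ValueError("weight set does not match the number of modalities")
    n = views[0].n_cells
    cand = _candidate_lists(views, candidate_width, seed)
    width = cand[0].shape[1]
    embs = [v.embedding for v in views]
    indices = np.empty((n, min(k, width)), dtype=np.int64)
    sims = np.empty((n, min(k, width)))
    if k > width:
        warnings.warn(f"k={k} exceeds the candidate pool; using k={width}")
        k = width
    for i in range(n):
        cands = np.unique(np.concatenate([c[i] for c in cand]))
        score = np.zeros(cands.size)
        for m in range(M):
            d = np.linalg.norm(embs[m][cands] - embs[m][i], axis=1)
            d1, sig = bandwidths[m].d_first[i], bandwidths[m].sigma[i]
            theta = np.exp(-np.maximum(d - d1, 0.0) / (sig - d1))
            score += weights.weights[i, m] * theta
        order = np.lexsort((cands, -score))[:k]
        indices[i] = cands[order]
        sims[i] = score[order]
    return WnnGraph(indices=indices, similarities=sims, k=k, candidate_width=width)


def wnn_multi(
    views: Sequence[ModalityView],
    graphs: Sequence[NeighborGraph],
    bandwidths: Sequence[BandwidthSet],
    k: int = 20,
    candidate_width: int = CANDIDATE_WIDTH,
    eps: float = EPSILON,
    seed: int = 42,
    modality_names: Optional[Sequence[str]] = None,
) -> Tuple[WeightSet, WnnGraph]:
    """Weights and WNN graph for M >= 2 modalities.

    For M = 2 this is exactly the two-modality path (the pairwise-ratio
    softmax reduces to the two-ratio softmax).
    """
    ws = _weights(views, graphs, bandwidths, eps=eps, modality_names=modality_names)
    graph = wnn_graph(
        views, ws, bandwidths, k=k, candidate_width=candidate_width, seed=seed
    )
    return ws, graph
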