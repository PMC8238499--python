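"""End-to-end convenience wrappers around the WNN building blocks."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from .containers import ModalityView
from .neighbors import BandwidthSet, NeighborGraph, build_knn, jaccard_snn, kernel_bandwidth
from .wnn import CANDIDATE_WIDTH, EPSILON, WeightSet, WnnGraph, wnn_multi

__all__ = ["WnnResult", "run_wnn"]


@dataclass
class WnnResult:
    """Everything produced by one WNN run, from per-modality graphs up."""

    views: List[ModalityView]
    graphs: List[NeighborGraph]
    bandwidths: List[BandwidthSet]
    weights: WeightSet
    graph: WnnGraph

    @property
    def modality_weights(self) -> np.ndarray:
        """cells x M weight matrix (rows sum to 1)."""
        return self.weights.weights


def run_wnn(
    views: Sequence[ModalityView],
    k: int = 20,
    candidate_width: int = CANDIDATE_WIDTH,
    n_bw: int = 20,
    eps: float = EPSILON,
    seed: int = 42,
    modality_names: Optional[Sequence[str]] = None,
) -> WnnResult:
    """Run the full WNN procedure on prepared modality views.

    Builds per-modality KNN graphs (k neighbors each), their Jaccard SNN
    matrices, the margin-cell kernel bandwidths, the softmax modality
    weights, and finally the weighted-nearest-neighbor graph.
    """
    views = list(views)
    graphs = [build_knn(v, k=k, seed=seed) for v in views]
    bandwidths = [
        kernel_bandwidth(v, g, jaccard_snn(g), n_bw=n_bw)
        for v, g in zip(views, graphs)
    ]
    weights, graph = wnn_multi(
        views,
        graphs,
        bandwidths,
        k=k,
        candidate_width=candidate_width,
        eps=eps,
        seed=seed,
        modality_names=modality_names,
    )
    return WnnResult(
        views=views,
        graphs=graphs,
        bandwidths=bandwidths,
        weights=weights,
        graph=graph,
    )
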