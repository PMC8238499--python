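"""Reference-query integration: mutual-nearest-neighbor anchors, weighted
vote label transfer, and UMAP placement of query cells.

Both datasets are assumed to live in the same L2-normalized low-dimensional
space (typically a supervised-PCA projection fitted on the reference).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._errors import EmptyAnchorError
from .neighbors import build_knn

__all__ = [
    "AnchorSet",
    "LabelTransfer",
    "find_anchors",
    "transfer_labels",
    "fit_reference_umap",
    "embed_query_umap",
]


@dataclass
class AnchorSet:
    """Mutual-nearest-neighbor reference-query cell pairs with scores."""

    ref_index: np.ndarray
    query_index: np.ndarray
    scores: np.ndarray  # in [0, 1]

    def __len__(self) -> int:
        return self.ref_index.size


@dataclass
class LabelTransfer:
    """Predicted label and per-label score row (summing to 1) per query cell."""

    predicted_label: np.ndarray
    prediction_scores: np.ndarray  # query x labels
    labels: list

    def max_scores(self) -> np.ndarray:
        return self.prediction_scores.max(axis=1)


def _cross_knn(a: np.ndarray, b: np.ndarray, k: int) -> np.ndarray:
    """Indices (len(a) x k) of each a-row's k nearest rows of b."""
    d2 = (
        np.einsum("ij,ij->i", a, a)[:, None]
        + np.einsum("ij,ij->i", b, b)[None, :]
        - 2.0 * a @ b.T
    )
    order = np.argsort(d2, axis=1, kind="stable")
    return order[:, :k]


def find_anchors(
    ref_embedding: np.ndarray,
    query_embedding: np.ndarray,
    k_anchor: int = 5,
    k_score: int = 30,
) -> AnchorSet:
    """Mutual nearest neighbors between reference and query.

    A pair (r, q) is an anchor iff q is among the k_anchor nearest query
    cells of r and r among the k_anchor nearest reference cells of q. Each
    anchor is scored by the Jaccard overlap of the two cells' k_score
    neighborhoods in the combined dataset — a shared-neighbor consistency
    measure already in [0, 1].
    """
    ref = np.asarray(ref_embedding, dtype=float)
    query = np.asarray(query_embedding, dtype=float)
    if ref.shape[1] != query.shape[1]:
        raise ValueError("reference and query embeddings have different dimensions")
    k_anchor = min(k_anchor, ref.shape[0], query.shape[0])
    rq = _cross_knn(ref, query, k_anchor)  # per ref cell: nearest query cells
    qr = _cross_knn(query, ref, k_anchor)
    qr_sets = [set(row) for row in qr]
    pairs = [
        (r, q) for r in range(ref.shape[0]) for q in rq[r] if r in qr_sets[q]
    ]
    if not pairs:
        raise EmptyAnchorError(
            "no mutual-nearest-neighbor anchors found; the datasets may be "
            "disjoint in this space — try a larger k_anchor"
        )
    ri = np.array([p[0] for p in pairs], dtype=np.int64)
    qi = np.array([p[1] for p in pairs], dtype=np.int64)
    combined = np.vstack([ref, query])
    k_sc = min(k_score, combined.shape[0] - 1)
    nn = build_knn(combined, k=k_sc).indices
    scores = np.empty(ri.size)
    for a, (r, q) in enumerate(zip(ri, qi)):
        s_r = set(nn[r])
        s_q = set(nn[ref.shape[0] + q])
        scores[a] = len(s_r & s_q) / len(s_r | s_q)
    return AnchorSet(ref_index=ri, query_index=qi, scores=scores)


def transfer_labels(
    anchors: AnchorSet,
    ref_labels: Sequence,
    query_embedding: np.ndarray,
    k_weight: int = 50,
) -> LabelTransfer:
    """Weighted-vote classification of query cells from anchors.

    Each query cell collects its k_weight nearest anchors (measured to the
    anchors' query-side cells). Each anchor votes for its reference cell's
    label with weight

        exp(-dist^2 / (2 * sigma^2)) * anchor_score,

    a Gaussian kernel whose bandwidth sigma is the distance to the
    k_weight-th selected anchor. Votes are accumulated per label and
    normalized to sum to 1; ties at the argmax resolve to the
    lexicographically first label.
    """
    if len(anchors) == 0:
        raise EmptyAnchorError("cannot transfer labels without anchors")
    query = np.asarray(query_embedding, dtype=float)
    ref_labels = np.asarray(ref_labels, dtype=object)
    label_list = sorted(set(ref_labels[anchors.ref_index]))
    label_pos = {l: j for j, l in enumerate(label_list)}
    anchor_labels = np.array([label_pos[l] for l in ref_labels[anchors.ref_index]])
    anchor_emb = query[anchors.query_index]
    kw = k_weight
    if kw > len(anchors):
        warnings.warn(
            f"k_weight={k_weight} exceeds the {len(anchors)} available anchors; using all"
        )
        kw = len(anchors)
    d2 = (
        np.einsum("ij,ij->i", query, query)[:, None]
        + np.einsum("ij,ij->i", anchor_emb, anchor_emb)[None, :]
        - 2.0 * query @ anchor_emb.T
    )
    np.maximum(d2, 0.0, out=d2)
    order = np.argsort(d2, axis=1, kind="stable")[:, :kw]
    scores = np.zeros((query.shape[0], len(label_list)))
    for i in range(query.shape[0]):
        sel = order[i]
        d = np.sqrt(d2[i, sel])
        sigma = d[-1] if d[-1] > 0 else 1.0
        w = np.exp(-(d**2) / (2.0 * sigma**2)) * anchors.scores[sel]
        if w.sum() == 0:
            w = np.ones_like(w)
        np.add.at(scores[i], anchor_labels[sel], w)
    scores /= scores.sum(axis=1, keepdims=True)
    pred = np.array([label_list[j] for j in scores.argmax(axis=1)], dtype=object)
    return LabelTransfer(predicted_label=pred, prediction_scores=scores, labels=label_list)


def fit_reference_umap(ref_embedding: np.ndarray, seed: int = 42, **umap_kw):
    """Fit a UMAP model on the reference embedding (delegated to umap-learn)."""
    import umap

    reducer = umap.UMAP(random_state=seed, **umap_kw)
    reducer.fit(np.asarray(ref_embedding, dtype=float))
    return reducer


def embed_query_umap(
    ref_umap_model,
    query_embedding: np.ndarray,
    mode: str = "reference",
    ref_embedding: Optional[np.ndarray] = None,
    seed: int = 42,
):
    """Place query cells on a UMAP layout.

    ``reference`` mode transforms query cells through the fitted reference
    model, preserving the reference layout. ``de-novo`` mode refits UMAP on
    the merged embeddings (requires ``ref_embedding``) and returns
    (ref_coords, query_coords) from the fresh layout — useful to reveal
    query populations absent from the reference.
    """
    query = np.asarray(query_embedding, dtype=float)
    if mode == "reference":
        if query.shape[1] != ref_umap_model._raw_data.shape[1]:
            raise ValueError(
                f"query dimension {query.shape[1]} does not match the model's "
                f"input dimension {ref_umap_model._raw_data.shape[1]}"
            )
        return ref_umap_model.transform(query)
    if mode == "de-novo":
        if ref_embedding is None:
            raise ValueError("de-novo mode needs the reference embedding")
        import umap

        ref = np.asarray(ref_embedding, dtype=float)
        if ref.shape[1] != query.shape[1]:
            raise ValueError("reference and query dimensions differ")
        merged = np.vstack([ref, query])
        coords = umap.UMAP(random_state=seed).fit_transform(merged)
        return coords[: ref.shape[0]], coords[ref.shape[0]:]
    raise ValueError("mode must be 'reference' or 'de-novo'")
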