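"""Core in-memory containers shared across the package.

Matrices follow the single-cell genomics convention of features x cells
(genes x cells for RNA, proteins x cells for ADT panels, peaks x cells for
chromatin accessibility). Embeddings are cells x d.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

VALID_MODALITY_TAGS = {"rna", "protein", "atac", "other"}


def as_dense(x) -> np.ndarray:
    """Return ``x`` as a dense float ndarray (no copy when already dense)."""
    if sp.issparse(x):
        return np.asarray(x.todense(), dtype=float)
    return np.asarray(x, dtype=float)


@dataclass
class CountsMatrix:
    """Raw non-negative counts for one modality over a common cell set.

    Parameters
    ----------
    values
        features x cells count matrix (dense or scipy sparse).
    feature_ids, cell_ids
        Row / column identifiers; ``cell_ids`` must be unique.
    modality_tag
        One of ``rna``, ``protein``, ``atac``, ``other``.
    """

    values: object
    feature_ids: Sequence[str]
    cell_ids: Sequence[str]
    modality_tag: str = "other"
    #: False marks already-normalized (possibly signed) data riding in the
    #: same container, e.g. the generator's Gaussian-embedding mode
    is_counts: bool = True

    def __post_init__(self):
        self.feature_ids = list(map(str, self.feature_ids))
        self.cell_ids = list(map(str, self.cell_ids))
        if self.modality_tag not in VALID_MODALITY_TAGS:
            raise ValueError(
                f"modality_tag must be one of {sorted(VALID_MODALITY_TAGS)}, "
                f"got {self.modality_tag!r}"
            )
        nf, nc = self.values.shape
        if nf != len(self.feature_ids):
            raise ValueError(
                f"{len(self.feature_ids)} feature ids for {nf} matrix rows"
            )
        if nc != len(self.cell_ids):
            raise ValueError(f"{len(self.cell_ids)} cell ids for {nc} matrix columns")
        if len(set(self.cell_ids)) != nc:
            raise ValueError("cell_ids must be unique")
        if self.is_counts:
            mn = self.values.min() if not sp.issparse(self.values) else (
                self.values.data.min() if self.values.nnz else 0.0
            )
            if mn < 0:
                raise ValueError("counts must be non-negative")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]


@dataclass
class ModalityView:
    """A normalized modality together with its low-dimensional embedding.

    ``embedding`` rows (cells) are L2-normalized onto the unit sphere; all
    downstream neighbor searches and kernel evaluations use Euclidean
    distance on these unit vectors. ``scores`` keeps the raw (pre
    L2-normalization) component scores for inspection.
    """

    embedding: np.ndarray  # cells x d, unit rows
    d: int
    reduction_tag: str  # {"pca", "lsi", "raw"}
    normalized: Optional[object] = None  # features x cells
    scores: Optional[np.ndarray] = None
    modality_tag: str = "other"
    feature_ids: Optional[Sequence[str]] = None
    zero_rows: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        emb = np.asarray(self.embedding, dtype=float)
        if emb.ndim != 2 or emb.shape[1] != self.d:
            raise ValueError("embedding must be cells x d")
        if self.d < 2:
            raise ValueError("embedding dimension must be >= 2")
        norms = np.linalg.norm(emb, axis=1)
        nonzero = norms > 0
        if np.any(np.abs(norms[nonzero] - 1.0) > 1e-8):
            raise ValueError("embedding rows must be L2-normalized (or zero)")
        if self.zero_rows is None:
            self.zero_rows = ~nonzero
        self.embedding = emb

    @property
    def n_cells(self) -> int:
        return self.embedding.shape[0]


def l2_normalize_rows(scores: np.ndarray):
    """Row-normalize ``scores`` to unit L2 norm; zero rows stay zero.

    Returns (normalized, zero_row_mask).
    """
    scores = np.asarray(scores, dtype=float)
    norms = np.linalg.norm(scores, axis=1, keepdims=True)
    zero = norms[:, 0] == 0
    safe = np.where(norms == 0, 1.0, norms)
    return scores / safe, zero


def view_from_scores(scores: np.ndarray, reduction_tag: str = "raw", **kw) -> ModalityView:
    """Wrap raw component scores into a :class:`ModalityView`."""
    emb, zero = l2_normalize_rows(scores)
    return ModalityView(
        embedding=emb,
        d=emb.shape[1],
        reduction_tag=reduction_tag,
        scores=np.asarray(scores, dtype=float),
        zero_rows=zero,
        **kw,
    )
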