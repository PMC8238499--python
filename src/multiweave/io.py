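"""Readers and writers for the standard single-cell exchange formats.

Counts come in as 10x-style MTX triplets, dense CSV/TSV tables
(features x cells), or h5ad containers; multimodal results go out as a
single AnnData whose X holds the first modality, with additional modalities
in ``obsm``, embeddings in ``obsm``, and graphs in ``obsp``.
"""

from __future__ import annotations

import os
from typing import Dict, Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .containers import CountsMatrix

__all__ = [
    "read_mtx_dir",
    "read_dense_table",
    "simulation_to_anndata",
    "anndata_to_matrices",
    "attach_wnn_result",
]


def read_mtx_dir(path: str, modality_tag: str = "other") -> CountsMatrix:
    """Read a 10x-style triplet directory (matrix.mtx + features/barcodes TSV).

    Accepts ``features.tsv`` or the legacy ``genes.tsv`` name; the matrix is
    features x cells as in CellRanger output.
    """
    from scipy.io import mmread

    mtx = sp.csr_matrix(mmread(os.path.join(path, "matrix.mtx")))
    feat_path = os.path.join(path, "features.tsv")
    if not os.path.exists(feat_path):
        feat_path = os.path.join(path, "genes.tsv")
    features = pd.read_csv(feat_path, sep="\t", header=None)[0].tolist()
    barcodes = pd.read_csv(
        os.path.join(path, "barcodes.tsv"), sep="\t", header=None
    )[0].tolist()
    return CountsMatrix(
        values=mtx, feature_ids=features, cell_ids=barcodes, modality_tag=modality_tag
    )


def read_dense_table(path: str, sep: Optional[str] = None, modality_tag: str = "other") -> CountsMatrix:
    """Read a dense features x cells CSV/TSV with feature rows and cell columns."""
    if sep is None:
        sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return CountsMatrix(
        values=df.to_numpy(dtype=float),
        feature_ids=df.index.tolist(),
        cell_ids=df.columns.tolist(),
        modality_tag=modality_tag,
    )


def simulation_to_anndata(result) -> "anndata.AnnData":
    """Pack a SimResult into one AnnData (cells x features of modality 1;
    further modalities as dense ``obsm`` blocks)."""
    import anndata as ad

    names = list(result.matrices)
    first = result.matrices[names[0]]
    adata = ad.AnnData(
        X=sp.csr_matrix(first.values.T) if sp.issparse(first.values) else np.asarray(first.values).T,
        obs=pd.DataFrame({"label": result.labels}, index=first.cell_ids),
        var=pd.DataFrame(index=first.feature_ids),
    )
    adata.uns["modalities"] = names
    adata.uns["modality_tags"] = {n: result.matrices[n].modality_tag for n in names}
    adata.uns["is_counts"] = {n: bool(result.matrices[n].is_counts) for n in names}
    adata.uns["seed"] = int(result.seed)
    for n in names[1:]:
        m = result.matrices[n]
        adata.obsm[f"mod_{n}"] = np.asarray(
            m.values.todense() if sp.issparse(m.values) else m.values
        ).T
        adata.uns[f"features_{n}"] = list(m.feature_ids)
    return adata


def anndata_to_matrices(adata) -> Dict[str, CountsMatrix]:
    """Recover the per-modality CountsMatrix dict written by
    :func:`simulation_to_anndata`."""
    names = list(adata.uns["modalities"])
    tags = dict(adata.uns.get("modality_tags", {}))
    counts_flags = dict(adata.uns.get("is_counts", {}))
    out = {}
    first = adata.X
    out[names[0]] = CountsMatrix(
        values=first.T if sp.issparse(first) else np.asarray(first).T,
        feature_ids=adata.var_names.tolist(),
        cell_ids=adata.obs_names.tolist(),
        modality_tag=tags.get(names[0], "other"),
        is_counts=bool(counts_flags.get(names[0], True)),
    )
    for n in names[1:]:
        out[n] = CountsMatrix(
            values=np.asarray(adata.obsm[f"mod_{n}"]).T,
            feature_ids=list(adata.uns[f"features_{n}"]),
            cell_ids=adata.obs_names.tolist(),
            modality_tag=tags.get(n, "other"),
            is_counts=bool(counts_flags.get(n, True)),
        )
    return out


def attach_wnn_result(adata, result, modality_names=None) -> None:
    """Write a WnnResult into AnnData slots in place.

    Embeddings land in ``obsm["X_<name>"]``, modality weights in ``obs``,
    the weighted graph in ``obsp`` (connectivities = similarities,
    distances = 1 - similarity), and the derived SNN in
    ``obsp["wnn_snn"]``.
    """
    n = adata.n_obs
    names = list(modality_names) if modality_names else [
        f"mod{m + 1}" for m in range(len(result.views))
    ]
    for name, view in zip(names, result.views):
        adata.obsm[f"X_{name}"] = view.embedding
    for m, name in enumerate(names):
        adata.obs[f"weight_{name}"] = result.modality_weights[:, m]
    g = result.graph
    rows = np.repeat(np.arange(n), g.k)
    conn = sp.csr_matrix((g.similarities.ravel(), (rows, g.indices.ravel())), shape=(n, n))
    dist = sp.csr_matrix(
        (1.0 - g.similarities.ravel(), (rows, g.indices.ravel())), shape=(n, n)
    )
    adata.obsp["wnn_connectivities"] = conn
    adata.obsp["wnn_distances"] = dist
    adata.obsp["wnn_snn"] = g.snn()
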