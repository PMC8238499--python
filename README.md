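# multiweave

Weighted-nearest-neighbor (WNN) integration of multimodal single-cell data,
with supervised-PCA reference mapping and the surrounding evaluation
toolkit.

## Why

Assays like CITE-seq measure a transcriptome and a surface-protein panel in
the same cells, but neither modality is uniformly informative: a small
antibody panel resolves CD4⁺ vs CD8⁺ T cells where their transcriptomes
blend, yet is blind to populations it carries no markers for. Treating the
modalities symmetrically wastes information in both directions. `multiweave`
learns, for every cell, how much each modality should count.

## The method

For each modality *m*, cells get an L2-normalized low-dimensional embedding
(PCA after log-normalization or CLR; LSI after TF-IDF for chromatin) and a
k-nearest-neighbor graph (k = 20). Each cell's profile is then *predicted*
twice per modality — from its own modality's neighbors and from each other
modality's neighbors — and prediction errors become affinities through an
exponential kernel with cell-specific bandwidth σᵢ (mean distance to the 20
lowest-non-zero-Jaccard "margin" cells) and local-connectivity offset:

    θ = exp(−max(d − d₁, 0) / (σᵢ − d₁))

The within/cross affinity ratios s_{m,n} = θ_{m,m}/(θ_{m,n} + ε) are
softmax-normalized into per-cell modality weights w_m(i) ≥ 0, Σ_m w_m(i) = 1,
and a single KNN graph is built under the weighted similarity
θ_weighted(i,j) = Σ_m w_m(i)·θ_m(i,j). The graph's Jaccard SNN matrix feeds
clustering, UMAP — and supervised PCA: the loadings U maximizing the HSIC
dependence tr(UᵀXHLHXᵀU) between projected expression and the multimodal
kernel L, which project any expression-only query into the reference space
for mutual-nearest-neighbor anchoring and weighted-vote label transfer.

See `docs/methods.md` for the full model description, parameter defaults,
and design notes.

## Worked example

```python
import numpy as np
from multiweave import (asymmetric_six, simulate_multimodal, pca_embed,
                        run_wnn, cross_cluster_edges, cluster_graph)

res = simulate_multimodal(asymmetric_six(n_cells=2000, seed=42))
v1 = pca_embed(res.matrices["mod1"].values, 30, seed=42)   # transcriptome-like
v2 = pca_embed(res.matrices["mod2"].values, 18, seed=42)   # protein-panel-like
out = run_wnn([v1, v2], k=20, seed=42)

w = out.modality_weights
print("mean weights:", np.round(w.mean(axis=0), 3))
sel = np.isin(res.labels, ["c0", "c1"])
print("c0/c1 mean modality-2 weight:", round(w[sel, 1].mean(), 3))
print("c0<->c1 cross edges:",
      cross_cluster_edges(out.graphs[0], res.labels, "c0", "c1"), "(mod-1 KNN) vs",
      cross_cluster_edges(out.graph, res.labels, "c0", "c1"), "(WNN)")
```

Output:

```
mean weights: [0.503 0.497]
c0/c1 mean modality-2 weight: 0.902
c0<->c1 cross edges: 6629 (mod-1 KNN) vs 0 (WNN)
```

Globally the two modalities are equally informative (0.503/0.497), but the
cells of the pair that only the protein-like modality can resolve assign it
90% of their weight — and the 6,629 spurious edges blending that pair in the
transcriptome-only graph vanish entirely in the WNN graph. Clustering the
WNN SNN (`cluster_graph(out.graph.snn(), resolution=0.8, seed=0)`) recovers
all six ground-truth clusters exactly (adjusted Rand index 1.0).

A thin CLI covers the shell workflows:

```bash
multiweave simulate --n-cells 2000 --seed 42 --out sim.h5ad
multiweave wnn --input sim.h5ad --dims 30,18 --weights-tsv weights.tsv --out wnn.h5ad
multiweave map --reference sim.h5ad --query query.h5ad --out predictions.tsv
```

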