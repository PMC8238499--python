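# Methods

## The integration problem

Multimodal single-cell assays (CITE-seq, ASAP-seq, 10x multiome) measure two
or more data types — transcriptome, surface-protein panels, chromatin
accessibility — in the same cells. The modalities are not equally informative
everywhere: a ten-antibody panel cleanly splits CD4⁺ from CD8⁺ T cells while
their transcriptomes blend, and the reverse holds for populations the panel
was never designed to see. `multiweave` implements weighted-nearest-neighbor
(WNN) integration: a per-cell, per-modality weight expressing how well each
modality's local neighborhood predicts the cell's state, and a single KNN
graph built under the per-cell weighted similarity.

## Per-modality preprocessing

Each modality is normalized by its field-standard transform and reduced to a
low-dimensional embedding whose rows are L2-normalized; all downstream
distances are Euclidean on these unit vectors (equivalently, cosine-like on
the raw scores).

- RNA: library-size log-normalization, `ln(1 + 1e4 · x / colsum)`, then PCA.
- Protein (ADT): centered log-ratio within each cell — `ln(x+1)` centered by
  its within-cell mean, natural log, pseudocount 1. There are several CLR
  dialects in circulation; the margin is exposed (`margin="feature"` centers
  across cells instead).
- ATAC: TF-IDF (term frequency = count / cell total; IDF = n_cells / peak
  total by default, with the binary document-frequency dialect as an option),
  scaled by 1e4 and log1p-transformed, then LSI: SVD, per-component
  standardization to mean 0 / sd 1, and optional removal of the first
  component, which usually tracks sequencing depth.

PCA centers features and by default scales them to unit variance; the scaling
switch exists because the convention for protein panels is not settled.
Cells with zero library size are an error, never silently dropped — QC is the
caller's decision.

## The WNN procedure

With `k = 20` neighbors per modality (the default throughout):

1. **KNN graphs.** Exact brute-force Euclidean search below 5,000 cells
   (stable tie-break by cell index), seeded pynndescent above.
2. **Predictions.** For each modality m and cell i, the within-modality
   prediction is the mean of i's k modality-m neighbors' embeddings; the
   cross-modality prediction averages modality-m embeddings over the
   neighbors defined by another modality n.
3. **Affinities.** Prediction errors become affinities through the
   exponential kernel used by UMAP,
   `θ = exp(−max(d − d₁, 0) / (σᵢ − d₁))`, where d₁ is the distance to the
   first nearest neighbor (local connectivity) and σᵢ a cell-specific
   bandwidth.
4. **Bandwidths.** σᵢ is the mean distance from cell i to the 20 cells with
   the *lowest non-zero* Jaccard neighborhood overlap with i (ties broken by
   the furthest Euclidean distance). These margin cells sit just outside the
   cell's own state, so the kernel decays over exactly the scale separating
   closely related states. Candidates are found through the sparse SNN
   product (only second-order neighbors can share a neighbor), which is
   exact. Cells with no non-zero-Jaccard partner fall back to the k-th
   neighbor distance; `σᵢ ≥ d₁ + 1e-10` is enforced so the kernel
   denominator stays positive.
5. **Weights.** The affinity ratio `s_{m,n}(i) = θ_{m,m} / (θ_{m,n} + ε)`,
   ε = 1e-4, compares how much better modality m's own neighborhood predicts
   m than modality n's neighborhood does. Weights are the softmax over all
   ordered pairs, grouped by m:
   `w_m(i) = Σ_n e^{s_{m,n}} / Σ_{m,n} e^{s_{m,n}}` — non-negative, summing
   to 1 per cell. The softmax is computed with per-cell max subtraction
   (ratios can reach 1/ε, far beyond exp overflow). For two modalities this
   reduces exactly to the textbook two-ratio softmax.
6. **WNN graph.** `θ_weighted(i,j) = Σ_m w_m(i) · θ_m(i,j)`, where
   θ_m(i,j) reuses the same kernel with cell i's bandwidth and local
   connectivity (the per-query convention: the similarity is deliberately
   asymmetric in i and j). Candidates for each cell are the union of its
   per-modality 200-nearest lists (clamped to n−1 on small data); the top-k
   by weighted similarity form the graph. Jaccard overlap of the WNN
   neighbor lists gives the SNN matrix used for clustering and as the sPCA
   kernel; `1 − similarity` serves as a distance for consumers that need
   one.

The M ≥ 3 extension changes nothing structurally: pairwise cross predictions
for all ordered modality pairs, the same ratios, the same grouped softmax.

## Supervised PCA and reference mapping

Given reference expression X (features × cells, restricted to variable
features — top 2,000 by standardized dispersion by default) and the WNN SNN
matrix L, supervised PCA solves

    argmax_U tr(UᵀXHLHXᵀU)  s.t.  UᵀU = I,   H = I − n⁻¹eeᵀ,

the closed form being the top-d eigenvectors of XHLHXᵀ (the HSIC-maximizing
transformation). The product is assembled as Xc·(L·Xcᵀ) with L sparse, so
the eigenproblem lives on the features × features matrix and no dense n × n
intermediate exists. With L = I this is exactly PCA; with the centered
linear self-kernel it reproduces PCA's eigenvectors with squared
eigenvalues — both serve as test oracles. Requests beyond the numerical rank
raise an error naming the attainable rank. Loadings carry a deterministic
sign convention (largest-magnitude entry positive).

Queries are projected as `Uᵀ(X_q − means)` after feature-id alignment;
missing features contribute zero post-centering (a warning fires below 50%
overlap). Anchors are mutual nearest neighbors (k_anchor = 5 per direction)
between reference and query in the shared L2-normalized space, scored by the
Jaccard overlap of the two cells' 30-neighborhoods in the combined dataset.
Label transfer is a weighted vote: each query cell's 50 nearest anchors vote
for their reference labels with weight `exp(−d²/2σ²) · anchor_score`, σ the
distance to the 50th selected anchor; vote rows are normalized to 1 and ties
resolve to the lexicographically first label. Query cells can be placed on
the reference UMAP (transform mode) or on a fresh fit of the merged
embeddings (de-novo mode), the latter being the right tool for spotting
query populations absent from the reference.

For the end-to-end synthetic harness the sPCA is fitted on the stacked
multimodal feature matrix: a cluster pair that shares its modality-1
centroid exactly is linearly invisible to any transformation of modality-1
features alone, so a transcriptome-only projection cannot beat chance on
that pair by construction. Stacking keeps the eigenproblem unchanged and
lets the mapping accuracy target cover the asymmetric pairs; the
expression-only path remains available and tested.

## Evaluation procedures

- **Clustering** delegates to Leiden (RBConfiguration partition) on the
  Jaccard-weighted SNN graph, seeded.
- **Noise robustness**: element-wise N(0, sd²) noise added to one modality
  immediately before its PCA, sd ∈ {0.5, 1, 1.5, 2, 3, 4, 5}; the corrupted
  modality's mean weight must fall monotonically.
- **Cross-cluster edges** count directed KNN edges between two labels
  (directed by default since KNN rows are directed; an undirected de-dup is
  available).
- **Neighbor-prediction correlation**: predict each feature per cell as the
  neighbor mean and report Pearson/Spearman correlation with the measured
  values; the standard latent-space benchmark.
- **Neighborhood homogeneity**: per-gene dropout rate (or sd) against
  pseudobulk mean, a Gaussian-kernel local-linear trend (Silverman
  bandwidth; local-linear avoids boundary bias on the steep part of a
  dropout curve), genes with residual > 0.1 (dropout) / > 0.5 (sd) called
  variable.
- **Perturbation score**: Wilcoxon rank-sum per gene across two conditions
  within a cell type, BH adjustment, candidate set at adjusted p < 0.1;
  the unit-normalized pseudobulk difference vector; per-cell score is the
  projection onto it. An empty candidate set returns a defined zero result
  with status "no response detected".
- **Marker panels**: clusters downsampled to ≤ 5% of cells each (floor of
  50), greedy forward selection maximizing 5-fold CV balanced accuracy of an
  L2-regularized balanced logistic regression, first five picks restricted
  to positive markers; per panel size, a 0.5-probability gate yields
  precision, recall, and enrichment = precision / prevalence (the
  "fold-over-prevalence" reading of enrichment; a recall-weighted reading
  exists and the components to compute it are all reported).

## The synthetic generator

`asymmetric_six` is the standard benchmark design: n = 2,000 cells, six
equally abundant clusters, a transcriptome-like modality (200 features,
centroid sd 1.0, within-cluster sd 0.6) and a protein-panel-like modality
(30 features, centroid sd 1.0, within-cluster sd 0.4). Pair (c0, c1) shares
its modality-1 centroid exactly and separates only in modality 2; (c2, c3)
is the mirror case. Feature counts and dimensionalities (30 and 18 retained
components) follow the proportions of a typical CITE-seq panel against a
transcriptome. Gaussian mode emits the centroid-plus-noise matrices directly
as normalized data; NB mode pushes the same structure through a log link to
gamma-Poisson counts (dispersion 0.3) to exercise the normalization path.
Queries redraw cells from the same centroids (rebuilt deterministically from
the design seed) under a new seed; a novel cluster draws fresh centroids.

What the generator does *not* emulate: dropout sparsity of real scRNA-seq,
ambient contamination, doublets, batch effects, donor variability, or
continuous trajectories. Passing tests therefore demonstrate the mechanics
and the mathematics of the procedure under controlled asymmetric structure,
not performance on any real dataset.

All randomness flows through `numpy.random.default_rng` (PCG64); fixed seeds
reproduce matrices bit-for-bit across platforms.

## Numerical choices and degeneracies

- KNN ties break by ascending cell index (stable sort); an exact duplicate
  of a cell is its first neighbor at distance 0.
- Jaccard neighbor sets include the cell itself (common SNN convention;
  configurable), so J(i,i) = 1.
- The softmax is stabilized by per-cell max subtraction; ε = 1e-4 is fixed.
- All-identical cells trigger the bandwidth fallback plus the σ floor, so
  kernels remain defined.
- Problem sizes in the test suite (n = 400–2,000 for fixtures, n ≤ 200 for
  dense-oracle equivalence, 20 seeds for the separation property) were
  chosen to keep the full suite in the low minutes while leaving every
  statistical margin wide.

## Known limitations

- The weighted similarity is asymmetric (query cell's weights and kernel);
  consumers needing a symmetric graph should use the derived SNN matrix.
- Approximate KNN above 5,000 cells has recall ≈ 0.99, not 1; all
  correctness tests run in the exact regime.
- sPCA assumes the variable-feature count stays in the low thousands (the
  eigenproblem is features × features).
- Anchor scoring is neighborhood-overlap only; no anchor filtering beyond
  MNN is applied, so heavily disjoint query populations are better examined
  through de-novo UMAP and prediction-score distributions than through
  anchor counts.
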