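# atlasmap

Compressed single-cell reference atlases with fast, reference-preserving
query mapping and annotation transfer.

## The problem

Integrated single-cell reference atlases — millions of cells, curated cell
type labels, trajectories, even surface-protein measurements — are expensive
to build and awkward to reuse: re-integrating every new dataset against the
raw atlas is slow and requires shipping the full expression matrix.
`atlasmap` compresses an integrated reference into a handful of small
matrices whose size is independent of the number of reference cells, then
places new query cells into the frozen harmonized embedding in milliseconds,
removes query-side batch effects, transfers discrete and continuous
annotations by k-NN, and scores how confidently each query cell maps. The
reference embedding never moves, and references can be shared without
distributing raw expression data.

It is aimed at computational biologists who maintain or consume reference
atlases: scRNA-seq, scATAC-seq (TF-IDF input), and cross-species queries
(ortholog mapping) are supported.

## The model

A reference of `n` cells is integrated with a per-cluster mixture-of-experts
linear model. Soft k-means (cosine distance, entropy weight `s`) assigns
cells to `k` clusters with memberships `R` (columns sum to 1), and each
cluster fits a ridge regression of the embedding `Z` (d × n) on the batch
design `X`:

```
B_k = (X* diag(R_k) X*^T + Λ)^(-1) X* diag(R_k) Z^T,   Λ = diag(0, λ, …, λ)
```

with the intercept (row 0 of `X*`) unpenalized; subtracting the
membership-weighted batch terms yields the harmonized embedding `Ẑ`.

The compressed ("minimal") reference stores only per-gene scaling statistics
μ, σ; the SVD gene loadings `U` (g × d); L2-normalized cluster centroids
`Y_cos` (d × k); and the compression terms

```
N_r(k) = Σ_i R_r[k, i]           (soft cluster sizes, k × 1)
C      = R_r Ẑ_r^T               (k × d)
```

Query cells are projected through the saved scaling and loadings
(`Z_q = U^T G_qs`), soft-assigned to the frozen centroids
(`R_q[k,i] ∝ exp(−(2/s)(1 − Y_cos[·,k]^T z_cos_i))`), and each cluster's
query model is solved **from the compression terms alone** — the normal
equations receive `N_r(k)` in the intercept block and `C(k,·)` on the
right-hand side, so no reference cell ever enters the computation and the
result equals the explicit reference+query ridge solve exactly. Subtracting
the fitted query batch terms places the query in the harmonized embedding;
reference cells cannot move by construction.

Annotation transfer is k-NN in the harmonized embedding: majority vote with
a winning-vote-fraction confidence for labels, unweighted neighbor means for
continuous values (trajectory coordinates, protein levels). Mapping quality
is scored by membership-weighted Mahalanobis distance to the reference
cluster distributions (per cell and per query cluster), k-NN distance rank
correlations against a gold embedding, and the local inverse Simpson index
(LISI) for mixing.

## Worked example

```python
import numpy as np
import atlasmap as am

# reference: two sequencing batches of the same five cell states
ref_spec = am.SimulationSpec(cells_per_batch=(1500, 1500), n_genes=300,
                             centroid_separation=8.0, batch_offset_scale=0.4,
                             seed=11, structure_seed=7)
ref_counts, ref_meta, _ = am.simulate_counts(ref_spec)
labels = ("type" + ref_meta["cluster"].astype(str)).to_numpy()

ref = am.build_reference(ref_counts, ref_meta["batch"].to_numpy(),
                         d=10, k=10, n_variable_genes=300,
                         labels=labels, seed=0)
print(f"reference: {len(ref.genes)} genes, d={ref.d}, k={ref.k}, "
      f"cluster sizes sum to {ref.N_r.sum():.0f}")

# query: a new batch from the same universe
q_spec = am.SimulationSpec(cells_per_batch=(500,), n_genes=300,
                           centroid_separation=8.0, batch_offset_scale=0.4,
                           seed=23, structure_seed=7)
q_counts, q_meta, _ = am.simulate_counts(q_spec)
mapped = am.map_query(q_counts, np.full(500, "new_batch"), ref)

pred = am.knn_predict_labels(ref.extras["Z_hat_r"], ref.extras["labels"],
                             mapped.Z_hat_q, k=5, min_confidence=0.6)
truth = ("type" + q_meta["cluster"].astype(str)).to_numpy()
scores = am.cell_type_f1(truth, pred.label, pred.assigned)
conf = am.per_cell_mapping_metric(mapped, ref.cluster_stats)
print(f"label transfer: accuracy {scores['accuracy']:.3f}, "
      f"median F1 {scores['per_type']['f1'].median():.3f}, "
      f"unassigned {scores['unassigned_fraction']:.1%}")
print(f"mapping confidence: median {np.median(conf):.2f} "
      f"(well-mapped cells typically score below 10)")
```

Output:

```
reference: 300 genes, d=10, k=10, cluster sizes sum to 3000
label transfer: accuracy 1.000, median F1 1.000, unassigned 0.0%
mapping confidence: median 3.21 (well-mapped cells typically score below 10)
```

The reference is built from 3,000 cells in two batches; the five simulated
cell states are well separated (8 within-cluster SDs), so a 5-NN vote in the
harmonized embedding recovers every query label and no cell falls below the
60% confidence gate. The median per-cell mapping score of 3.2 indicates the
query states are well covered by the reference.

Scikit-learn-style estimators wrap the same pipeline
(`ReferenceAtlas.fit/transform`, `KNNLabelTransfer`, `KNNValueTransfer`),
and a CLI covers the file-based workflow:

```bash
atlasmap simulate --n-cells 2000 --out fixture/
atlasmap build-reference --counts fixture/matrix.mtx --features fixture/features.tsv \
    --cells fixture/barcodes.tsv --meta fixture/meta.tsv --batch batch \
    --label-col cell_type --d 10 --k 10 --out ref.h5
atlasmap map --ref ref.h5 --counts fixture/matrix.mtx --features fixture/features.tsv \
    --cells fixture/barcodes.tsv --meta fixture/meta.tsv --batch batch --out mapped.h5
atlasmap predict --ref ref.h5 --mapped mapped.h5 --min-confidence 0.6 --out predictions.tsv
```

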