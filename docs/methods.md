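# Methods

## Model overview

`atlasmap` treats an integrated single-cell reference as a mixture of
experts: `k` soft clusters in a `d`-dimensional embedding, each with a
linear model whose intercept is the cluster centroid and whose remaining
coefficients capture batch displacements. Reference building fits this model
once; the fitted pieces that a future query needs are compressed into six
elements whose size depends only on the panel size `g`, the dimensionality
`d` and the cluster count `k` — never on the number of reference cells:

| element | shape | role |
|---|---|---|
| μ, σ | g | per-gene scaling statistics |
| U | g × d | SVD gene loadings for projection |
| Y_cos | d × k | L2-normalized cluster centroids |
| N_r | k | soft cluster sizes, `Σ_i R_r[k,i]` |
| C | k × d | compression term, `R_r Ẑ_r^T` |

The identity that makes mapping exact rather than approximate at the solve
stage: partitioning the joint (reference + query) ridge normal equations by
design-matrix structure, every reference-dependent entry collapses into
`N_r` (intercept × intercept block) and `C` (intercept right-hand side),
because reference cells carry zeros in all query-batch rows. The per-cluster
query solve assembled from `(N_r, C)` therefore equals the explicit
concatenated solve to machine precision; the test suite enforces this
against an independent brute-force implementation over randomized shapes,
and the empty-query closed form `B_qk[0,·] = C(k,·)/N_r(k)` (the
un-normalized centroid) exactly.

## Pipeline stages and parameters

**Normalization** — log(CP10K + 1); natural log default, base 2 available
(some protein-panel workflows use log2). Binarized scATAC peaks instead use
log(TF·IDF·10⁴ + 1) with the IDF vector computed on reference cells only and
frozen into the model so queries land in the same space; the +1/scale-factor
dialect is recorded in the model and in the serialized reference so
mismatched normalizations are rejected at mapping time. Cross-species
queries are first projected through a column-stochastic ortholog matrix
(`E_target = M E_source`), which conserves per-cell totals for mapped genes.

**Variable genes** — per batch, a loess (span 0.3) of log10 variance on
log10 mean gives each gene an expected standard deviation; standardized
values are clipped at √n_cells and genes are ranked by the variance of the
clipped values. Per-batch top lists are pooled as a union ordered by best
within-batch rank (the pooling order is not fixed by the published recipe;
the union convention is stable and deterministic). Clipping is one-sided
(upper), matching the standard implementation.

**Scaling** — genes are z-scored with the sample (n−1) standard deviation;
the convention is fixed here because downstream projections reuse σ
verbatim. Zero-variance genes scale to 0 and stay in place so indices align
between reference and query; query genes missing from the reference panel
are dropped and panel genes missing from the query contribute zero rows.

**Embedding** — truncated SVD of the scaled matrix, `G_s = U Σ V^T`,
embedding `Z = Σ V^T`, default `d = 20`. Column signs are fixed
deterministically (largest-magnitude loading positive) so rebuilds are
bit-identical. Any external linear embedding can be substituted as long as
its loadings are supplied; the integration pass-through accepts externally
harmonized `(Ẑ_r, R_r)` unchanged.

**Integration** — default cluster count `k = min(100, n/30)`. Single-batch
references are clustered by entropy-regularized soft k-means on cosine
distance (`s = 0.1`), initialized from a converged hard k-means (k-means++
seeding, 10 restarts, fixed seed) so the soft solution does not depend on a
single lucky draw. Multi-batch references iterate two steps: (1) clustering
on the current corrected embedding with a multiplicative diversity factor
`((E+1)/(O+1))^θ` for the cell's batch (expected vs observed soft batch
counts per cluster, θ = 2; the add-one bounds the boost when a batch has
near-zero presence in a distant cluster), and (2) a per-cluster ridge solve
(λ = 1 on batch terms, intercept unpenalized) whose batch terms are
subtracted **from the original embedding**. Correcting from the original
coordinates each iteration — rather than accumulating corrections — makes
the converged embedding a one-shot function of the final memberships,
mirroring the query-side correction exactly; this is what lets mapping
reproduce the de novo result under the stated conditions. Convergence is
declared when the median per-cell displacement falls below `tol` (default
1e-3 of the RMS embedding scale); a handful of boundary cells can flip
clusters indefinitely, which is why the criterion is a median, not a max.
`tau` (cluster-size discounting in the full published integrator) is
accepted but inert here and warns when set.

**Query mapping** — projection, soft assignment to `Y_cos` with the same
`s`, the compression-term solve (λ = 1 per query-batch coefficient), and
subtraction of membership-weighted batch terms. Clustering always uses
L2-normalized coordinates; the solve/correct steps operate on the
un-normalized projection by default, which keeps the correction additive in
the same space as the embedding and makes exact offset recovery and the
de novo comparison well-posed. A `l2_normalize_correction` flag feeds the
normalized coordinates through the solve/correct instead, for compatibility
with pipelines that work entirely on the unit sphere. Multiple query
covariates (donor and technology, say) enter as stacked one-hot blocks, each
level penalized with λ = 1. Mapping is deterministic and touches no
reference cell, so a serialized reference is byte-identical after any number
of mapping calls, and mapping cost is independent of reference size.

Mapping results differ slightly depending on whether query batches are
mapped jointly or separately — with a joint solve all query cells inform the
shared intercepts — and the package makes no attempt to hide this; the test
suite asserts the difference exists rather than pretending it does not.

**Annotation transfer** — Euclidean k-NN in the harmonized embedding
(cosine optional). Labels: majority vote, ties broken by a seeded RNG,
confidence = winning votes / k, and a cell is assigned only when confidence
is *strictly* above the threshold (so gating at 0.6 with k = 5 demands at
least 4 agreeing neighbors). Continuous values: unweighted mean over the k
nearest reference cells (k = 10 is typical for trajectory coordinates,
k = 50 for protein panels); applied reference-to-reference the same operator
is the smoother used to build denoised ground truth.

**Mapping confidence** — per cell, the membership-weighted Mahalanobis
distance of the query's pre-harmonized position to each cluster's weighted
mean/covariance (computed from `R_r` and `Z_r`, population-normalized);
empirically, well-covered states score below ~10, and the score is reported,
never thresholded. Per query cluster, the Mahalanobis distance from the
cluster's own mean/covariance (in reference PC space) to the nearest
reference centroid; clusters smaller than `2d` return NA because their
covariance estimate is unstable. Every covariance inversion adds a 1e-6
diagonal ridge; singular covariances are otherwise rejected.

**Embedding fidelity** — k-NN-corr fixes each query cell's k nearest
reference neighbors in a gold embedding and Spearman-correlates the gold and
alternative distances over those pairs (asymmetric by construction;
tie-handling uses average ranks). The within-query variant builds a separate
PCA per query batch (default: 2,000 variable genes, 20 dimensions) and asks
whether mapping preserved each cell's within-batch neighbor distances. LISI
calibrates a Gaussian kernel over each cell's 3×perplexity nearest neighbors
by bisecting the precision until the weight entropy matches log(perplexity)
(to 1e-5), then returns the inverse Simpson index of per-category summed
weights; squared Euclidean distances, following the published
implementation's convention.

## Synthetic data

The generator draws cells from a Gaussian mixture in a `d_latent`-dimensional
space (centroids on orthogonal axes at a fixed pairwise separation, in units
of the within-cluster SD; with zero noise the separation is read as an
absolute distance), adds per-batch per-cluster offset vectors, and emits
counts by Poisson-sampling a softplus-linear gene model at a target library
size, with optional dropout. A `structure_seed` fixes the shared universe
(centroids, gene program) independently of the per-dataset sampling seed so
reference and query datasets describe the same biology.

Default study conditions, chosen once: 5 balanced states, `d_latent = 10`,
300 genes, separation 8 (clearly separable types, as the method's
equivalence conditions presuppose), within-cluster SD 1, library size 2,000,
batch offsets drawn i.i.d. per batch and cluster with scale 0.4 per
coordinate (≈1.3 SD total displacement — a real but assignment-preserving
batch effect; offsets large enough to flip cosine cluster assignment violate
the "no novel states" premise the mapping model relies on, because
assignment happens before correction). The equivalence experiment uses
n = 5,000 reference cells in two batches against m = 250 query cells in one
disjoint batch, with `k = 5` matching the number of simulated states and the
full 300-gene panel; the label-transfer and novel-type experiments use
n = 3,000 references. The size/time contract builds n = 1,000 and n = 50,000
references at fixed (g = 150, d = 10, k = 20).

What the generator does **not** emulate: overdispersion beyond Poisson,
doublets, ambient RNA, gene–gene correlation beyond the linear latent
program, continuous differentiation topologies, and batch effects that
interact with library size. Passing tests therefore demonstrate the
algorithmic contracts (exactness of the compression solve, recovery of
additive offsets, neighborhood preservation under the stated conditions),
not robustness to every artifact of real droplet data. A negative-binomial
count option is a natural extension point.

## Numerical choices and degenerate inputs

- Softmax memberships use max-subtraction; zero-norm query cells (no
  expression on the panel) receive uniform membership and are flagged.
- All per-cluster linear systems are solved with a symmetric direct solve;
  a cluster with zero total weight is an error naming the cluster.
- Ridge defaults: λ = 0 on intercepts everywhere, λ = 1 per batch
  coefficient; unidentified coefficients (empty batches) shrink exactly to 0.
- Serialization is a single HDF5 container: a `required` group with the six
  minimal elements, a JSON metadata attribute (format version, d, k,
  normalization dialect), and an `extras` group (per-cell embeddings,
  labels, cluster statistics) that can be stripped without breaking
  mapping — only neighbor-based transfer and the confidence metrics demand
  extras, and they say so explicitly when absent.
- Rebuilds with the same seed are bit-identical; round-trips through the
  container reproduce mapping outputs bit-identically.

## Known limitations

- The multi-batch integrator is a deliberately simplified form of the
  published maximum-diversity framework: full-batch updates, multiplicative
  diversity factor, `tau` inert, one-shot correction from the original
  embedding. Users with a preferred integrator can pass `(Ẑ_r, R_r)` through
  unchanged and still get a mappable compressed reference.
- Equivalence between mapping and de novo integration degrades, as the
  model predicts, when query batch effects are large enough to corrupt the
  cosine cluster assignment, when the query is not small relative to the
  reference, or when query states are missing from the reference — the
  per-cell confidence metric exists precisely to flag the last case.
- k-NN label transfer inherits the usual caveat that `k` should not exceed
  the size of the rarest reference population.
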