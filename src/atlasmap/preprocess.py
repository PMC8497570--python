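"""Normalization, feature selection, scaling, and embedding of expression matrices.

All matrices in this package follow the features x cells orientation; embeddings
are dimensions x cells. The I/O layer converts from cell-major on-disk formats.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "ExpressionMatrix",
    "ScalingModel",
    "EmbeddingModel",
    "OrthologMap",
    "TfidfModel",
    "normalize_log_cp10k",
    "select_variable_genes_vst",
    "scale_genes",
    "run_svd_embedding",
    "tfidf_normalize",
    "map_orthologs",
]

VALID_LAYERS = ("counts", "lognorm", "scaled", "tfidf")


def _check_unique(ids, what):
    if len(set(ids)) != len(ids):
        seen, dups = set(), []
        for x in ids:
            if x in seen:
                dups.append(x)
            seen.add(x)
        raise ValueError(f"duplicated {what}: {sorted(set(dups))[:5]}")


@dataclass
class ExpressionMatrix:
    """A feature x cell matrix with aligned identifier lists.

    ``values`` may be dense (ndarray) or scipy sparse. ``layer`` records which
    normalization the values carry: raw ``counts``, ``lognorm`` (log CP10K),
    ``scaled`` (z-scored genes) or ``tfidf`` (normalized binary peaks).
    """

    values: object
    feature_ids: list
    cell_ids: list
    layer: str = "counts"

    def __post_init__(self):
        self.feature_ids = list(self.feature_ids)
        self.cell_ids = list(self.cell_ids)
        if self.layer not in VALID_LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {VALID_LAYERS}")
        g, n = self.values.shape
        if g != len(self.feature_ids):
            raise ValueError(
                f"matrix has {g} rows but {len(self.feature_ids)} feature ids"
            )
        if n != len(self.cell_ids):
            raise ValueError(f"matrix has {n} columns but {len(self.cell_ids)} cell ids")
        _check_unique(self.feature_ids, "feature ids")
        _check_unique(self.cell_ids, "cell ids")
        if self.layer == "counts":
            mn = self.values.min() if not sp.issparse(self.values) else self.values.min()
            if mn < 0:
                raise ValueError("counts layer must be nonnegative")

    @property
    def n_features(self):
        return self.values.shape[0]

    @property
    def n_cells(self):
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        v = self.values
        return v.toarray() if sp.issparse(v) else np.asarray(v)


@dataclass
class ScalingModel:
    """Per-gene centering/scaling statistics learned on the reference.

    ``sigma`` uses the sample standard deviation (n - 1 denominator).
    Zero-variance genes keep sigma as stored but are flagged; their scaled
    rows are set to zero so gene indices stay aligned.
    """

    genes: list
    mu: np.ndarray
    sigma: np.ndarray
    zero_variance: np.ndarray = None

    def __post_init__(self):
        self.genes = list(self.genes)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (len(self.genes) == self.mu.size == self.sigma.size):
            raise ValueError("genes, mu and sigma must have equal length")
        if not np.all(np.isfinite(self.sigma)):
            raise ValueError("sigma entries must be finite")
        _check_unique(self.genes, "model genes")
        if self.zero_variance is None:
            self.zero_variance = self.sigma == 0
        self.zero_variance = np.asarray(self.zero_variance, dtype=bool)


@dataclass
class EmbeddingModel:
    """Gene loadings and singular values of the reference SVD embedding."""

    loadings: np.ndarray  # genes x d, orthonormal columns
    singular_values: np.ndarray
    d: int

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        g, d = self.loadings.shape
        if d != self.d:
            raise ValueError("loadings column count disagrees with d")
        if d > g:
            raise ValueError("d cannot exceed the number of genes")
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(d), atol=1e-6):
            raise ValueError("loadings columns are not orthonormal")


@dataclass
class OrthologMap:
    """Column-stochastic map M from source (e.g. mouse) to target (human) genes.

    Every nonzero column sums to 1, so a source gene's counts are split among
    its orthologs without changing per-cell totals.
    """

    matrix: object  # target x source, sparse or dense
    human_ids: list
    mouse_ids: list

    def __post_init__(self):
        self.human_ids = list(self.human_ids)
        self.mouse_ids = list(self.mouse_ids)
        H, h = self.matrix.shape
        if H != len(self.human_ids) or h != len(self.mouse_ids):
            raise ValueError("matrix shape disagrees with id lists")
        colsums = np.asarray(self.matrix.sum(axis=0)).ravel()
        bad = ~(np.isclose(colsums, 0) | np.isclose(colsums, 1))
        if bad.any():
            raise ValueError(
                f"invalid ortholog map: {bad.sum()} columns sum to neither 0 nor 1"
            )

    @classmethod
    def from_pairs(cls, pairs):
        """Build from (mouse_symbol, human_symbol) pairs; one-to-many allowed."""
        mouse = sorted({m for m, _ in pairs})
        human = sorted({h for _, h in pairs})
        midx = {g: i for i, g in enumerate(mouse)}
        hidx = {g: i for i, g in enumerate(human)}
        rows, cols = [], []
        for m, h in pairs:
            rows.append(hidx[h])
            cols.append(midx[m])
        M = sp.csc_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(len(human), len(mouse))
        )
        colsums = np.asarray(M.sum(axis=0)).ravel()
        colsums[colsums == 0] = 1.0
        M = M @ sp.diags(1.0 / colsums)
        return cls(matrix=M, human_ids=human, mouse_ids=mouse)


@dataclass
class TfidfModel:
    """IDF vector computed on reference cells, reused for query normalization."""

    idf: np.ndarray
    n_ref: int
    undefined: np.ndarray = None  # peaks absent from all reference cells
    dialect: str = "log_tfidf_1e4"

    def __post_init__(self):
        self.idf = np.asarray(self.idf, dtype=float)
        if self.undefined is None:
            self.undefined = np.zeros(self.idf.size, dtype=bool)
        self.undefined = np.asarray(self.undefined, dtype=bool)
        if np.any(self.idf[~self.undefined] <= 0):
            raise ValueError("idf must be strictly positive where defined")


def normalize_log_cp10k(counts: ExpressionMatrix, scale_factor: float = 1e4,
                        log_base: str = "e") -> ExpressionMatrix:
    """log(CP10K + 1) library-size normalization.

    Each cell's counts are divided by the cell total, multiplied by
    ``scale_factor`` and passed through log1p (natural log by default,
    base 2 with ``log_base="2"``). Zero entries map to zero, so the sparsity
    pattern is preserved.
    """
    if counts.layer != "counts":
        raise ValueError(f"expected counts layer, got {counts.layer!r}")
    if log_base not in ("e", "2", 2):
        raise ValueError("log_base must be 'e' or '2'")
    totals = np.asarray(counts.values.sum(axis=0)).ravel()
    if np.any(totals == 0):
        bad = [counts.cell_ids[i] for i in np.flatnonzero(totals == 0)[:5]]
        raise ValueError(f"cells with zero total counts: {bad}")
    if sp.issparse(counts.values):
        out = counts.values.tocsc(copy=True).astype(float)
        out = out @ sp.diags(scale_factor / totals)
        out.data = np.log1p(out.data)
    else:
        out = np.log1p(np.asarray(counts.values, dtype=float) / totals * scale_factor)
    if log_base in ("2", 2):
        if sp.issparse(out):
            out.data /= np.log(2.0)
        else:
            out = out / np.log(2.0)
    return ExpressionMatrix(out, counts.feature_ids, counts.cell_ids, layer="lognorm")


def _vst_standardized_variance(X: np.ndarray, span: float = 0.3) -> np.ndarray:
    """Variance of clipped standardized values, per gene (rows).

    Fits a loess of log10(variance) on log10(mean), standardizes each gene by
    its observed mean and loess-expected standard deviation, clips at
    sqrt(n_cells), and returns the variance of the clipped values. Genes with
    zero variance (or zero mean) get 0.
    """
    g, n = X.shape
    mean = X.mean(axis=1)
    var = X.var(axis=1, ddof=1)
    out = np.zeros(g)
    ok = (var > 0) & (mean > 0)
    if ok.sum() < 2:
        return out
    lx = np.log10(mean[ok])
    ly = np.log10(var[ok])
    fit = lowess(ly, lx, frac=span, return_sorted=False)
    sd_exp = np.sqrt(10.0 ** fit)
    clip = np.sqrt(n)
    z = (X[ok] - mean[ok, None]) / sd_exp[:, None]
    np.minimum(z, clip, out=z)
    out[ok] = (z ** 2).sum(axis=1) / (n - 1)
    return out


def select_variable_genes_vst(lognorm: ExpressionMatrix, batch, n_top: int,
                              span: float = 0.3) -> list:
    """Rank genes by variance-stabilized dispersion, per batch, and pool.

    Within each batch a loess is fit to the log10(variance)/log10(mean)
    relationship, standardized values are clipped at sqrt(n_cells), and genes
    are ranked by the variance of the standardized values. The per-batch top
    ``n_top`` lists are pooled as a union ordered by best within-batch rank
    (ties by input gene order).
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    batch = np.asarray(batch)
    if batch.size != lognorm.n_cells:
        raise ValueError("batch labels must align with cells")
    X = lognorm.dense()
    if n_top > lognorm.n_features:
        warnings.warn(
            f"n_top={n_top} exceeds gene count {lognorm.n_features}; "
            "returning all expressed genes"
        )
    best_rank = {}
    for b in np.unique(batch):
        cols = batch == b
        if cols.sum() < 2:
            raise ValueError(f"batch {b!r} has fewer than 2 cells")
        sv = _vst_standardized_variance(X[:, cols], span=span)
        order = np.argsort(-sv, kind="stable")
        for rank, gi in enumerate(order[: min(n_top, lognorm.n_features)]):
            if sv[gi] <= 0:
                continue
            name = lognorm.feature_ids[gi]
            if name not in best_rank or rank < best_rank[name][0]:
                best_rank[name] = (rank, gi)
    pooled = sorted(best_rank.items(), key=lambda kv: (kv[1][0], kv[1][1]))
    return [name for name, _ in pooled]


def scale_genes(lognorm: ExpressionMatrix, genes=None, model: ScalingModel | None = None):
    """Z-score genes; reference mode learns mu/sigma, query mode reuses them.

    In reference mode (``model is None``) statistics are computed from the
    data over ``genes`` (default all) and rows come out with mean 0 and unit
    sample variance; zero-variance genes become all-zero rows and are flagged.
    In query mode the output rows follow ``model.genes``: genes absent from
    the query become zero rows, query genes absent from the model are dropped.
    """
    X = lognorm.dense().astype(float)
    gene_index = {g: i for i, g in enumerate(lognorm.feature_ids)}
    if model is None:
        genes = list(genes) if genes is not None else list(lognorm.feature_ids)
        missing = [g for g in genes if g not in gene_index]
        if missing:
            raise ValueError(f"genes not present in matrix: {missing[:5]}")
        rows = [gene_index[g] for g in genes]
        sub = X[rows]
        mu = sub.mean(axis=1)
        sigma = sub.std(axis=1, ddof=1) if sub.shape[1] > 1 else np.zeros(len(rows))
        zero = sigma == 0
        safe = np.where(zero, 1.0, sigma)
        out = (sub - mu[:, None]) / safe[:, None]
        out[zero] = 0.0
        model = ScalingModel(genes=genes, mu=mu, sigma=sigma, zero_variance=zero)
        return (
            ExpressionMatrix(out, genes, lognorm.cell_ids, layer="scaled"),
            model,
        )
    # query mode: pure function of (query lognorm, model)
    out = np.zeros((len(model.genes), lognorm.n_cells))
    safe = np.where(model.zero_variance | (model.sigma == 0), 1.0, model.sigma)
    for j, g in enumerate(model.genes):
        i = gene_index.get(g)
        if i is None:
            continue  # absent from query -> zero row
        if model.zero_variance[j]:
            continue
        out[j] = (X[i] - model.mu[j]) / safe[j]
    return ExpressionMatrix(out, list(model.genes), lognorm.cell_ids, layer="scaled"), model


def run_svd_embedding(scaled: ExpressionMatrix, d: int):
    """Truncated SVD of the scaled matrix: G_s = U S V^T, embedding Z = S V^T.

    The gene loadings U (orthonormal columns) are saved so queries can be
    projected with Z = U^T G_s. Column signs are fixed deterministically
    (largest-magnitude loading positive).
    """
    X = scaled.dense()
    g, n = X.shape
    if d > min(g, n):
        raise ValueError(f"d={d} exceeds min(genes, cells)={min(g, n)}")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    rank = int(np.sum(S > S[0] * max(g, n) * np.finfo(float).eps)) if S.size else 0
    if d > rank:
        raise ValueError(f"d={d} exceeds achievable rank {rank}")
    U, S, Vt = U[:, :d], S[:d], Vt[:d]
    # deterministic sign convention
    signs = np.sign(U[np.argmax(np.abs(U), axis=0), np.arange(d)])
    signs[signs == 0] = 1.0
    U = U * signs
    Vt = Vt * signs[:, None]
    Z = S[:, None] * Vt
    return EmbeddingModel(loadings=U, singular_values=S, d=d), Z


def tfidf_normalize(binary_peaks: ExpressionMatrix, model: TfidfModel | None = None,
                    scale_factor: float = 1e4):
    """log(TF x IDF) normalization of binarized peak matrices.

    TF is the per-cell frequency of each peak; IDF = n_ref / n_cells_with_peak
    is computed on reference cells only and reused for queries. The output is
    log(TF * IDF * scale_factor + 1) so zeros stay zero. Peaks absent from all
    reference cells have undefined IDF; their output rows are zeroed and
    flagged in the model.
    """
    X = binary_peaks.dense().astype(float)
    vals = np.unique(X)
    if not np.all(np.isin(vals, [0.0, 1.0])):
        raise ValueError("tfidf_normalize expects a binarized {0,1} matrix")
    if model is None:
        row_count = X.sum(axis=1)
        undefined = row_count == 0
        idf = np.where(undefined, 1.0, X.shape[1] / np.where(undefined, 1.0, row_count))
        model = TfidfModel(idf=idf, n_ref=X.shape[1], undefined=undefined,
                           dialect=f"log_tfidf_{scale_factor:g}")
    if model.idf.size != binary_peaks.n_features:
        raise ValueError("model peak count disagrees with matrix")
    totals = X.sum(axis=0)
    totals[totals == 0] = 1.0
    tf = X / totals
    out = np.log1p(tf * model.idf[:, None] * scale_factor)
    out[model.undefined] = 0.0
    return (
        ExpressionMatrix(out, binary_peaks.feature_ids, binary_peaks.cell_ids,
                         layer="tfidf"),
        model,
    )


def map_orthologs(mouse_counts: ExpressionMatrix, orthologs: OrthologMap) -> ExpressionMatrix:
    """Project counts into the target gene space: E_human = M E_mouse.

    Count-preserving: because nonzero columns of M sum to 1, each mapped
    source gene's counts are conserved per cell. Source genes missing from the
    map are dropped with a warning; target genes with no mapped source gene
    come out as zero rows.
    """
    midx = {g: i for i, g in enumerate(orthologs.mouse_ids)}
    keep = [i for i, g in enumerate(mouse_counts.feature_ids) if g in midx]
    dropped = mouse_counts.n_features - len(keep)
    if dropped:
        warnings.warn(f"{dropped} source genes absent from ortholog map; dropped")
    cols = [midx[mouse_counts.feature_ids[i]] for i in keep]
    M = orthologs.matrix
    Msub = M[:, cols] if not sp.issparse(M) else M.tocsc()[:, cols]
    X = mouse_counts.dense()[keep]
    out = np.asarray(Msub @ X)
    return ExpressionMatrix(out, orthologs.human_ids, mouse_counts.cell_ids,
                            layer=mouse_counts.layer)
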