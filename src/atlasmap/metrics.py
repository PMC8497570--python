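"""Mapping confidence and embedding-quality metrics.

Mahalanobis-based scores flag query cells or clusters that land far from the
reference cluster distributions in pre-harmonized PC space (a multivariate
Z-score analogue; well-represented states tend to score below ~10). k-NN-corr
and its within-query variant measure how faithfully an embedding preserves
neighbor distances relative to a gold standard; LISI measures local category
mixing; per-type F1 summarizes label-transfer quality.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import spearmanr
from sklearn.neighbors import NearestNeighbors

from .compress import ClusterStats
from .mapping import MappedQuery
from .preprocess import (
    ExpressionMatrix,
    normalize_log_cp10k,
    scale_genes,
    select_variable_genes_vst,
    run_svd_embedding,
)

__all__ = [
    "mahalanobis",
    "per_cell_mapping_metric",
    "per_cluster_mapping_metric",
    "knn_corr",
    "wiq_knn_corr",
    "lisi",
    "cell_type_f1",
]

_RIDGE = 1e-6


def _regularized_cholesky(cov, ridge=_RIDGE):
    cov = np.asarray(cov, dtype=float)
    if not np.allclose(cov, cov.T, atol=1e-8):
        raise ValueError("covariance must be symmetric")
    try:
        return scipy.linalg.cholesky(cov + ridge * np.eye(cov.shape[0]), lower=True)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError("covariance not positive semidefinite after ridge") from exc


def mahalanobis(x, mean, cov, ridge=_RIDGE) -> float:
    """D = sqrt((x - mu)^T Sigma^-1 (x - mu)) with a small diagonal ridge."""
    L = _regularized_cholesky(cov, ridge)
    diff = np.asarray(x, dtype=float) - np.asarray(mean, dtype=float)
    y = scipy.linalg.solve_triangular(L, diff, lower=True)
    return float(np.sqrt(y @ y))


def per_cell_mapping_metric(mapped: MappedQuery, stats: ClusterStats) -> np.ndarray:
    """Membership-weighted Mahalanobis distance of each query cell.

    score_i = sum_k R_q[k,i] D(Z_q[:,i]; mean_k, cov_k), computed in
    pre-harmonized PC space against the reference cluster statistics.
    """
    if stats is None:
        raise ValueError("ClusterStats absent")
    Z_q = mapped.Z_q
    k, m = mapped.R_q.shape
    D = np.empty((k, m))
    for kk in range(k):
        L = _regularized_cholesky(stats.cov[kk])
        diff = Z_q - stats.mean[kk][:, None]
        y = scipy.linalg.solve_triangular(L, diff, lower=True)
        D[kk] = np.sqrt((y ** 2).sum(axis=0))
    return (mapped.R_q * D).sum(axis=0)


def per_cluster_mapping_metric(Z_q, query_cluster_labels, ref_centroids) -> pd.Series:
    """Per-query-cluster Mahalanobis distance to the nearest reference centroid.

    The covariance is the query cluster's own, estimated in reference
    pre-harmonized PC space; clusters smaller than 2d return NA because the
    covariance estimate is unstable. Returns a Series indexed by cluster.
    """
    Z_q = np.asarray(Z_q, dtype=float)
    d = Z_q.shape[0]
    labels = np.asarray(query_cluster_labels)
    if labels.size != Z_q.shape[1]:
        raise ValueError("query cluster labels must align with cells")
    cents = np.asarray(ref_centroids, dtype=float)  # k x d
    scores = {}
    for lab in pd.unique(labels):
        cols = labels == lab
        size = int(cols.sum())
        if size < 2 * d:
            scores[lab] = np.nan
            continue
        pts = Z_q[:, cols]
        mean = pts.mean(axis=1)
        cov = np.cov(pts)
        nearest = cents[np.argmin(((cents - mean) ** 2).sum(axis=1))]
        scores[lab] = mahalanobis(nearest, mean, cov)
    return pd.Series(scores)


def knn_corr(gold, alt, query_idx, ref_idx, k: int = 500) -> np.ndarray:
    """Spearman correlation of fixed neighbor-pair distances, per query cell.

    Neighbor pairs are each query cell's k nearest reference cells in the
    gold embedding; the correlation compares the gold and alternative
    distances over those pairs (asymmetric in gold/alt by construction).
    """
    gold = np.asarray(gold, dtype=float)
    alt = np.asarray(alt, dtype=float)
    query_idx = np.asarray(query_idx)
    ref_idx = np.asarray(ref_idx)
    if k > ref_idx.size:
        raise ValueError(f"k={k} exceeds number of reference cells {ref_idx.size}")
    nn = NearestNeighbors().fit(gold[:, ref_idx].T)
    gd, nbr = nn.kneighbors(gold[:, query_idx].T, n_neighbors=k)
    out = np.empty(query_idx.size)
    for i in range(query_idx.size):
        cols = ref_idx[nbr[i]]
        ad = np.linalg.norm(alt[:, cols] - alt[:, query_idx[i]][:, None], axis=0)
        out[i] = spearmanr(gd[i], ad).statistic
    return out


def wiq_knn_corr(G_q: ExpressionMatrix, batch, Z_hat_q, k: int = 500,
                 d_pca: int = 20, n_vargenes: int = 2000) -> np.ndarray:
    """Within-query k-NN correlation: is the query's own structure preserved?

    Each batch gets its own standard PCA pipeline (normalize, variable genes,
    scale, SVD); per cell, the distances to its k nearest within-batch
    neighbors in that PCA are rank-correlated with the distances to the same
    cells after mapping.
    """
    batch = np.asarray(batch)
    if batch.size != G_q.n_cells:
        raise ValueError("batch labels must cover all query cells")
    Z_hat_q = np.asarray(Z_hat_q, dtype=float)
    out = np.full(G_q.n_cells, np.nan)
    X = G_q.dense()
    for b in np.unique(batch):
        cols = np.flatnonzero(batch == b)
        kb = k
        if cols.size < k + 1:
            kb = cols.size - 1
            warnings.warn(f"batch {b!r} smaller than k+1; k truncated to {kb}")
        sub = ExpressionMatrix(X[:, cols], G_q.feature_ids,
                               [G_q.cell_ids[i] for i in cols], layer=G_q.layer)
        if sub.layer == "counts":
            sub = normalize_log_cp10k(sub)
        genes = select_variable_genes_vst(sub, np.zeros(cols.size, dtype=int),
                                          min(n_vargenes, sub.n_features))
        scaled, _ = scale_genes(sub, genes)
        dd = min(d_pca, len(genes) - 1, cols.size - 1)
        _, Zb = run_svd_embedding(scaled, dd)
        nn = NearestNeighbors().fit(Zb.T)
        pre_d, nbr = nn.kneighbors(Zb.T, n_neighbors=kb + 1)
        pre_d, nbr = pre_d[:, 1:], nbr[:, 1:]  # drop self
        for j, ci in enumerate(cols):
            post = np.linalg.norm(
                Z_hat_q[:, cols[nbr[j]]] - Z_hat_q[:, ci][:, None], axis=0
            )
            out[ci] = spearmanr(pre_d[j], post).statistic
    return out


def lisi(embedding, categories, perplexity: float = 30.0) -> np.ndarray:
    """Local inverse Simpson index: effective category count per neighborhood.

    Gaussian-kernel weights over each cell's 3 x perplexity nearest neighbors
    with the bandwidth tuned by bisection so the weight entropy matches
    log(perplexity); the score is the inverse Simpson index of the summed
    per-category weights. Ranges from 1 to the number of categories.
    """
    Z = np.asarray(embedding, dtype=float)
    cats = np.asarray(categories)
    n = Z.shape[1]
    if n < 2:
        raise ValueError("need at least 2 cells")
    n_neighbors = min(int(3 * perplexity), n - 1)
    if perplexity >= n_neighbors + 1:
        raise ValueError("perplexity must be smaller than the neighborhood size")
    levels, codes = np.unique(cats, return_inverse=True)
    nn = NearestNeighbors().fit(Z.T)
    dist, idx = nn.kneighbors(Z.T, n_neighbors=n_neighbors + 1)
    dist, idx = dist[:, 1:], idx[:, 1:]
    target = np.log(perplexity)
    out = np.empty(n)
    d2 = dist ** 2
    for i in range(n):
        beta = _calibrate_bandwidth(d2[i], target)
        w = np.exp(-beta * (d2[i] - d2[i].min()))
        w = w / w.sum()
        p = np.bincount(codes[idx[i]], weights=w, minlength=levels.size)
        out[i] = 1.0 / (p ** 2).sum()
    return out


def _calibrate_bandwidth(d2, target, tol=1e-5, max_iter=100):
    """Bisection on the Gaussian precision so Shannon entropy hits the target."""
    def entropy(beta):
        w = np.exp(-beta * (d2 - d2.min()))
        s = w.sum()
        p = w / s
        with np.errstate(divide="ignore", invalid="ignore"):
            lp = np.where(p > 0, np.log(p), 0.0)
        return -(p * lp).sum()

    lo, hi = 0.0, 1.0
    while entropy(hi) > target and hi < 1e12:
        hi *= 2
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        h = entropy(mid)
        if abs(h - target) < tol:
            return mid
        if h > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def cell_type_f1(truth, predicted, assigned=None):
    """Per-type precision/recall/F1, overall accuracy and confusion matrix.

    Unassigned predictions (``assigned`` False) are excluded from the scores
    and reported separately as ``unassigned_fraction``. Types never predicted
    get recall 0 and F1 0.
    """
    truth = np.asarray(truth).astype(str)
    predicted = np.asarray(predicted).astype(str)
    if truth.size == 0 or predicted.size == 0:
        raise ValueError("empty inputs")
    if truth.size != predicted.size:
        raise ValueError("truth and predicted must align")
    if assigned is None:
        assigned = np.ones(truth.size, dtype=bool)
    assigned = np.asarray(assigned, dtype=bool)
    unassigned_fraction = float(1.0 - assigned.mean())
    t, p = truth[assigned], predicted[assigned]
    types = sorted(set(t) | set(p))
    confusion = pd.DataFrame(0, index=types, columns=types)
    for a, b in zip(t, p):
        confusion.loc[a, b] += 1
    rows = {}
    for ty in sorted(set(t)):
        tp = float(np.sum((t == ty) & (p == ty)))
        fp = float(np.sum((t != ty) & (p == ty)))
        fn = float(np.sum((t == ty) & (p != ty)))
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        rows[ty] = {"precision": prec, "recall": rec, "f1": f1}
    per_type = pd.DataFrame(rows).T
    accuracy = float((t == p).mean()) if t.size else float("nan")
    return {
        "per_type": per_type,
        "accuracy": accuracy,
        "confusion": confusion,
        "unassigned_fraction": unassigned_fraction,
    }
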