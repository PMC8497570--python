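"""Soft k-means clustering and batch correction of the reference embedding.

Single-batch references are clustered with entropy-regularized soft k-means on
cosine distance. Multi-batch references go through a simplified
maximum-diversity mixture-of-experts integrator: clustering with a
multiplicative diversity factor alternates with per-cluster ridge fits whose
batch terms are subtracted from the embedding. Users who integrate elsewhere
can pass their embedding and memberships straight through.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.cluster import KMeans

__all__ = [
    "IntegrationParams",
    "IntegrationResult",
    "default_num_clusters",
    "soft_kmeans_cosine",
    "solve_mixture_betas",
    "harmonize_reference",
]


@dataclass
class IntegrationParams:
    """Tuning knobs of the clustering/correction loop.

    ``s`` weights the entropy regularizer of the soft assignments (default
    0.1); ``theta`` sets the strength of the diversity factor that discourages
    single-batch clusters (default 2). ``tau`` is accepted for interface
    compatibility but is a documented no-op in this simplified integrator.
    ``lambda_ridge`` penalizes batch coefficients only; the intercept is never
    penalized.
    """

    k: int = 20
    s: float = 0.1
    theta: float = 2.0
    tau: float = 0.0
    lambda_ridge: float = 1.0
    max_iter: int = 20
    tol: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.s <= 0:
            raise ValueError("s must be > 0")
        lam = np.atleast_1d(np.asarray(self.lambda_ridge, dtype=float))
        if np.any(lam < 0):
            raise ValueError("lambda_ridge must be nonnegative")
        if self.tau != 0:
            warnings.warn("tau is accepted but has no effect in this integrator")


@dataclass
class IntegrationResult:
    Z_r: np.ndarray        # d x n pre-harmonized embedding
    Z_hat_r: np.ndarray    # d x n harmonized embedding
    R_r: np.ndarray        # k x n soft memberships (columns sum to 1)
    Y: np.ndarray          # d x k centroids, Y = Z_hat_r R_r^T
    B_r: np.ndarray        # k x (1+b) x d fitted mixture parameters
    converged: bool = True


def default_num_clusters(n: int) -> int:
    """Default cluster count: min(100, n/30), floored at 1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return max(1, min(100, n // 30))


def _l2_normalize_columns(Z: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(Z, axis=0)
    norms = np.where(norms == 0, 1.0, norms)
    return Z / norms


def _softmax_columns(logits: np.ndarray) -> np.ndarray:
    logits = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=0, keepdims=True)


def _membership_logits(Y_cos: np.ndarray, Z_cos: np.ndarray, s: float) -> np.ndarray:
    return -(2.0 / s) * (1.0 - Y_cos.T @ Z_cos)


def soft_kmeans_objective(Z_cos, Y_cos, R, s):
    """Entropy-regularized cosine k-means objective (used by monotonicity tests)."""
    dist = 2.0 * (1.0 - Y_cos.T @ Z_cos)
    with np.errstate(divide="ignore", invalid="ignore"):
        ent = np.where(R > 0, R * np.log(R), 0.0)
    return float((R * dist).sum() + s * ent.sum())


def soft_kmeans_cosine(Z: np.ndarray, params: IntegrationParams):
    """Entropy-regularized soft k-means on L2-normalized columns of Z.

    E-step: memberships proportional to exp(-(2/s)(1 - cos)); M-step:
    centroids Y = Z R^T (cosine-normalized for the next E-step). Deterministic
    for a fixed seed (k-means++ initialization on the normalized columns).
    Returns memberships R (k x n) and un-normalized centroids Y = Z R^T.
    """
    Z = np.asarray(Z, dtype=float)
    d, n = Z.shape
    k = params.k
    if k > n:
        raise ValueError(f"k={k} exceeds number of cells n={n}")
    Zc = _l2_normalize_columns(Z)
    # init: converged hard k-means (k-means++ seeding, multiple restarts) on
    # the normalized columns; makes the soft solution robust to seeding
    km = KMeans(n_clusters=k, n_init=10, random_state=params.seed).fit(Zc.T)
    Y_cos = _l2_normalize_columns(km.cluster_centers_.T)
    R = None
    for _ in range(max(1, params.max_iter)):
        R_new = _softmax_columns(_membership_logits(Y_cos, Zc, params.s))
        Y_cos = _l2_normalize_columns(Zc @ R_new.T)
        if R is not None and np.abs(R_new - R).max() < params.tol:
            R = R_new
            break
        R = R_new
    Y = Z @ R.T
    return R, Y


def solve_mixture_betas(X_star: np.ndarray, R_k: np.ndarray, Z: np.ndarray,
                        lambda_ridge=1.0, cluster: int | None = None) -> np.ndarray:
    """Weighted ridge solve of one cluster's linear mixture model.

    B_k = (X* diag(R_k) X*^T + Lambda)^-1 X* diag(R_k) Z^T, with the
    batch-independent intercept (row 0) unpenalized and every batch
    coefficient penalized by ``lambda_ridge`` (scalar or per-coefficient
    vector).
    """
    X_star = np.asarray(X_star, dtype=float)
    R_k = np.asarray(R_k, dtype=float)
    Z = np.asarray(Z, dtype=float)
    if not np.allclose(X_star[0], 1.0):
        raise ValueError("row 0 of X_star must be all ones (intercept)")
    if np.any(R_k < 0):
        raise ValueError("weights must be nonnegative")
    total = R_k.sum()
    if total == 0:
        which = f" {cluster}" if cluster is not None else ""
        raise ValueError(f"cluster{which} has zero total weight; system singular")
    p = X_star.shape[0]
    lam = np.atleast_1d(np.asarray(lambda_ridge, dtype=float))
    if lam.size == 1:
        lam = np.full(p - 1, lam[0])
    if lam.size != p - 1:
        raise ValueError("lambda_ridge must be scalar or length (rows - 1)")
    Lambda = np.diag(np.concatenate([[0.0], lam]))
    Xw = X_star * R_k
    A = Xw @ X_star.T + Lambda
    b = Xw @ Z.T
    return scipy.linalg.solve(A, b, assume_a="sym")


def _one_hot(labels) -> tuple[np.ndarray, list]:
    labels = np.asarray(labels)
    levels = list(dict.fromkeys(labels.tolist()))  # order of first appearance
    X = np.zeros((len(levels), labels.size))
    for i, lev in enumerate(levels):
        X[i] = labels == lev
    return X, levels


def _diversity_cluster(Zc, Y_cos, X_r, params, n_inner=3):
    """Soft assignment with a multiplicative batch-diversity factor.

    Memberships are the entropy-regularized base assignment multiplied by
    ((expected + 1) / (observed + 1))^theta for the cell's batch, renormalized
    (the add-one keeps the boost bounded when a batch has near-zero soft count
    in a distant cluster). Because the observed frequencies depend on R, a few
    fixed-point rounds are run.
    """
    b, n = X_r.shape
    pi = X_r.sum(axis=1) / n  # batch proportions
    base = _membership_logits(Y_cos, Zc, params.s)
    R = _softmax_columns(base)
    for _ in range(n_inner):
        O = R @ X_r.T                       # k x b observed soft counts
        E = R.sum(axis=1)[:, None] * pi     # k x b expected under independence
        ratio = (E + 1.0) / (O + 1.0)
        penalty = params.theta * (np.log(ratio) @ X_r)  # k x n, per cell's batch
        R = _softmax_columns(base + penalty)
    return R


def harmonize_reference(Z_r: np.ndarray, X_r=None, params: IntegrationParams | None = None,
                        external: tuple | None = None) -> IntegrationResult:
    """Cluster and batch-correct the reference embedding.

    ``X_r`` is a b x n one-hot design (or per-cell labels). With fewer than
    two batches no correction is performed and clusters come from plain soft
    k-means. With ``external=(Z_hat_r, R_r)`` the supplied integration is
    passed through unchanged and only centroids/parameters are recomputed.
    """
    Z_r = np.asarray(Z_r, dtype=float)
    d, n = Z_r.shape
    if params is None:
        params = IntegrationParams(k=default_num_clusters(n))

    if X_r is None:
        X_r = np.ones((1, n))
    X_r = np.asarray(X_r)
    if X_r.ndim == 1:
        X_r, _ = _one_hot(X_r)
    X_r = X_r.astype(float)
    b = X_r.shape[0]
    if np.any(X_r.sum(axis=1) == 0):
        raise ValueError("every batch must be nonempty")

    if external is not None:
        Z_hat, R = (np.asarray(a, dtype=float) for a in external)
        Y = Z_hat @ R.T
        B_r = _fit_all_betas(R, Z_hat, X_r, params.lambda_ridge)
        return IntegrationResult(Z_r=Z_r, Z_hat_r=Z_hat, R_r=R, Y=Y, B_r=B_r)

    if b < 2:
        R, Y = soft_kmeans_cosine(Z_r, params)
        B_r = _fit_all_betas(R, Z_r, np.zeros((0, n)), params.lambda_ridge)
        return IntegrationResult(Z_r=Z_r, Z_hat_r=Z_r, R_r=R, Y=Y, B_r=B_r)

    scale = float(np.sqrt((Z_r ** 2).mean()))
    Zcur = Z_r.copy()
    # initial clustering for centroid seeds
    R, _ = soft_kmeans_cosine(Zcur, params)
    Y_cos = _l2_normalize_columns(_l2_normalize_columns(Zcur) @ R.T)
    X_star = np.vstack([np.ones(n), X_r])
    converged = False
    B_r = None
    for _ in range(params.max_iter):
        # cluster on the corrected embedding so clusters are batch-mixed,
        # but always regress the batch terms out of the *original* embedding:
        # the result is a one-shot function of the final memberships, exactly
        # like the query-side correction, instead of a path-dependent
        # accumulation of per-iteration corrections.
        Zc = _l2_normalize_columns(Zcur)
        R = _diversity_cluster(Zc, Y_cos, X_r, params)
        Y_cos = _l2_normalize_columns(Zc @ R.T)
        correction = np.zeros_like(Zcur)
        B_r = np.empty((params.k, 1 + b, d))
        for kk in range(params.k):
            B_r[kk] = solve_mixture_betas(X_star, R[kk], Z_r,
                                          params.lambda_ridge, cluster=kk)
            correction += R[kk] * (B_r[kk, 1:].T @ X_r)
        Znew = Z_r - correction
        # robust criterion: a handful of boundary cells can flip clusters
        # indefinitely, so convergence is judged on the median displacement
        delta = float(np.median(np.linalg.norm(Znew - Zcur, axis=0)))
        Zcur = Znew
        if delta < params.tol * max(scale, 1e-12):
            converged = True
            break
    if not converged:
        warnings.warn("harmonize_reference did not converge; returning last iterate")
    Y = Zcur @ R.T
    return IntegrationResult(Z_r=Z_r, Z_hat_r=Zcur, R_r=R, Y=Y, B_r=B_r,
                             converged=converged)


def _fit_all_betas(R, Z, X_r, lambda_ridge):
    n = Z.shape[1]
    X_star = np.vstack([np.ones(n), X_r])
    return np.stack([
        solve_mixture_betas(X_star, R[kk], Z, lambda_ridge, cluster=kk)
        for kk in range(R.shape[0])
    ])
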