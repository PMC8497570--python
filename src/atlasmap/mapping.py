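"""Placement of query cells into a frozen compressed reference.

The mapping pipeline is project -> soft-assign -> solve -> correct. The query
is projected through the saved gene loadings, soft-assigned to the frozen
centroids with cosine distance, and each cluster's mixture model is solved
from the compression terms alone: no reference cell ever enters the
computation, so mapping cost is independent of reference size and the
reference embedding cannot move.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .compress import MinimalReference
from .integrate import _l2_normalize_columns, _one_hot, _softmax_columns
from .preprocess import ExpressionMatrix, normalize_log_cp10k, scale_genes

__all__ = [
    "MappedQuery",
    "project_query",
    "assign_query_clusters",
    "solve_query_betas",
    "correct_query",
    "map_query",
]


@dataclass
class MappedQuery:
    """Query matrices through the mapping pipeline."""

    Z_q: np.ndarray          # d x m pre-correction projection
    R_q: np.ndarray          # k x m soft memberships
    B_q: np.ndarray          # k x (1+c) x d fitted query parameters
    Z_hat_q: np.ndarray      # d x m corrected embedding
    cell_ids: list = None
    X_q: np.ndarray = None
    zero_norm: np.ndarray = None  # cells with no expression on reference genes

    def __post_init__(self):
        if not np.all(np.isfinite(self.Z_hat_q)):
            raise ValueError("corrected embedding contains non-finite values")


def project_query(G_q: ExpressionMatrix, ref: MinimalReference) -> np.ndarray:
    """Project query expression into the reference embedding: Z_q = U^T G_qs.

    The query is subset/reordered to the reference variable genes and scaled
    by the saved reference means and standard deviations; genes missing from
    the query contribute zero rows.
    """
    if G_q.layer not in ("lognorm", "tfidf"):
        raise ValueError(
            f"project_query expects normalized input, got layer {G_q.layer!r}"
        )
    present = set(G_q.feature_ids)
    overlap = sum(1 for g in ref.genes if g in present) / len(ref.genes)
    if overlap < 0.01:
        raise ValueError(
            f"query shares only {overlap:.1%} of reference variable genes"
        )
    if overlap < 0.5:
        warnings.warn(
            f"query shares only {overlap:.1%} of reference variable genes"
        )
    scaled, _ = scale_genes(G_q, model=ref.scaling_model)
    return ref.loadings.T @ scaled.dense()


def assign_query_clusters(Z_q: np.ndarray, Y_cos: np.ndarray, s: float = 0.1):
    """Soft-assign query cells to frozen centroids with cosine distance.

    R[k,i] is a softmax over -(2/s)(1 - Y_cos^T z_cos), computed with
    max-subtraction. Cells with zero norm on the reference gene set get a
    uniform membership and are flagged.
    """
    if s <= 0:
        raise ValueError("s must be > 0")
    Z_q = np.asarray(Z_q, dtype=float)
    norms = np.linalg.norm(Z_q, axis=0)
    zero = norms == 0
    Zc = Z_q / np.where(zero, 1.0, norms)
    k = Y_cos.shape[1]
    R = _softmax_columns(-(2.0 / s) * (1.0 - Y_cos.T @ Zc))
    if zero.any():
        warnings.warn(f"{int(zero.sum())} query cells have zero norm; uniform membership")
        R[:, zero] = 1.0 / k
    return R, zero


def solve_query_betas(R_q: np.ndarray, Z_q: np.ndarray, X_q: np.ndarray | None,
                      ref: MinimalReference, lambda_ridge=1.0) -> np.ndarray:
    """Solve each cluster's query mixture model from the compression terms.

    Assembles the (1+c) x (1+c) normal equations per cluster without touching
    reference cells: the intercept block receives the saved cluster size
    N_r(k) and the saved C(k,.) right-hand side, the query blocks come from
    the query memberships alone, and batch coefficients carry the ridge
    penalty (intercept unpenalized). Equals the explicit reference+query
    concatenation solve exactly.
    """
    R_q = np.asarray(R_q, dtype=float)
    Z_q = np.asarray(Z_q, dtype=float)
    k, m = R_q.shape
    if X_q is None or (hasattr(X_q, "shape") and np.asarray(X_q).size == 0):
        X_q = np.zeros((0, m))
    X_q = np.asarray(X_q, dtype=float)
    c = X_q.shape[0]
    lam = np.atleast_1d(np.asarray(lambda_ridge, dtype=float))
    if lam.size == 1:
        lam = np.full(c, lam[0])
    if lam.size != c:
        raise ValueError("lambda_ridge must be scalar or length c")
    Xs = np.vstack([np.ones(m), X_q]) if m else np.ones((1 + c, 0))
    Lambda = np.diag(np.concatenate([[0.0], lam]))
    B = np.empty((k, 1 + c, ref.d))
    for kk in range(k):
        w = R_q[kk]
        Xw = Xs * w
        A = Xw @ Xs.T + Lambda
        A[0, 0] += ref.N_r[kk]
        b = Xw @ Z_q.T if m else np.zeros((1 + c, ref.d))
        b[0] += ref.C[kk]
        B[kk] = scipy.linalg.solve(A, b, assume_a="sym")
    return B


def correct_query(Z_q: np.ndarray, R_q: np.ndarray, B_q: np.ndarray,
                  X_q: np.ndarray | None) -> np.ndarray:
    """Subtract membership-weighted batch terms: Z_hat_q = Z_q - sum_k R_qk B_qk[1:]^T X_q.

    Only the non-intercept rows of B_q are used; the reference embedding is
    never an input, so reference cells cannot move. With no query covariates
    this is the identity.
    """
    Z_q = np.asarray(Z_q, dtype=float)
    if X_q is None or np.asarray(X_q).size == 0:
        return Z_q.copy()
    X_q = np.asarray(X_q, dtype=float)
    correction = np.zeros_like(Z_q)
    for kk in range(R_q.shape[0]):
        correction += R_q[kk] * (B_q[kk, 1:].T @ X_q)
    return Z_q - correction


def map_query(G_q: ExpressionMatrix, X_q=None, ref: MinimalReference = None, *,
              s: float = 0.1, lambda_ridge=1.0,
              l2_normalize_correction: bool = False) -> MappedQuery:
    """Full mapping pipeline: project, assign, solve, correct.

    ``X_q`` may be per-cell batch labels, a DataFrame of covariate columns
    (one-hot blocks stacked, c = total levels), an explicit c x m one-hot
    design, or None for a batch-free query. Deterministic: no randomness
    anywhere in mapping. With ``l2_normalize_correction`` the projected
    coordinates are L2-normalized once and used through solve/correct as well
    (clustering always uses normalized coordinates).
    """
    stage = "project_query"
    try:
        if G_q.layer == "counts":
            if ref.dialect != "log1p_cp10k":
                raise ValueError(
                    f"reference dialect {ref.dialect!r} incompatible with raw counts; "
                    "normalize the query accordingly"
                )
            G_q = normalize_log_cp10k(G_q)
        Z_q = project_query(G_q, ref)
        if l2_normalize_correction:
            norms = np.linalg.norm(Z_q, axis=0)
            Z_q = Z_q / np.where(norms == 0, 1.0, norms)
        stage = "assign_query_clusters"
        R_q, zero = assign_query_clusters(Z_q, ref.Y_cos, s=s)
        stage = "solve_query_betas"
        design = _query_design(X_q, G_q.n_cells)
        B_q = solve_query_betas(R_q, Z_q, design, ref, lambda_ridge)
        stage = "correct_query"
        Z_hat_q = correct_query(Z_q, R_q, B_q, design)
    except Exception as exc:
        raise type(exc)(f"[{stage}] {exc}") from exc
    return MappedQuery(Z_q=Z_q, R_q=R_q, B_q=B_q, Z_hat_q=Z_hat_q,
                       cell_ids=list(G_q.cell_ids), X_q=design, zero_norm=zero)


def _query_design(X_q, m):
    if X_q is None:
        return np.zeros((0, m))
    try:
        import pandas as pd
        if isinstance(X_q, pd.DataFrame):
            blocks = [
                _one_hot(X_q[col].to_numpy())[0] for col in X_q.columns
            ]
            return np.vstack(blocks)
    except ImportError:  # pragma: no cover
        pass
    X_q = np.asarray(X_q)
    if X_q.ndim == 1:
        return _one_hot(X_q)[0]
    if X_q.shape[1] != m:
        raise ValueError("design matrix columns must match query cells")
    return X_q.astype(float)
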