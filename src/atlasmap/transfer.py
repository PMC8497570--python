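"""k-NN transfer of reference annotations to mapped query cells.

Discrete labels are transferred by majority vote among the k nearest
reference cells in the harmonized embedding, with a confidence equal to the
winning-vote fraction. Continuous values (trajectory coordinates, surface
protein levels) are transferred as unweighted k-NN means; applied
reference-to-reference the same operator acts as a smoother.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["LabelPrediction", "knn_predict_labels", "knn_transfer_continuous"]


@dataclass
class LabelPrediction:
    """Per-query-cell predicted label, confidence, and assignment flag.

    Confidence is the fraction of the k reference neighbors voting for the
    winning label; cells are unassigned exactly when confidence <= the
    threshold supplied at prediction time.
    """

    label: np.ndarray
    confidence: np.ndarray
    assigned: np.ndarray

    def __post_init__(self):
        if not (len(self.label) == len(self.confidence) == len(self.assigned)):
            raise ValueError("prediction fields must have equal length")


def _fit_neighbors(Z_ref, metric):
    if metric not in ("euclidean", "cosine"):
        raise ValueError("metric must be 'euclidean' or 'cosine'")
    return NearestNeighbors(metric=metric).fit(np.asarray(Z_ref, dtype=float).T)


def knn_predict_labels(Z_hat_r, ref_labels, Z_hat_q, k: int = 5,
                       min_confidence: float = 0.0, seed: int = 0,
                       metric: str = "euclidean") -> LabelPrediction:
    """Majority-vote k-NN label transfer in the harmonized embedding.

    Ties are broken randomly with the given seed. Reference cells with
    missing labels are excluded from voting. A cell is assigned only when
    its confidence is strictly greater than ``min_confidence`` (so a 60%
    threshold requires at least 4 of 5 winning votes at k=5).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    Z_hat_r = np.asarray(Z_hat_r, dtype=float)
    labels = np.asarray(ref_labels, dtype=object)
    ok = np.array([lab is not None and lab == lab for lab in labels])  # drop None/NaN
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} reference cells lack labels; excluded from voting")
        Z_hat_r = Z_hat_r[:, ok]
        labels = labels[ok]
    n = Z_hat_r.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds number of labeled reference cells n={n}")
    nn = _fit_neighbors(Z_hat_r, metric)
    _, idx = nn.kneighbors(np.asarray(Z_hat_q, dtype=float).T, n_neighbors=k)
    rng = np.random.default_rng(seed)
    m = idx.shape[0]
    out_label = np.empty(m, dtype=object)
    out_conf = np.empty(m)
    for i in range(m):
        votes, counts = np.unique(labels[idx[i]].astype(str), return_counts=True)
        top = counts.max()
        winners = votes[counts == top]
        out_label[i] = winners[0] if winners.size == 1 else rng.choice(winners)
        out_conf[i] = top / k
    assigned = out_conf > min_confidence
    return LabelPrediction(label=out_label, confidence=out_conf, assigned=assigned)


def knn_transfer_continuous(Z_hat_r, ref_values, Z_hat_q, k: int,
                            metric: str = "euclidean") -> np.ndarray:
    """Unweighted k-NN mean of reference values, per query cell.

    ``ref_values`` is (n_ref, p), row-aligned to reference cells; the result
    is (m_query, p). Non-finite reference values are excluded per dimension
    with a renormalized mean.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    Z_hat_r = np.asarray(Z_hat_r, dtype=float)
    V = np.atleast_2d(np.asarray(ref_values, dtype=float))
    if V.shape[0] != Z_hat_r.shape[1]:
        if V.shape[1] == Z_hat_r.shape[1] and V.shape[0] != Z_hat_r.shape[1]:
            raise ValueError("ref_values must be row-aligned to reference cells (n, p)")
    n = Z_hat_r.shape[1]
    if k > n:
        raise ValueError(f"k={k} exceeds number of reference cells n={n}")
    nn = _fit_neighbors(Z_hat_r, metric)
    _, idx = nn.kneighbors(np.asarray(Z_hat_q, dtype=float).T, n_neighbors=k)
    finite = np.isfinite(V)
    if not finite.all():
        warnings.warn("non-finite reference values excluded from transfer means")
        Vz = np.where(finite, V, 0.0)
        sums = Vz[idx].sum(axis=1)
        counts = finite[idx].sum(axis=1)
        with np.errstate(invalid="ignore"):
            return sums / np.where(counts == 0, np.nan, counts)
    return V[idx].mean(axis=1)
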