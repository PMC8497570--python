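"""Scikit-learn style estimators over the reference/mapping pipeline.

``ReferenceAtlas.fit`` builds the compressed reference from reference counts;
``transform`` maps query cells into the frozen harmonized embedding.
``KNNLabelTransfer`` and ``KNNValueTransfer`` are thin neighbor-based
annotation-transfer estimators over harmonized coordinates. All follow the
sklearn conventions (cells are samples/rows; fitted attributes carry a
trailing underscore; ``get_params``/``set_params`` work with model selection
tools). The module-level functions in the other modules remain the
lower-level functional interface these estimators compose.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin, TransformerMixin

from .compress import build_reference
from .integrate import IntegrationParams, default_num_clusters
from .mapping import map_query
from .metrics import per_cell_mapping_metric
from .preprocess import ExpressionMatrix
from .transfer import knn_predict_labels, knn_transfer_continuous

__all__ = ["ReferenceAtlas", "KNNLabelTransfer", "KNNValueTransfer"]


def _as_expression(X, feature_names, layer):
    if isinstance(X, ExpressionMatrix):
        return X
    X = np.asarray(X, dtype=float)
    n, g = X.shape  # sklearn orientation: cells x genes
    if feature_names is None:
        feature_names = [f"feature{i}" for i in range(g)]
    return ExpressionMatrix(X.T, feature_names, [f"cell{i}" for i in range(n)],
                            layer=layer)


class ReferenceAtlas(TransformerMixin, BaseEstimator):
    """Compressed reference atlas with frozen-embedding query mapping.

    fit(X, batch=...) runs normalization, per-batch variable-gene selection,
    scaling, SVD and batch integration, then compresses the result;
    transform(X, batch=...) places new cells into the harmonized embedding
    without moving any reference cell. ``X`` is cells x genes (sklearn
    orientation) or an ExpressionMatrix.
    """

    def __init__(self, d=20, k="auto", n_variable_genes=2000, s=0.1, theta=2.0,
                 lambda_ridge=1.0, max_iter=20, tol=1e-4,
                 l2_normalize_correction=False, random_state=0):
        self.d = d
        self.k = k
        self.n_variable_genes = n_variable_genes
        self.s = s
        self.theta = theta
        self.lambda_ridge = lambda_ridge
        self.max_iter = max_iter
        self.tol = tol
        self.l2_normalize_correction = l2_normalize_correction
        self.random_state = random_state

    def fit(self, X, y=None, *, batch=None, feature_names=None, layer="counts",
            labels=None, annotations=None):
        em = _as_expression(X, feature_names, layer)
        k = default_num_clusters(em.n_cells) if self.k == "auto" else int(self.k)
        params = IntegrationParams(
            k=k, s=self.s, theta=self.theta, lambda_ridge=self.lambda_ridge,
            max_iter=self.max_iter, tol=self.tol, seed=self.random_state,
        )
        self.reference_ = build_reference(
            em, batch, d=self.d, k=k, n_variable_genes=self.n_variable_genes,
            params=params, labels=labels, annotations=annotations,
            seed=self.random_state,
        )
        self.n_features_in_ = em.n_features
        return self

    def transform(self, X, *, batch=None, feature_names=None, layer="counts"):
        """Map query cells; returns the harmonized embedding, cells x d."""
        mapped = self.map(X, batch=batch, feature_names=feature_names, layer=layer)
        return mapped.Z_hat_q.T

    def map(self, X, *, batch=None, feature_names=None, layer="counts"):
        """Full mapping result (projection, memberships, betas, embedding)."""
        self._check_fitted()
        em = _as_expression(X, feature_names, layer)
        return map_query(em, batch, self.reference_, s=self.s,
                         lambda_ridge=self.lambda_ridge,
                         l2_normalize_correction=self.l2_normalize_correction)

    def mapping_confidence(self, X, *, batch=None, feature_names=None,
                           layer="counts"):
        """Per-cell weighted Mahalanobis mapping-confidence score."""
        mapped = self.map(X, batch=batch, feature_names=feature_names, layer=layer)
        return per_cell_mapping_metric(mapped, self.reference_.cluster_stats)

    def _check_fitted(self):
        if not hasattr(self, "reference_"):
            raise AttributeError("ReferenceAtlas is not fitted yet")


class KNNLabelTransfer(ClassifierMixin, BaseEstimator):
    """Majority-vote k-NN label transfer in a harmonized embedding.

    X is cells x d. ``predict`` returns labels; ``predict_with_confidence``
    adds the winning-vote fraction and the assignment mask under the
    confidence threshold.
    """

    def __init__(self, k=5, min_confidence=0.0, metric="euclidean", random_state=0):
        self.k = k
        self.min_confidence = min_confidence
        self.metric = metric
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] != y.size:
            raise ValueError("X rows and y must align")
        self.X_ = X
        self.y_ = y
        self.classes_ = np.unique(y.astype(str))
        return self

    def predict(self, X):
        return self.predict_with_confidence(X).label

    def predict_with_confidence(self, X):
        if not hasattr(self, "X_"):
            raise AttributeError("KNNLabelTransfer is not fitted yet")
        return knn_predict_labels(
            self.X_.T, self.y_, np.asarray(X, dtype=float).T, k=self.k,
            min_confidence=self.min_confidence, seed=self.random_state,
            metric=self.metric,
        )


class KNNValueTransfer(RegressorMixin, BaseEstimator):
    """Unweighted k-NN mean transfer of continuous annotations (n x p values)."""

    def __init__(self, k=50, metric="euclidean"):
        self.k = k
        self.metric = metric

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X rows and y must align")
        self.X_ = X
        self.y_ = y
        return self

    def predict(self, X):
        if not hasattr(self, "X_"):
            raise AttributeError("KNNValueTransfer is not fitted yet")
        return knn_transfer_continuous(self.X_.T, self.y_,
                                       np.asarray(X, dtype=float).T,
                                       k=self.k, metric=self.metric)
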