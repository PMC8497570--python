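"""Compression of an integrated reference into its minimal mappable elements.

The compressed reference stores only per-gene scaling statistics (mu, sigma),
gene loadings U, L2-normalized cluster centroids Y_cos, and the compression
terms N_r (soft cluster sizes) and C = R_r Z_hat_r^T. None of these scale with
the number of reference cells, so an atlas of millions of cells compresses to
a few megabytes while still supporting exact query correction. Per-cell
extras (the harmonized embedding, annotations, cluster statistics for mapping
confidence) are optional and only needed for neighbor-based transfer and
quality metrics.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import h5py

from .preprocess import (
    ExpressionMatrix,
    ScalingModel,
    normalize_log_cp10k,
    scale_genes,
    select_variable_genes_vst,
    run_svd_embedding,
)
from .integrate import (
    IntegrationParams,
    default_num_clusters,
    harmonize_reference,
    _l2_normalize_columns,
    _one_hot,
)

__all__ = [
    "ClusterStats",
    "MinimalReference",
    "compute_centroids",
    "compute_compression_terms",
    "compute_cluster_stats",
    "build_reference",
    "serialize_reference",
    "deserialize_reference",
]

FORMAT_VERSION = "1"
REQUIRED_ELEMENTS = ("mu", "sigma", "loadings", "Y_cos", "N_r", "C")


@dataclass
class ClusterStats:
    """Weighted per-cluster means and covariances in pre-harmonized PC space.

    Used by the Mahalanobis mapping-confidence metrics. Covariances are
    population-normalized by the soft cluster size; clusters with weight
    below d are flagged unstable (kept, not dropped).
    """

    mean: np.ndarray        # k x d
    cov: np.ndarray         # k x d x d
    space: str = "pre-harmonized"
    unstable: np.ndarray = None

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.cov = np.asarray(self.cov, dtype=float)
        k, d = self.mean.shape
        if self.cov.shape != (k, d, d):
            raise ValueError("cov shape disagrees with mean")
        if not np.allclose(self.cov, np.swapaxes(self.cov, 1, 2), atol=1e-8):
            raise ValueError("covariances must be symmetric")
        if self.unstable is None:
            self.unstable = np.zeros(k, dtype=bool)
        self.unstable = np.asarray(self.unstable, dtype=bool)


@dataclass
class MinimalReference:
    """The compressed, mappable atlas.

    Required elements: per-gene scaling (mu, sigma), gene loadings U,
    L2-normalized centroids Y_cos, and compression terms N_r and C. ``extras``
    may hold the harmonized per-cell embedding ``Z_hat_r`` (d x n), the
    pre-harmonized ``Z_r``, reference cell ``labels``, continuous annotation
    matrices, and ``cluster_stats`` for confidence metrics.
    """

    mu: np.ndarray
    sigma: np.ndarray
    loadings: np.ndarray    # g x d
    Y_cos: np.ndarray       # d x k
    N_r: np.ndarray         # k
    C: np.ndarray           # k x d
    genes: list
    d: int
    k: int
    dialect: str = "log1p_cp10k"
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.Y_cos = np.asarray(self.Y_cos, dtype=float)
        self.N_r = np.asarray(self.N_r, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        self.genes = list(self.genes)
        g = len(self.genes)
        if self.mu.size != g or self.sigma.size != g:
            raise ValueError("mu/sigma length disagrees with gene list")
        if self.loadings.shape != (g, self.d):
            raise ValueError("loadings shape disagrees with (genes, d)")
        if self.Y_cos.shape != (self.d, self.k):
            raise ValueError("Y_cos shape disagrees with (d, k)")
        if self.N_r.shape != (self.k,) or self.C.shape != (self.k, self.d):
            raise ValueError("compression term shapes disagree with (k, d)")
        if np.any(self.N_r <= 0):
            raise ValueError("N_r entries must be positive")
        norms = np.linalg.norm(self.Y_cos, axis=0)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("Y_cos columns must be unit norm")

    @property
    def scaling_model(self) -> ScalingModel:
        return ScalingModel(genes=self.genes, mu=self.mu, sigma=self.sigma)

    @property
    def cluster_stats(self) -> ClusterStats | None:
        return self.extras.get("cluster_stats")


def compute_centroids(Z_hat_r: np.ndarray, R_r: np.ndarray) -> np.ndarray:
    """Cluster centroids Y = Z_hat_r R_r^T (membership-weighted coordinate sums)."""
    Z_hat_r = np.asarray(Z_hat_r, dtype=float)
    R_r = np.asarray(R_r, dtype=float)
    if Z_hat_r.shape[1] != R_r.shape[1]:
        raise ValueError("embedding and membership cell counts disagree")
    N = R_r.sum(axis=1)
    if np.any(N == 0):
        raise ValueError(f"clusters with zero total membership: {np.flatnonzero(N == 0).tolist()}")
    return Z_hat_r @ R_r.T


def compute_compression_terms(R_r: np.ndarray, Z_hat_r: np.ndarray):
    """Compression terms: soft cluster sizes N_r and C = R_r Z_hat_r^T."""
    R_r = np.asarray(R_r, dtype=float)
    Z_hat_r = np.asarray(Z_hat_r, dtype=float)
    if R_r.shape[1] != Z_hat_r.shape[1]:
        raise ValueError("membership and embedding cell counts disagree")
    colsums = R_r.sum(axis=0)
    if not np.allclose(colsums, 1.0, atol=1e-6):
        raise ValueError("R_r columns must sum to 1")
    N_r = R_r.sum(axis=1)
    C = R_r @ Z_hat_r.T
    return N_r, C


def compute_cluster_stats(Z_r: np.ndarray, R_r: np.ndarray) -> ClusterStats:
    """Membership-weighted cluster means and covariances in pre-harmonized space.

    mean_k = sum_i R[k,i] z_i / N_k; cov_k is the weighted covariance about
    mean_k normalized by N_k (population convention). Clusters with weight
    below d are flagged unstable.
    """
    Z_r = np.asarray(Z_r, dtype=float)
    R_r = np.asarray(R_r, dtype=float)
    d, n = Z_r.shape
    k = R_r.shape[0]
    N = R_r.sum(axis=1)
    if np.any(N == 0):
        raise ValueError("cluster with zero total weight")
    mean = (R_r @ Z_r.T) / N[:, None]
    cov = np.empty((k, d, d))
    for kk in range(k):
        Xc = Z_r - mean[kk][:, None]
        cov[kk] = (Xc * R_r[kk]) @ Xc.T / N[kk]
        cov[kk] = 0.5 * (cov[kk] + cov[kk].T)
    unstable = N < d
    if unstable.any():
        warnings.warn(
            f"{int(unstable.sum())} clusters have weight below d; covariance flagged unstable"
        )
    return ClusterStats(mean=mean, cov=cov, unstable=unstable)


def build_reference(G_r: ExpressionMatrix, batch=None, *, d: int = 20, k=None,
                    n_variable_genes: int = 2000, params: IntegrationParams | None = None,
                    save_cells: bool = True, labels=None, annotations: dict | None = None,
                    external_integration: tuple | None = None,
                    seed: int = 0) -> MinimalReference:
    """Run the full reference pipeline and return the compressed reference.

    Normalize (when counts are supplied), select variable genes per batch,
    scale, embed by SVD, integrate over batches, then compute centroids,
    compression terms and cluster statistics. ``batch`` may be per-cell labels
    or a DataFrame of covariate columns (one-hot blocks are stacked).
    ``save_cells`` keeps the per-cell embeddings (needed for k-NN transfer).
    """
    stage = "normalize"
    try:
        if G_r.layer == "counts":
            lognorm = normalize_log_cp10k(G_r)
            dialect = "log1p_cp10k"
        elif G_r.layer in ("lognorm", "tfidf"):
            lognorm = G_r
            dialect = "log1p_cp10k" if G_r.layer == "lognorm" else "tfidf"
        else:
            raise ValueError(f"cannot build reference from layer {G_r.layer!r}")

        n = lognorm.n_cells
        X_r, batch_labels = _design_from_metadata(batch, n)

        stage = "select_variable_genes_vst"
        vst_batch = batch_labels if batch_labels is not None else np.zeros(n, dtype=int)
        genes = select_variable_genes_vst(lognorm, vst_batch,
                                          min(n_variable_genes, lognorm.n_features))

        stage = "scale_genes"
        scaled, scaling = scale_genes(lognorm, genes)

        stage = "run_svd_embedding"
        emb, Z_r = run_svd_embedding(scaled, d)

        stage = "harmonize_reference"
        if k is None:
            k = default_num_clusters(n)
        if params is None:
            params = IntegrationParams(k=k, seed=seed)
        res = harmonize_reference(Z_r, X_r, params, external=external_integration)

        stage = "compress"
        Y = compute_centroids(res.Z_hat_r, res.R_r)
        N_r, C = compute_compression_terms(res.R_r, res.Z_hat_r)
        stats = compute_cluster_stats(res.Z_r, res.R_r)
    except Exception as exc:
        raise type(exc)(f"[{stage}] {exc}") from exc

    extras = {"cluster_stats": stats}
    if save_cells:
        extras["Z_hat_r"] = res.Z_hat_r
        extras["Z_r"] = res.Z_r
        extras["R_r"] = res.R_r
        extras["cell_ids"] = list(lognorm.cell_ids)
    if labels is not None:
        extras["labels"] = np.asarray(labels)
    if annotations:
        extras.update(annotations)

    return MinimalReference(
        mu=scaling.mu, sigma=scaling.sigma, loadings=emb.loadings,
        Y_cos=_l2_normalize_columns(Y), N_r=N_r, C=C, genes=genes,
        d=d, k=params.k, dialect=dialect, extras=extras,
    )


def _design_from_metadata(batch, n):
    """Build a stacked one-hot design from labels or a covariate DataFrame."""
    if batch is None:
        return None, None
    try:
        import pandas as pd
        if isinstance(batch, pd.DataFrame):
            blocks, combined = [], None
            for col in batch.columns:
                X, _ = _one_hot(batch[col].to_numpy())
                blocks.append(X)
                lab = batch[col].astype(str)
                combined = lab if combined is None else combined + "|" + lab
            return np.vstack(blocks), combined.to_numpy()
    except ImportError:  # pragma: no cover
        pass
    labels = np.asarray(batch)
    if labels.size != n:
        raise ValueError("batch labels must align with cells")
    X, _ = _one_hot(labels)
    return X, labels


def serialize_reference(ref: MinimalReference, path) -> str:
    """Write the reference to a single HDF5 container; returns the path."""
    meta = {"format_version": FORMAT_VERSION, "d": ref.d, "k": ref.k,
            "dialect": ref.dialect}
    with h5py.File(path, "w") as f:
        f.attrs["metadata"] = json.dumps(meta)
        req = f.create_group("required")
        req.create_dataset("mu", data=ref.mu)
        req.create_dataset("sigma", data=ref.sigma)
        req.create_dataset("loadings", data=ref.loadings)
        req.create_dataset("Y_cos", data=ref.Y_cos)
        req.create_dataset("N_r", data=ref.N_r)
        req.create_dataset("C", data=ref.C)
        f.create_dataset("genes", data=np.array(ref.genes, dtype="S"))
        ex = f.create_group("extras")
        for key, val in ref.extras.items():
            if val is None:
                continue
            if key == "cluster_stats":
                grp = ex.create_group("cluster_stats")
                grp.create_dataset("mean", data=val.mean)
                grp.create_dataset("cov", data=val.cov)
                grp.create_dataset("unstable", data=val.unstable)
                grp.attrs["space"] = val.space
            elif key in ("labels", "cell_ids"):
                ex.create_dataset(key, data=np.array(val, dtype="S"))
            else:
                ex.create_dataset(key, data=np.asarray(val))
    return str(path)


def deserialize_reference(path) -> MinimalReference:
    """Load a reference container; round-trips bit-identically."""
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["metadata"])
        if meta.get("format_version") != FORMAT_VERSION:
            raise ValueError(
                f"reference format version {meta.get('format_version')!r} is not "
                f"supported (expected {FORMAT_VERSION!r})"
            )
        req = f["required"]
        for name in REQUIRED_ELEMENTS:
            if name not in req:
                raise ValueError(f"missing required element {name}")
        genes = [g.decode() for g in f["genes"][()]]
        extras = {}
        if "extras" in f:
            for key in f["extras"]:
                if key == "cluster_stats":
                    grp = f["extras"]["cluster_stats"]
                    extras["cluster_stats"] = ClusterStats(
                        mean=grp["mean"][()], cov=grp["cov"][()],
                        unstable=grp["unstable"][()].astype(bool),
                        space=grp.attrs.get("space", "pre-harmonized"),
                    )
                elif key in ("labels", "cell_ids"):
                    arr = f["extras"][key][()]
                    extras[key] = np.array([x.decode() for x in arr])
                else:
                    extras[key] = f["extras"][key][()]
        return MinimalReference(
            mu=req["mu"][()], sigma=req["sigma"][()], loadings=req["loadings"][()],
            Y_cos=req["Y_cos"][()], N_r=req["N_r"][()], C=req["C"][()],
            genes=genes, d=meta["d"], k=meta["k"], dialect=meta["dialect"],
            extras=extras,
        )
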