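"""Deterministic synthetic fixtures with known cluster and batch structure.

Cells live in a latent Gaussian mixture; batch effects are additive offsets
in latent space; counts are Poisson draws from a softplus-linear gene model
so the latent structure is linearly recoverable by PCA. The generator aims at
recoverability, not biological realism: no doublets, ambient RNA or
overdispersion beyond Poisson (a negative-binomial extension is left as a
flag for future work).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ExpressionMatrix

__all__ = ["SimulationSpec", "simulate_latent", "simulate_counts"]


@dataclass
class SimulationSpec:
    """Parameters of the synthetic mixture generator used by all tests.

    ``centroid_separation`` is the pairwise distance between cluster centroids
    in units of the within-cluster standard deviation (``noise_sd``).
    ``batch_offsets`` is (n_batches, n_clusters, d) or (n_batches, d); when
    None and ``batch_offset_scale`` > 0, offsets are drawn once from a seeded
    Gaussian of that scale. ``held_out_clusters`` marks clusters to exclude
    from a reference in novel-cell-type experiments (the generator emits them;
    callers subset).

    ``seed`` drives cell sampling; ``structure_seed`` (default: same as seed)
    fixes the shared universe — centroid directions and the gene model — so a
    reference and a query drawn with different seeds but one structure_seed
    share cell states and expression programs, as required for mapping
    experiments.
    """

    n_clusters: int = 5
    d_latent: int = 10
    n_genes: int = 300
    cells_per_batch: tuple = (1000, 1000)
    cluster_proportions: tuple | None = None
    centroid_separation: float = 8.0
    batch_offsets: np.ndarray | None = None
    batch_offset_scale: float = 0.0
    library_size_mean: float = 2000.0
    noise_sd: float = 1.0
    dropout_rate: float = 0.0
    held_out_clusters: tuple = ()
    seed: int = 0
    structure_seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.centroid_separation <= 0:
            raise ValueError("separation must be > 0")
        if self.cluster_proportions is not None:
            p = np.asarray(self.cluster_proportions, dtype=float)
            if p.size != self.n_clusters or not np.isclose(p.sum(), 1.0):
                raise ValueError("proportions must sum to 1 over n_clusters")
        for h in self.held_out_clusters:
            if not 0 <= h < self.n_clusters:
                raise ValueError(f"held_out cluster {h} not in [0, {self.n_clusters})")

    @property
    def structure(self):
        return self.seed if self.structure_seed is None else self.structure_seed

    @property
    def n_batches(self):
        return len(self.cells_per_batch)

    @property
    def n_cells(self):
        return int(sum(self.cells_per_batch))


def _centroids(spec: SimulationSpec) -> np.ndarray:
    """Cluster centroids with pairwise distance = separation x noise_sd."""
    K, d = spec.n_clusters, spec.d_latent
    # separation is in units of the within-cluster SD; with zero noise it is
    # read as an absolute distance
    sd_unit = spec.noise_sd if spec.noise_sd > 0 else 1.0
    scale = spec.centroid_separation * sd_unit / np.sqrt(2.0)
    if K <= d:
        return scale * np.eye(d)[:, :K]
    # more clusters than dimensions: random directions, rescaled to the
    # minimum pairwise distance
    rng = np.random.default_rng(spec.structure + 7)
    Y = rng.standard_normal((d, K))
    Y /= np.linalg.norm(Y, axis=0)
    dists = np.linalg.norm(Y[:, :, None] - Y[:, None, :], axis=0)
    np.fill_diagonal(dists, np.inf)
    return Y * (spec.centroid_separation * spec.noise_sd / dists.min())


def _batch_offsets(spec: SimulationSpec) -> np.ndarray:
    """(n_batches, n_clusters, d) additive offsets."""
    B, K, d = spec.n_batches, spec.n_clusters, spec.d_latent
    if spec.batch_offsets is not None:
        off = np.asarray(spec.batch_offsets, dtype=float)
        if off.shape == (B, d):
            off = np.repeat(off[:, None, :], K, axis=1)
        if off.shape != (B, K, d):
            raise ValueError("batch_offsets must be (n_batches, d) or (n_batches, n_clusters, d)")
        return off
    if spec.batch_offset_scale > 0:
        rng = np.random.default_rng(spec.seed + 13)
        return rng.normal(scale=spec.batch_offset_scale, size=(B, K, d))
    return np.zeros((B, K, d))


def simulate_latent(spec: SimulationSpec):
    """Draw latent coordinates: Gaussian mixture plus per-batch offsets.

    Returns (observed d x N embedding, metadata DataFrame with cluster/batch/
    held-out flags, batch-free truth d x N). Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    cents = _centroids(spec)
    offsets = _batch_offsets(spec)
    p = (np.asarray(spec.cluster_proportions, dtype=float)
         if spec.cluster_proportions is not None
         else np.full(spec.n_clusters, 1.0 / spec.n_clusters))
    Z, truth, cluster, batch = [], [], [], []
    for b, nb in enumerate(spec.cells_per_batch):
        labs = rng.choice(spec.n_clusters, size=nb, p=p)
        base = cents[:, labs] + rng.normal(scale=spec.noise_sd,
                                           size=(spec.d_latent, nb))
        obs = base + offsets[b][labs].T
        truth.append(base)
        Z.append(obs)
        cluster.append(labs)
        batch.append(np.full(nb, b))
    Z = np.concatenate(Z, axis=1)
    truth = np.concatenate(truth, axis=1)
    cluster = np.concatenate(cluster)
    batch = np.concatenate(batch)
    meta = pd.DataFrame({
        "cell_id": [f"cell{i}" for i in range(Z.shape[1])],
        "cluster": cluster,
        "batch": batch,
        "held_out": np.isin(cluster, list(spec.held_out_clusters)),
    })
    return Z, meta, truth


def simulate_counts(spec: SimulationSpec):
    """Poisson counts from a softplus-linear gene model over the latent mixture.

    Gene rates are softplus(L z + b) with a seed-fixed loading matrix L, then
    cells are sampled at the spec library size with optional dropout. Returns
    (ExpressionMatrix[counts], metadata, latent truth d x N).
    """
    Z, meta, truth = simulate_latent(spec)
    struct_rng = np.random.default_rng(spec.structure + 1)
    rng = np.random.default_rng(spec.seed + 2)
    g, d = spec.n_genes, spec.d_latent
    L = struct_rng.standard_normal((g, d)) / np.sqrt(d)
    b0 = struct_rng.normal(scale=0.5, size=g)
    eta = L @ Z + b0[:, None]
    rate = np.logaddexp(0.0, eta)  # softplus, numerically stable
    prob = rate / rate.sum(axis=0, keepdims=True)
    counts = rng.poisson(prob * spec.library_size_mean).astype(float)
    if spec.dropout_rate > 0:
        keep = rng.random(counts.shape) >= spec.dropout_rate
        counts = counts * keep
    em = ExpressionMatrix(
        counts,
        feature_ids=[f"gene{i}" for i in range(g)],
        cell_ids=list(meta["cell_id"]),
        layer="counts",
    )
    return em, meta, truth
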