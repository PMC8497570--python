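import numpy as np
import pytest

import atlasmap as am
from atlasmap.integrate import _l2_normalize_columns


def make_embedding_reference(Z_hat_r, R_r, Z_r=None, with_stats=False):
    """Build a MinimalReference directly from an embedding-level integration.

    Uses identity loadings so the reference lives in the embedding space
    itself; convenient for exercising the mapping solver in isolation.
    """
    Z_hat_r = np.asarray(Z_hat_r, float)
    R_r = np.asarray(R_r, float)
    d = Z_hat_r.shape[0]
    Y = am.compute_centroids(Z_hat_r, R_r)
    N_r, C = am.compute_compression_terms(R_r, Z_hat_r)
    extras = {"Z_hat_r": Z_hat_r, "R_r": R_r}
    if with_stats:
        extras["cluster_stats"] = am.compute_cluster_stats(
            Z_r if Z_r is not None else Z_hat_r, R_r
        )
    return am.MinimalReference(
        mu=np.zeros(d), sigma=np.ones(d), loadings=np.eye(d),
        Y_cos=_l2_normalize_columns(Y), N_r=N_r, C=C,
        genes=[f"g{i}" for i in range(d)], d=d, k=R_r.shape[0], extras=extras,
    )


def hard_memberships(labels, k):
    labels = np.asarray(labels)
    R = np.zeros((k, labels.size))
    R[labels, np.arange(labels.size)] = 1.0
    return R


def brute_force_query_betas(R_q, Z_q, X_q, R_r, Z_hat_r, lam=1.0):
    """Independent oracle: ridge solve on the explicit reference+query
    concatenation, with reference design rows all zero."""
    m = Z_q.shape[1]
    n = Z_hat_r.shape[1]
    c = X_q.shape[0]
    Xs = np.vstack([np.ones(m + n), np.hstack([X_q, np.zeros((c, n))])])
    Z = np.hstack([Z_q, Z_hat_r])
    R = np.hstack([R_q, R_r])
    out = []
    for k in range(R.shape[0]):
        W = R[k]
        Lam = np.diag([0.0] + [lam] * c)
        out.append(np.linalg.solve((Xs * W) @ Xs.T + Lam, (Xs * W) @ Z.T))
    return np.stack(out)


@pytest.fixture(scope="session")
def small_counts_fixture():
    """A 2-batch, 5-type counts fixture with moderate batch effects."""
    spec = am.SimulationSpec(
        cells_per_batch=(400, 400), n_genes=150, d_latent=8,
        centroid_separation=8.0, batch_offset_scale=0.4,
        seed=11, structure_seed=7,
    )
    em, meta, truth = am.simulate_counts(spec)
    return spec, em, meta, truth


@pytest.fixture(scope="session")
def small_reference(small_counts_fixture):
    spec, em, meta, _ = small_counts_fixture
    labels = ("type" + meta["cluster"].astype(str)).to_numpy()
    ref = am.build_reference(
        em, meta["batch"].to_numpy(), d=8, k=6, n_variable_genes=120,
        labels=labels, seed=0,
    )
    return ref


@pytest.fixture(scope="session")
def small_query():
    spec = am.SimulationSpec(
        cells_per_batch=(150,), n_genes=150, d_latent=8,
        centroid_separation=8.0, batch_offset_scale=0.4,
        seed=23, structure_seed=7,
    )
    em, meta, truth = am.simulate_counts(spec)
    return spec, em, meta, truth
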