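"""Format adapters: MatrixMarket / dense CSV expression input, metadata TSV,
mapped-query HDF5 containers, and small helpers shared by the CLI."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .mapping import MappedQuery
from .preprocess import ExpressionMatrix

__all__ = [
    "read_expression",
    "write_expression_mtx",
    "read_metadata",
    "write_mapped_query",
    "read_mapped_query",
    "reference_checksum",
]


def read_expression(matrix_path, features_path=None, cells_path=None,
                    layer: str = "counts") -> ExpressionMatrix:
    """Read a features x cells matrix from MTX (+ feature/cell TSVs) or dense CSV/TSV.

    Dense files carry feature ids in the first column and cell ids in the
    header. Orientation is normalized to features x cells internally.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if features_path is None or cells_path is None:
            raise ValueError("MTX input requires features and cells TSV paths")
        values = sp.csc_matrix(scipy.io.mmread(matrix_path))
        features = pd.read_csv(features_path, sep="\t", header=None)[0].tolist()
        cells = pd.read_csv(cells_path, sep="\t", header=None)[0].tolist()
        g, n = values.shape
        if g != len(features) or n != len(cells):
            raise ValueError(
                f"matrix is {g}x{n} but id files list {len(features)} features "
                f"and {len(cells)} cells"
            )
        return ExpressionMatrix(values, features, cells, layer=layer)
    sep = "\t" if matrix_path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(matrix_path, sep=sep, index_col=0)
    return ExpressionMatrix(df.to_numpy(dtype=float), df.index.tolist(),
                            df.columns.tolist(), layer=layer)


def write_expression_mtx(em: ExpressionMatrix, out_dir) -> dict:
    """Write matrix.mtx + features.tsv + barcodes.tsv; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out_dir / "matrix.mtx",
        "features": out_dir / "features.tsv",
        "cells": out_dir / "barcodes.tsv",
    }
    values = em.values if sp.issparse(em.values) else sp.csc_matrix(em.values)
    scipy.io.mmwrite(str(paths["matrix"]), values)
    pd.Series(em.feature_ids).to_csv(paths["features"], sep="\t", index=False, header=False)
    pd.Series(em.cell_ids).to_csv(paths["cells"], sep="\t", index=False, header=False)
    return paths


def read_metadata(path) -> pd.DataFrame:
    """Metadata TSV with a header row; first column indexes cells."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        raise ValueError("duplicated cell ids in metadata")
    return df


def reference_checksum(ref) -> str:
    """SHA-256 over the six required reference elements (provenance tag)."""
    h = hashlib.sha256()
    for arr in (ref.mu, ref.sigma, ref.loadings, ref.Y_cos, ref.N_r, ref.C):
        h.update(np.ascontiguousarray(arr).tobytes())
    h.update("".join(ref.genes).encode())
    return h.hexdigest()


def write_mapped_query(mapped: MappedQuery, path, ref_checksum: str | None = None) -> str:
    with h5py.File(path, "w") as f:
        f.attrs["metadata"] = json.dumps({"reference_checksum": ref_checksum})
        f.create_dataset("Z_q", data=mapped.Z_q)
        f.create_dataset("R_q", data=mapped.R_q)
        f.create_dataset("B_q", data=mapped.B_q)
        f.create_dataset("Z_hat_q", data=mapped.Z_hat_q)
        if mapped.X_q is not None:
            f.create_dataset("X_q", data=mapped.X_q)
        if mapped.cell_ids is not None:
            f.create_dataset("cell_ids", data=np.array(mapped.cell_ids, dtype="S"))
    return str(path)


def read_mapped_query(path) -> MappedQuery:
    with h5py.File(path, "r") as f:
        cell_ids = ([c.decode() for c in f["cell_ids"][()]]
                    if "cell_ids" in f else None)
        return MappedQuery(
            Z_q=f["Z_q"][()], R_q=f["R_q"][()], B_q=f["B_q"][()],
            Z_hat_q=f["Z_hat_q"][()],
            X_q=f["X_q"][()] if "X_q" in f else None,
            cell_ids=cell_ids,
        )
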