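"""Readers and writers for the standard single-cell exchange formats.

Three on-disk representations are supported and mirrored by writers:

* MatrixMarket: ``matrix.mtx`` (features × cells or cells × features, see
  ``cells_as_rows``) next to ``barcodes.tsv`` and ``features.tsv``;
* the h5ad container (via :mod:`anndata`);
* dense delimited text with a header row of feature ids and a first column
  of cell ids.
"""

from __future__ import annotations

import json
import os
from typing import Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix, QC_COLUMNS

LABEL_KEY = "cell_type"


# ---------------------------------------------------------------------------
# MatrixMarket directory (matrix.mtx + barcodes.tsv + features.tsv)
# ---------------------------------------------------------------------------

def write_mtx_dir(m: CountMatrix, path: str, cells_as_rows: bool = True) -> None:
    os.makedirs(path, exist_ok=True)
    mat = sp.coo_matrix(m.counts if cells_as_rows else m.counts.T)
    scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), mat)
    bc = pd.DataFrame({"barcode": m.cell_ids})
    if m.labels is not None:
        bc[LABEL_KEY] = m.labels
    if m.qc is not None:
        for col in m.qc.columns:
            bc[col] = np.asarray(m.qc[col])
    bc.to_csv(os.path.join(path, "barcodes.tsv"), sep="\t", index=False)
    pd.DataFrame({"feature": m.feature_ids}).to_csv(
        os.path.join(path, "features.tsv"), sep="\t", index=False
    )
    with open(os.path.join(path, "meta.json"), "w") as fh:
        json.dump(
            {
                "modality": m.modality,
                "is_normalised": m.is_normalised,
                "is_log": m.is_log,
                "cells_as_rows": cells_as_rows,
            },
            fh,
        )


def read_mtx_dir(path: str, modality: Optional[str] = None) -> CountMatrix:
    mat = scipy.io.mmread(os.path.join(path, "matrix.mtx"))
    mat = np.asarray(sp.coo_matrix(mat).todense(), dtype=np.float64)
    meta = {}
    meta_path = os.path.join(path, "meta.json")
    if os.path.exists(meta_path):
        with open(meta_path) as fh:
            meta = json.load(fh)
    if not meta.get("cells_as_rows", True):
        mat = mat.T
    bc = pd.read_csv(os.path.join(path, "barcodes.tsv"), sep="\t")
    feats = pd.read_csv(os.path.join(path, "features.tsv"), sep="\t")
    labels = bc[LABEL_KEY].to_numpy() if LABEL_KEY in bc else None
    qc_cols = [c for c in QC_COLUMNS if c in bc]
    qc = bc[qc_cols].reset_index(drop=True) if qc_cols else None
    return CountMatrix(
        counts=mat,
        cell_ids=bc.iloc[:, 0].astype(str).to_numpy(),
        feature_ids=feats.iloc[:, 0].astype(str).to_numpy(),
        labels=labels,
        modality=modality or meta.get("modality", "GEX"),
        qc=qc,
        is_normalised=meta.get("is_normalised", False),
        is_log=meta.get("is_log", False),
    )


# ---------------------------------------------------------------------------
# h5ad container
# ---------------------------------------------------------------------------

def to_anndata(m: CountMatrix):
    import anndata as ad

    obs = pd.DataFrame(index=pd.Index(m.cell_ids.astype(str), name="cell_id"))
    if m.labels is not None:
        obs[LABEL_KEY] = pd.Categorical(m.labels.astype(str))
    if m.qc is not None:
        for col in m.qc.columns:
            obs[col] = np.asarray(m.qc[col])
    var = pd.DataFrame(index=pd.Index(m.feature_ids.astype(str), name="feature_id"))
    adata = ad.AnnData(X=m.counts.copy(), obs=obs, var=var)
    adata.uns["scgale"] = {
        "modality": m.modality,
        "is_normalised": m.is_normalised,
        "is_log": m.is_log,
    }
    return adata


def from_anndata(adata, modality: Optional[str] = None) -> CountMatrix:
    X = adata.X
    if sp.issparse(X):
        X = np.asarray(X.todense())
    meta = dict(adata.uns.get("scgale", {}))
    labels = (
        np.asarray(adata.obs[LABEL_KEY]) if LABEL_KEY in adata.obs.columns else None
    )
    qc_cols = [c for c in QC_COLUMNS if c in adata.obs.columns]
    qc = adata.obs[qc_cols].reset_index(drop=True) if qc_cols else None
    return CountMatrix(
        counts=np.asarray(X, dtype=np.float64),
        cell_ids=np.asarray(adata.obs_names, dtype=object),
        feature_ids=np.asarray(adata.var_names, dtype=object),
        labels=labels,
        modality=modality or meta.get("modality", "GEX"),
        qc=qc,
        is_normalised=bool(meta.get("is_normalised", False)),
        is_log=bool(meta.get("is_log", False)),
    )


def write_h5ad(m: CountMatrix, path: str) -> None:
    to_anndata(m).write_h5ad(path)


def read_h5ad(path: str, modality: Optional[str] = None) -> CountMatrix:
    import anndata as ad

    return from_anndata(ad.read_h5ad(path), modality=modality)


# ---------------------------------------------------------------------------
# Dense delimited text
# ---------------------------------------------------------------------------

def write_dense(m: CountMatrix, path: str, sep: str = "\t") -> None:
    df = pd.DataFrame(m.counts, index=m.cell_ids.astype(str),
                      columns=m.feature_ids.astype(str))
    df.index.name = "cell_id"
    df.to_csv(path, sep=sep)


def read_dense(path: str, sep: str = "\t", modality: str = "GEX") -> CountMatrix:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return CountMatrix(
        counts=df.to_numpy(dtype=np.float64),
        cell_ids=df.index.astype(str).to_numpy(dtype=object),
        feature_ids=df.columns.astype(str).to_numpy(dtype=object),
        modality=modality,
    )


# ---------------------------------------------------------------------------
# Auxiliary tables
# ---------------------------------------------------------------------------

def write_labels_tsv(m: CountMatrix, path: str) -> None:
    if m.labels is None:
        raise ValueError("no labels to write")
    pd.DataFrame({"cell_id": m.cell_ids.astype(str), "label": m.labels}).to_csv(
        path, sep="\t", index=False
    )


def write_marker_manifest(marker_sets: dict, feature_ids, path: str) -> None:
    feature_ids = np.asarray(feature_ids)
    payload = {
        str(k): [str(feature_ids[j]) for j in sorted(v)]
        for k, v in marker_sets.items()
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def write_edge_list(graph, path: str) -> None:
    pd.DataFrame(graph.edges, columns=["node_a", "node_b"]).to_csv(
        path, sep="\t", index=False
    )
    with open(path + ".json", "w") as fh:
        json.dump({"k": graph.k, "n": graph.n_nodes, "source": graph.source}, fh)


def write_coords_tsv(cell_ids, coords, path: str, prefix: str = "dim") -> None:
    coords = np.asarray(coords)
    df = pd.DataFrame(
        coords, columns=[f"{prefix}{i + 1}" for i in range(coords.shape[1])]
    )
    df.insert(0, "cell_id", np.asarray(cell_ids).astype(str))
    df.to_csv(path, sep="\t", index=False)
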