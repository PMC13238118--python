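"""In-memory containers shared by every pipeline stage.

`CountMatrix` is the central object: a dense cells × features matrix of
non-negative values with cell/feature identifiers, optional per-cell type
labels, optional per-cell QC columns, and two processing flags
(``is_normalised``, ``is_log``). Raw matrices hold integers; normalisation
and the log transform produce reals.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

MODALITIES = ("GEX", "PEAKS", "WINDOWS")

QC_COLUMNS = ("mito_count", "tss_enrichment", "nucleosome_signal")


@dataclass
class CountMatrix:
    counts: np.ndarray
    cell_ids: np.ndarray
    feature_ids: np.ndarray
    labels: Optional[np.ndarray] = None
    modality: str = "GEX"
    qc: Optional[pd.DataFrame] = None
    is_normalised: bool = False
    is_log: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells × features)")
        n, f = self.counts.shape
        if len(self.cell_ids) != n:
            raise ValueError(f"{len(self.cell_ids)} cell_ids for {n} rows")
        if len(self.feature_ids) != f:
            raise ValueError(f"{len(self.feature_ids)} feature_ids for {f} columns")
        if len(set(self.cell_ids)) != n or len(set(self.feature_ids)) != f:
            raise ValueError("cell_ids and feature_ids must be unique")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != n:
                raise ValueError("labels length must match n_cells")
        if self.qc is not None and len(self.qc) != n:
            raise ValueError("qc rows must match n_cells")
        if self.is_log and not self.is_normalised:
            raise ValueError("is_log implies is_normalised")

    # -- basic views -------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    def label_codes(self):
        """(categories, integer codes) for the labels, deterministic order."""
        if self.labels is None:
            raise ValueError("CountMatrix has no labels")
        cats, codes = np.unique(self.labels, return_inverse=True)
        return cats, codes

    def copy(self) -> "CountMatrix":
        return replace(
            self,
            counts=self.counts.copy(),
            cell_ids=self.cell_ids.copy(),
            feature_ids=self.feature_ids.copy(),
            labels=None if self.labels is None else self.labels.copy(),
            qc=None if self.qc is None else self.qc.copy(),
        )

    def subset_cells(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            counts=self.counts[idx],
            cell_ids=self.cell_ids[idx],
            labels=None if self.labels is None else self.labels[idx],
            qc=None if self.qc is None else self.qc.iloc[idx].reset_index(drop=True),
        )

    def subset_features(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        return replace(
            self,
            counts=self.counts[:, idx],
            feature_ids=self.feature_ids[idx],
        )


@dataclass
class QCReport:
    """What a QC pass removed and why."""

    n_cells_in: int
    n_cells_out: int
    n_features_in: int
    n_features_out: int
    thresholds: dict = field(default_factory=dict)
    removals: dict = field(default_factory=dict)
    skipped_rules: list = field(default_factory=list)

    def __post_init__(self):
        if self.n_cells_out > self.n_cells_in:
            raise ValueError("n_cells_out > n_cells_in")
        if self.n_features_out > self.n_features_in:
            raise ValueError("n_features_out > n_features_in")

    def to_json(self, path=None) -> str:
        payload = {
            "n_cells_in": self.n_cells_in,
            "n_cells_out": self.n_cells_out,
            "n_features_in": self.n_features_in,
            "n_features_out": self.n_features_out,
            "thresholds": self.thresholds,
            "removals": self.removals,
            "skipped_rules": self.skipped_rules,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


@dataclass
class GeometryEmbedding:
    """Low-dimensional manifold coordinates used to regularise the autoencoder."""

    coords: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding coordinates must be finite")

    @property
    def p(self) -> int:
        return self.coords.shape[1]

    @property
    def n_cells(self) -> int:
        return self.coords.shape[0]


@dataclass
class CellGraph:
    """Undirected k-NN cell–cell graph.

    ``edges`` is a (m, 2) array of unordered node pairs (lower index first);
    ``neighbors`` keeps the directed k-nearest lists (n, k) that produced it,
    needed by the neighbourhood-homogeneity metric.
    """

    n_nodes: int
    edges: np.ndarray
    k: int
    neighbors: Optional[np.ndarray] = None
    source: str = ""

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if len(self.edges):
            lo = self.edges.min(axis=1)
            hi = self.edges.max(axis=1)
            if (lo == hi).any():
                raise ValueError("self-loops are not allowed")
            self.edges = np.stack([lo, hi], axis=1)
            order = np.lexsort((self.edges[:, 1], self.edges[:, 0]))
            self.edges = self.edges[order]
            if len(np.unique(self.edges, axis=0)) != len(self.edges):
                raise ValueError("duplicate edges")
            if self.edges.max() >= self.n_nodes:
                raise ValueError("edge index out of range")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        np.add.at(deg, self.edges[:, 0], 1)
        np.add.at(deg, self.edges[:, 1], 1)
        return deg

    def has_edge(self, i: int, j: int) -> bool:
        a, b = min(i, j), max(i, j)
        return bool(((self.edges[:, 0] == a) & (self.edges[:, 1] == b)).any())
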