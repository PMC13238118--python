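"""Undirected k-NN cell–cell graph from a latent coordinate matrix.

Each node is linked to its k nearest neighbours by Euclidean distance
(self excluded); the directed neighbourhoods are then symmetrised by union,
which cannot create isolated nodes. Distance ties are broken by ascending
node index, so the graph is deterministic under fixed input. Edges are
unweighted: the attention mechanism downstream learns edge relevance.
"""

from __future__ import annotations

import numpy as np

from .containers import CellGraph

__all__ = ["knn_graph"]


def knn_graph(latent: np.ndarray, k: int = 15, source: str = "") -> CellGraph:
    X = np.asarray(latent, dtype=np.float64)
    if X.ndim != 2:
        raise ValueError("latent must be 2-D")
    n = X.shape[0]
    if n <= k:
        raise ValueError(f"need more than k={k} cells (got {n})")
    if not np.isfinite(X).all():
        raise ValueError("latent coordinates must be finite")

    sq = (X ** 2).sum(axis=1)
    D2 = sq[:, None] + sq[None, :] - 2.0 * (X @ X.T)
    np.fill_diagonal(D2, np.inf)  # exclude self
    # stable argsort → equal distances resolved by ascending node index
    order = np.argsort(D2, axis=1, kind="stable")
    neighbors = order[:, :k]

    src = np.repeat(np.arange(n), k)
    dst = neighbors.reshape(-1)
    lo = np.minimum(src, dst)
    hi = np.maximum(src, dst)
    edges = np.unique(np.stack([lo, hi], axis=1), axis=0)
    return CellGraph(n_nodes=n, edges=edges, k=k, neighbors=neighbors,
                     source=source)
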