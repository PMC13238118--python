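"""Mask-based post-hoc explanation of the trained graph classifier.

For a node v, the explainer learns a feature mask (shared across the node's
computation subgraph) and a per-edge mask, both squashed through a logistic
function and initialised near 1, that keep the frozen model's prediction at
v while being encouraged to shrink. Maximising the mutual information
between the prediction and the masked (subgraph, features) pair is realised
as the standard surrogate: minimise the cross-entropy between the model's
original predicted class at v and its prediction under the masked inputs,
plus size (mean mask) and elementwise entropy penalties.

Per-cell-type importance is the mean feature mask over the class's nodes
(optionally a seeded stratified subsample); features are ranked by it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import scipy.sparse as sp

from ._autodiff import Adam, Tensor, no_grad, spmm
from .classifier import EdgeIndex, TrainedClassifier
from .containers import CellGraph

__all__ = [
    "ExplainerConfig", "NodeExplanation", "ClassExplanation",
    "node_computation_subgraph", "explain_node", "explain_class",
    "importance_decay",
]

_EPS = 1e-12


@dataclass
class ExplainerConfig:
    epochs: int = 300
    lr: float = 1e-2
    feat_size_weight: float = 1.0
    feat_entropy_weight: float = 0.1
    edge_size_weight: float = 0.005
    edge_entropy_weight: float = 1.0
    init_logit: float = 3.0  # sigmoid(3) ≈ 0.95: masks start near 1
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class NodeExplanation:
    node: int
    feature_mask: np.ndarray
    edge_mask: np.ndarray
    masked_prediction: np.ndarray
    predicted_class: int

    def __post_init__(self):
        for m in (self.feature_mask, self.edge_mask):
            if len(m) and ((m < 0) | (m > 1)).any():
                raise ValueError("masks must lie in [0, 1]")


@dataclass
class ClassExplanation:
    cls: str
    importance: np.ndarray
    feature_ids: np.ndarray
    n_nodes_explained: int = 0

    def __post_init__(self):
        if len(self.importance) != len(self.feature_ids):
            raise ValueError("importance must align with feature ids")
        # descending importance, ties broken by ascending feature index
        self._order = np.lexsort((np.arange(len(self.importance)),
                                  -self.importance))

    @property
    def ranking(self) -> np.ndarray:
        return np.asarray(self.feature_ids)[self._order]

    @property
    def ranked_importance(self) -> np.ndarray:
        return self.importance[self._order]

    def top_set(self, n: int) -> List[str]:
        return list(self.ranking[:n])


def node_computation_subgraph(g: CellGraph, v: int, hops: int = 2):
    """Nodes within `hops` of v and the induced subgraph (relabelled 0..m-1).

    Returns (node index array, sub-CellGraph, local index of v).
    """
    n = g.n_nodes
    rows = np.concatenate([g.edges[:, 0], g.edges[:, 1]])
    cols = np.concatenate([g.edges[:, 1], g.edges[:, 0]])
    adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    frontier = {v}
    nodes = {v}
    for _ in range(hops):
        nxt = set()
        for u in frontier:
            nxt.update(adj.indices[adj.indptr[u]:adj.indptr[u + 1]].tolist())
        nxt -= nodes
        nodes |= nxt
        frontier = nxt
    node_arr = np.array(sorted(nodes))
    local = {int(u): i for i, u in enumerate(node_arr)}
    keep = np.isin(g.edges[:, 0], node_arr) & np.isin(g.edges[:, 1], node_arr)
    sub_edges = np.array(
        [[local[int(a)], local[int(b)]] for a, b in g.edges[keep]], dtype=np.int64
    ).reshape(-1, 2)
    sub = CellGraph(n_nodes=len(node_arr), edges=sub_edges, k=g.k,
                    source=f"{g.source}|sub({v})")
    return node_arr, sub, local[v]


def _bernoulli_entropy(p: Tensor) -> Tensor:
    return -(p * (p + _EPS).log() + (1.0 - p) * (1.0 - p + _EPS).log())


def explain_node(
    model: TrainedClassifier,
    g: CellGraph,
    X: np.ndarray,
    v: int,
    cfg: ExplainerConfig | None = None,
) -> NodeExplanation:
    """Learn feature and edge masks preserving the frozen model's prediction
    at node v. Deterministic under ``cfg.seed``."""
    cfg = cfg or ExplainerConfig()
    if model.net is None:
        raise ValueError("model must be trained before explaining")
    X = np.asarray(X, dtype=np.float64)
    n, F = X.shape
    if not 0 <= v < n:
        raise ValueError("node index out of range")

    # target class from the full-graph prediction (frozen model)
    full_proba = model.predict_proba(X=X)
    yhat = int(np.argmax(full_proba[v]))

    node_arr, sub, v_local = node_computation_subgraph(g, v, hops=2)
    ei = EdgeIndex(sub)
    Xs = X[node_arr]
    m_edges = len(sub.edges)

    rng = np.random.default_rng(cfg.seed)
    fm = Tensor(cfg.init_logit + 0.1 * rng.standard_normal(F), requires_grad=True)
    params = [fm]
    if m_edges:
        em = Tensor(cfg.init_logit + 0.1 * rng.standard_normal(m_edges),
                    requires_grad=True)
        params.append(em)
        # map the undirected-edge mask onto both directed copies; gate = 1
        # on self-loops
        E = ei.n_edges
        rows = np.arange(ei.n_real)
        cols = np.concatenate([np.arange(m_edges), np.arange(m_edges)])
        expand = sp.csr_matrix((np.ones(ei.n_real), (rows, cols)),
                               shape=(E, m_edges))
        self_const = np.zeros(E)
        self_const[ei.n_real:] = 1.0

    opt = Adam(params, lr=cfg.lr)
    onehot = np.zeros((len(node_arr), model.net.n_classes))
    onehot[v_local, yhat] = 1.0

    logp = None
    for _ in range(cfg.epochs):
        feat_gate = fm.sigmoid()
        x_masked = Tensor(Xs) * feat_gate
        if m_edges:
            edge_gate = spmm(expand, em.sigmoid().reshape(-1, 1)).reshape(-1) \
                + Tensor(self_const)
        else:
            edge_gate = None
        logp, _ = model.net.forward(x_masked, ei, edge_gate=edge_gate)
        ce = (logp * onehot).sum() * (-1.0)
        loss = ce \
            + cfg.feat_size_weight * feat_gate.mean() \
            + cfg.feat_entropy_weight * _bernoulli_entropy(feat_gate).mean()
        if m_edges:
            eg = em.sigmoid()
            loss = loss + cfg.edge_size_weight * eg.mean() \
                + cfg.edge_entropy_weight * _bernoulli_entropy(eg).mean()
        opt.zero_grad()
        loss.backward()
        opt.step()

    # evaluate the prediction under the final masks
    with no_grad():
        feat_gate = fm.sigmoid()
        x_masked = Tensor(Xs) * feat_gate
        if m_edges:
            edge_gate = spmm(expand, em.sigmoid().reshape(-1, 1)).reshape(-1) \
                + Tensor(self_const)
        else:
            edge_gate = None
        logp, _ = model.net.forward(x_masked, ei, edge_gate=edge_gate)

    feat_final = 1.0 / (1.0 + np.exp(-fm.data))
    edge_final = (1.0 / (1.0 + np.exp(-em.data))) if m_edges else np.array([])
    masked_pred = np.exp(logp.data[v_local])
    return NodeExplanation(
        node=v,
        feature_mask=np.clip(feat_final, 0.0, 1.0),
        edge_mask=np.clip(edge_final, 0.0, 1.0),
        masked_prediction=masked_pred,
        predicted_class=yhat,
    )


def explain_class(
    model: TrainedClassifier,
    g: CellGraph,
    X: np.ndarray,
    labels: np.ndarray,
    cfg: ExplainerConfig | None = None,
    n_top: int = 50,
    feature_ids: Optional[np.ndarray] = None,
    subsample_cap: Optional[int] = 500,
) -> Dict[str, ClassExplanation]:
    """Average node feature masks within each class and rank features.

    Classes larger than ``subsample_cap`` nodes are represented by a seeded
    uniform subsample (recorded in ``n_nodes_explained``); averaging over a
    subsample is unbiased for the class mean mask.
    """
    cfg = cfg or ExplainerConfig()
    labels = np.asarray(labels)
    X = np.asarray(X, dtype=np.float64)
    if len(labels) == 0 or X.shape[0] == 0:
        raise ValueError("no cells to explain")
    F = X.shape[1]
    if feature_ids is None:
        feature_ids = np.array([f"feat_{j}" for j in range(F)], dtype=object)
    rng = np.random.default_rng(cfg.seed)
    out: Dict[str, ClassExplanation] = {}
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) == 0:
            raise ValueError(f"class {cls!r} has no nodes")
        if subsample_cap is not None and len(idx) > subsample_cap:
            idx = np.sort(rng.choice(idx, size=subsample_cap, replace=False))
        masks = np.zeros((len(idx), F))
        for i, v in enumerate(idx):
            node_cfg = ExplainerConfig(**{**cfg.__dict__, "seed": cfg.seed + int(v)})
            masks[i] = explain_node(model, g, X, int(v), node_cfg).feature_mask
        out[str(cls)] = ClassExplanation(
            cls=str(cls),
            importance=masks.mean(axis=0),
            feature_ids=feature_ids,
            n_nodes_explained=len(idx),
        )
    return out


def importance_decay(e: ClassExplanation) -> np.ndarray:
    """|first differences| of importance along the rank; length F − 1."""
    return np.abs(np.diff(e.ranked_importance))
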