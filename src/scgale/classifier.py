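"""Graph neural network node classifiers: two-layer GAT and a GCN baseline.

The GAT layer computes, for each directed edge (j → i) of the symmetrised
graph augmented with self-loops,

    score_ij = aᵀ LeakyReLU(Θ_s x_i + Θ_t x_j)
    α_ij     = softmax_j(score_ij)          (over j ∈ N(i) ∪ {i})
    x'_i     = Σ_j α_ij Θ_t x_j

Layer 1 uses multi-head attention with concatenated heads and a LeakyReLU
nonlinearity; layer 2 is single-head and produces the class logits, mapped
to probabilities by a softmax. The GCN baseline replaces attention with the
symmetric-normalised adjacency convolution. Both support a per-edge gate in
[0, 1] multiplying the post-softmax attention (or the normalised adjacency
weight), which is how the explainer perturbs the graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import scipy.sparse as sp

from ._autodiff import (Adam, SegmentIndex, Tensor, log_softmax,
                        no_grad, segment_softmax, spmm)
from .containers import CellGraph, CountMatrix

__all__ = [
    "GATConfig", "ClassificationReport", "TrainedClassifier",
    "EdgeIndex", "GATNet", "GCNNet", "train_classifier",
]


class EdgeIndex:
    """Directed edge arrays (both directions of each undirected edge plus a
    self-loop per node) with gather/scatter helpers."""

    def __init__(self, graph: CellGraph):
        n = graph.n_nodes
        e = graph.edges
        loops = np.arange(n)
        self.src = np.concatenate([e[:, 0], e[:, 1], loops])
        self.dst = np.concatenate([e[:, 1], e[:, 0], loops])
        self.n_nodes = n
        self.n_real = 2 * len(e)  # directed non-self edges precede self-loops
        E = len(self.src)
        ones = np.ones(E)
        self.sel_src = sp.csr_matrix((ones, (np.arange(E), self.src)), shape=(E, n))
        self.sel_dst = sp.csr_matrix((ones, (np.arange(E), self.dst)), shape=(E, n))
        self.seg = SegmentIndex(self.dst, n)

    @property
    def n_edges(self) -> int:
        return len(self.src)


@dataclass
class GATConfig:
    hidden_dim: Optional[int] = None  # default: ⌈∛F⌉, the embedding latent dim
    n_heads: int = 4
    lr: float = 5e-3
    weight_decay: float = 5e-4
    max_epochs: int = 300
    patience: int = 30
    split: Tuple[float, float, float] = (0.70, 0.10, 0.20)
    dropout: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")


@dataclass
class ClassificationReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    per_class: Dict[str, Dict[str, float]]
    confusion: np.ndarray
    split_indices: Dict[str, np.ndarray]

    def __post_init__(self):
        for v in (self.accuracy, self.precision, self.recall, self.f1):
            if not 0.0 <= v <= 1.0:
                raise ValueError("metrics must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "per_class": self.per_class,
            "confusion": self.confusion.tolist(),
        }


def _glorot(rng, a, b):
    return rng.normal(0.0, np.sqrt(2.0 / (a + b)), size=(a, b))


class GATNet:
    """Two-layer graph attention network."""

    def __init__(self, in_dim: int, hidden_dim: int, n_classes: int,
                 n_heads: int = 4, seed: int = 0, slope: float = 0.2):
        rng = np.random.default_rng(seed)
        h, H = hidden_dim, n_heads
        self.in_dim, self.hidden_dim = in_dim, hidden_dim
        self.n_classes, self.n_heads = n_classes, n_heads
        self.slope = slope
        self.Ws1 = Tensor(_glorot(rng, in_dim, H * h), requires_grad=True)
        self.Wt1 = Tensor(_glorot(rng, in_dim, H * h), requires_grad=True)
        self.a1 = Tensor(rng.normal(0.0, 0.1, size=(H, h)), requires_grad=True)
        self.Ws2 = Tensor(_glorot(rng, H * h, n_classes), requires_grad=True)
        self.Wt2 = Tensor(_glorot(rng, H * h, n_classes), requires_grad=True)
        self.a2 = Tensor(rng.normal(0.0, 0.1, size=(1, n_classes)),
                         requires_grad=True)

    @property
    def params(self) -> List[Tensor]:
        return [self.Ws1, self.Wt1, self.a1, self.Ws2, self.Wt2, self.a2]

    def _layer(self, Xt: Tensor, ei: EdgeIndex, Ws, Wt, a, heads, out_dim,
               edge_gate, training, rng, dropout):
        Hs = Xt @ Ws
        Ht = Xt @ Wt
        Hs_d = spmm(ei.sel_dst, Hs).reshape(-1, heads, out_dim)
        Ht_s = spmm(ei.sel_src, Ht).reshape(-1, heads, out_dim)
        score = ((Hs_d + Ht_s).leaky_relu(self.slope) * a).sum(axis=2)
        alpha = segment_softmax(score, ei.seg)  # rows sum to 1 per target node
        alpha_raw = alpha.data.copy()
        if edge_gate is not None:
            alpha = alpha * edge_gate.reshape(-1, 1)
        if training and dropout > 0:
            keep = (rng.random(alpha.data.shape) >= dropout) / (1.0 - dropout)
            alpha = alpha * keep
        msg = alpha.reshape(-1, heads, 1) * Ht_s
        return spmm(ei.seg.scatter, msg.reshape(-1, heads * out_dim)), alpha_raw

    def forward(self, X, ei: EdgeIndex, training: bool = False,
                rng: Optional[np.random.Generator] = None, dropout: float = 0.0,
                edge_gate: Optional[Tensor] = None):
        """Returns (log-probabilities (n, C), [layer-1 α, layer-2 α])."""
        Xt = X if isinstance(X, Tensor) else Tensor(np.asarray(X, float))
        if Xt.shape[0] != ei.n_nodes:
            raise ValueError("node features and graph disagree on node count")
        if training and dropout > 0:
            keep = (rng.random(Xt.data.shape) >= dropout) / (1.0 - dropout)
            Xt = Xt * keep
        h1, alpha1 = self._layer(Xt, ei, self.Ws1, self.Wt1, self.a1,
                                 self.n_heads, self.hidden_dim,
                                 edge_gate, training, rng, dropout)
        h1 = h1.leaky_relu(self.slope)
        logits, alpha2 = self._layer(h1, ei, self.Ws2, self.Wt2, self.a2,
                                     1, self.n_classes,
                                     edge_gate, training, rng, dropout)
        return log_softmax(logits), [alpha1, alpha2]


class GCNNet:
    """Two-layer graph convolution with symmetric adjacency normalisation."""

    def __init__(self, in_dim: int, hidden_dim: int, n_classes: int,
                 seed: int = 0, slope: float = 0.2):
        rng = np.random.default_rng(seed)
        self.in_dim, self.hidden_dim, self.n_classes = in_dim, hidden_dim, n_classes
        self.slope = slope
        self.W1 = Tensor(_glorot(rng, in_dim, hidden_dim), requires_grad=True)
        self.b1 = Tensor(np.zeros(hidden_dim), requires_grad=True)
        self.W2 = Tensor(_glorot(rng, hidden_dim, n_classes), requires_grad=True)
        self.b2 = Tensor(np.zeros(n_classes), requires_grad=True)

    @property
    def params(self) -> List[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]

    @staticmethod
    def _edge_weights(ei: EdgeIndex) -> np.ndarray:
        deg = np.bincount(ei.dst, minlength=ei.n_nodes).astype(float)
        return 1.0 / np.sqrt(deg[ei.src] * deg[ei.dst])

    def _conv(self, Ht: Tensor, ei: EdgeIndex, weights, edge_gate):
        w = Tensor(weights.reshape(-1, 1))
        gathered = spmm(ei.sel_src, Ht)
        msg = gathered * w
        if edge_gate is not None:
            msg = msg * edge_gate.reshape(-1, 1)
        return spmm(ei.seg.scatter, msg)

    def forward(self, X, ei: EdgeIndex, training: bool = False,
                rng: Optional[np.random.Generator] = None, dropout: float = 0.0,
                edge_gate: Optional[Tensor] = None):
        Xt = X if isinstance(X, Tensor) else Tensor(np.asarray(X, float))
        if Xt.shape[0] != ei.n_nodes:
            raise ValueError("node features and graph disagree on node count")
        if training and dropout > 0:
            keep = (rng.random(Xt.data.shape) >= dropout) / (1.0 - dropout)
            Xt = Xt * keep
        w = self._edge_weights(ei)
        h = (self._conv(Xt, ei, w, edge_gate) @ self.W1 + self.b1).leaky_relu(
            self.slope
        )
        logits = self._conv(h, ei, w, edge_gate) @ self.W2 + self.b2
        return log_softmax(logits), []


@dataclass
class TrainedClassifier:
    arch: str
    net: object
    classes: np.ndarray
    edge_index: EdgeIndex
    history: List[dict] = field(default_factory=list)

    def predict_proba(self, graph: Optional[CellGraph] = None,
                      X: Optional[np.ndarray] = None) -> np.ndarray:
        ei = EdgeIndex(graph) if graph is not None else self.edge_index
        with no_grad():
            logp, _ = self.net.forward(X, ei)
        return np.exp(logp.data)

    def predict(self, graph: Optional[CellGraph] = None,
                X: Optional[np.ndarray] = None) -> np.ndarray:
        proba = self.predict_proba(graph, X)
        return self.classes[np.argmax(proba, axis=1)]


def stratified_split(codes: np.ndarray, fractions, seed: int):
    """Seeded per-class split into train/val/test index arrays."""
    rng = np.random.default_rng(seed)
    tr, va, te = [], [], []
    f_tr, f_va, _ = fractions
    for c in np.unique(codes):
        idx = np.flatnonzero(codes == c)
        rng.shuffle(idx)
        n = len(idx)
        n_tr = int(round(f_tr * n))
        n_va = int(round(f_va * n))
        n_tr = max(1, min(n_tr, n - 2)) if n >= 3 else n_tr
        n_va = max(1, min(n_va, n - n_tr - 1)) if n - n_tr >= 2 else 0
        tr.append(idx[:n_tr])
        va.append(idx[n_tr:n_tr + n_va])
        te.append(idx[n_tr + n_va:])
    tr = np.sort(np.concatenate(tr))
    va = np.sort(np.concatenate(va))
    te = np.sort(np.concatenate(te))
    for c in np.unique(codes):
        if not np.isin(c, codes[tr]).any():
            raise ValueError(f"class {c} absent from the training split")
    return tr, va, te


def _nll(logp: Tensor, onehot: np.ndarray) -> Tensor:
    n = onehot.sum()
    return (logp * onehot).sum() * (-1.0 / n)


def train_classifier(
    g: CellGraph,
    m: CountMatrix,
    cfg: GATConfig | None = None,
    arch: str = "GAT",
) -> Tuple[TrainedClassifier, ClassificationReport]:
    """Train a GAT or GCN on the cell graph with a stratified 70/10/20 split.

    Cross-entropy on training nodes, Adam, early stopping on validation loss
    (patience 30, at most 300 epochs), best weights restored; the report is
    computed on test nodes only with macro-averaged metrics.
    """
    from sklearn.metrics import (accuracy_score, confusion_matrix,
                                 precision_recall_fscore_support)

    cfg = cfg or GATConfig()
    if m.labels is None:
        raise ValueError("classifier training requires cell labels")
    if g.n_nodes != m.n_cells:
        raise ValueError("graph and matrix disagree on cell count")
    classes, codes = m.label_codes()
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    X = np.asarray(m.counts, dtype=np.float64)
    n, F = X.shape
    C = len(classes)
    hidden = cfg.hidden_dim or int(np.ceil(np.cbrt(F)))

    ei = EdgeIndex(g)
    if arch == "GAT":
        net = GATNet(F, hidden, C, n_heads=cfg.n_heads, seed=cfg.seed)
    elif arch == "GCN":
        net = GCNNet(F, hidden, C, seed=cfg.seed)
    else:
        raise ValueError("arch must be 'GAT' or 'GCN'")

    tr, va, te = stratified_split(codes, cfg.split, cfg.seed)
    onehot = np.zeros((n, C))
    onehot[np.arange(n), codes] = 1.0
    oh_tr = np.where(np.isin(np.arange(n), tr)[:, None], onehot, 0.0)
    oh_va = np.where(np.isin(np.arange(n), va)[:, None], onehot, 0.0)

    rng = np.random.default_rng(cfg.seed)
    opt = Adam(net.params, lr=cfg.lr, weight_decay=cfg.weight_decay)
    history: List[dict] = []
    best_val, since_best = np.inf, 0
    best_state = [p.data.copy() for p in net.params]
    for epoch in range(cfg.max_epochs):
        logp, alphas = net.forward(X, ei, training=True, rng=rng,
                                   dropout=cfg.dropout)
        loss = _nll(logp, oh_tr)
        opt.zero_grad()
        loss.backward()
        opt.step()

        with no_grad():
            logp_eval, alphas_eval = net.forward(X, ei)
        val_loss = float(_nll(logp_eval, oh_va).data)
        dev = max(
            (float(np.abs(ei.seg.scatter @ a - 1.0).max()) for a in alphas_eval),
            default=0.0,
        )
        history.append({
            "epoch": epoch,
            "train_loss": float(loss.data),
            "val_loss": val_loss,
            "alpha_rowsum_max_dev": dev,
        })
        if val_loss < best_val - 1e-12:
            best_val, since_best = val_loss, 0
            best_state = [p.data.copy() for p in net.params]
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    for p, s in zip(net.params, best_state):
        p.data = s

    clf = TrainedClassifier(arch=arch, net=net, classes=classes,
                            edge_index=ei, history=history)
    pred = np.argmax(clf.predict_proba(X=X), axis=1)
    y_true, y_pred = codes[te], pred[te]
    labels_idx = np.arange(C)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels_idx, average="macro", zero_division=0
    )
    p_c, r_c, f_c, s_c = precision_recall_fscore_support(
        y_true, y_pred, labels=labels_idx, average=None, zero_division=0
    )
    report = ClassificationReport(
        accuracy=float(accuracy_score(y_true, y_pred)),
        precision=float(prec),
        recall=float(rec),
        f1=float(f1),
        per_class={
            str(classes[c]): {
                "precision": float(p_c[c]), "recall": float(r_c[c]),
                "f1": float(f_c[c]), "support": int(s_c[c]),
            }
            for c in labels_idx
        },
        confusion=confusion_matrix(y_true, y_pred, labels=labels_idx),
        split_indices={"train": tr, "val": va, "test": te},
    )
    return clf, report
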