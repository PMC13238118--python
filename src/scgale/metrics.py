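"""Quantitative evaluation metrics for reconstruction, graph structure and
explanations.

Reconstruction: MSE, Spearman (flattened entries, midranks), the
coverage-restricted MSE variants (top 1% most-covered features, coverage on
the observed or the imputed matrix), and the negative-binomial negative
log-likelihood with Var = mu + mu²/theta.

Graph: neighbourhood homogeneity — per cell the number of distinct label
values among its k directed nearest neighbours (self excluded), divided by
k·C; homogeneity is one minus the mean of that heterogeneity.

Explanations: specificity (1 − mean cross-class top-n overlap), stability
(mean same-class top-n overlap across runs), technical-bias overlaps,
signal-to-noise ratios, and the overlap between explainer and
differential-analysis feature sets. Set overlaps are |A∩B|/n.
"""

from __future__ import annotations

from itertools import combinations
from typing import Dict, Iterable, List, Sequence

import numpy as np
from scipy import stats

from .containers import CellGraph, CountMatrix

__all__ = [
    "mse", "spearman", "mse_top_covered", "nb_loss", "estimate_nb_dispersion",
    "homogeneity", "specificity", "stability", "feature_coverage",
    "feature_expression", "bias_overlap", "stn_ratio", "xai_da_similarity",
]

_EPS = 1e-8


def _as_arrays(X, Xhat):
    X = np.asarray(X, dtype=np.float64)
    Xhat = np.asarray(Xhat, dtype=np.float64)
    if X.shape != Xhat.shape:
        raise ValueError("matrices must have equal shapes")
    return X, Xhat


def mse(X, Xhat) -> float:
    X, Xhat = _as_arrays(X, Xhat)
    return float(np.mean((X - Xhat) ** 2))


def spearman(X, Xhat, per_feature: bool = False) -> float:
    """Spearman rank correlation over the flattened entry pairs (default),
    or averaged per feature column when ``per_feature`` is set."""
    X, Xhat = _as_arrays(X, Xhat)
    if per_feature:
        vals = []
        for j in range(X.shape[1]):
            if np.ptp(X[:, j]) == 0 or np.ptp(Xhat[:, j]) == 0:
                continue
            vals.append(stats.spearmanr(X[:, j], Xhat[:, j]).statistic)
        if not vals:
            raise ValueError("Spearman undefined: all columns constant")
        return float(np.mean(vals))
    x, y = X.ravel(), Xhat.ravel()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman undefined for a constant matrix")
    return float(stats.spearmanr(x, y).statistic)


def mse_top_covered(X_obs, Xhat, basis: str = "observed",
                    top_frac: float = 0.01) -> float:
    """MSE restricted to the ⌈top_frac·F⌉ most-covered features.

    Coverage (number of cells with a non-zero value) is computed on the
    observed matrix (``basis='observed'``) or the imputed/reconstructed one
    (``basis='imputed'``). Ties break by ascending feature index.
    """
    X_obs, Xhat = _as_arrays(X_obs, Xhat)
    if basis not in ("observed", "imputed"):
        raise ValueError("basis must be 'observed' or 'imputed'")
    ref = X_obs if basis == "observed" else Xhat
    coverage = (np.abs(ref) > 0).sum(axis=0)
    F = X_obs.shape[1]
    k = int(np.ceil(top_frac * F))
    top = np.argsort(-coverage, kind="stable")[:k]
    return float(np.mean((X_obs[:, top] - Xhat[:, top]) ** 2))


def nb_loss(X_obs, mu, theta: float) -> float:
    """Mean NB negative log-likelihood of integer counts under mean ``mu``
    and inverse-dispersion ``theta`` (Var = mu + mu²/theta)."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    X_obs, mu = _as_arrays(X_obs, mu)
    if (X_obs < 0).any():
        raise ValueError("observed counts must be non-negative")
    mu = np.maximum(mu, _EPS)
    p = theta / (theta + mu)
    logpmf = stats.nbinom.logpmf(np.round(X_obs).astype(np.int64), theta, p)
    return float(-logpmf.mean())


def estimate_nb_dispersion(X) -> float:
    """Global method-of-moments inverse-dispersion from an observed matrix."""
    X = np.asarray(X, dtype=np.float64)
    m = X.mean()
    v = X.var()
    if v <= m:
        return 1e6  # effectively Poisson
    return float(m ** 2 / (v - m))


def homogeneity(g: CellGraph, labels: Sequence, k: int | None = None,
                n_classes: int | None = None) -> float:
    """1 − mean over cells of (distinct neighbour types) / (k · C).

    Uses the directed k-nearest neighbourhoods stored on the graph (exactly
    k per cell, self excluded), so the divisor k is exact.
    """
    labels = np.asarray(labels)
    if len(labels) != g.n_nodes:
        raise ValueError("labels must cover all nodes")
    if g.neighbors is None:
        raise ValueError("graph lacks directed neighbour lists")
    k = k or g.k
    _, codes = np.unique(labels, return_inverse=True)
    C = n_classes or int(codes.max()) + 1
    if C < 1:
        raise ValueError("need at least one class")
    neigh_labels = codes[g.neighbors[:, :k]]
    distinct = np.array([len(np.unique(row)) for row in neigh_labels])
    heterogeneity = distinct / (k * C)
    return float(1.0 - heterogeneity.mean())


def _pair_overlap(a: Iterable, b: Iterable, n: int) -> float:
    return len(set(a) & set(b)) / n


def specificity(explanations: Dict[str, Sequence], n: int = 50) -> float:
    """1 − mean cross-class overlap of the top-n sets."""
    sets = {c: list(s) for c, s in explanations.items()}
    if len(sets) < 2:
        raise ValueError("need at least 2 classes")
    for c, s in sets.items():
        if len(s) != n:
            raise ValueError(f"class {c!r} set has size {len(s)}, expected {n}")
    overlaps = [
        _pair_overlap(sets[a], sets[b], n) for a, b in combinations(sets, 2)
    ]
    return float(1.0 - np.mean(overlaps))


def stability(runs: List[Dict[str, Sequence]], n: int = 50) -> float:
    """Mean over classes of the mean pairwise overlap across runs."""
    if len(runs) < 2:
        raise ValueError("need at least 2 runs")
    classes = set(runs[0])
    for i, run in enumerate(runs):
        for c in classes:
            if c not in run:
                raise ValueError(f"run {i} is missing class {c!r}")
            if len(run[c]) != n:
                raise ValueError(
                    f"run {i} class {c!r} set has size {len(run[c])}, expected {n}"
                )
    per_class = []
    for c in sorted(classes):
        overlaps = [
            _pair_overlap(r1[c], r2[c], n) for r1, r2 in combinations(runs, 2)
        ]
        per_class.append(np.mean(overlaps))
    return float(np.mean(per_class))


def feature_coverage(m: CountMatrix) -> np.ndarray:
    """Number of cells in which each feature is detected (non-zero)."""
    return (m.counts > 0).sum(axis=0)


def feature_expression(m: CountMatrix) -> np.ndarray:
    """Total signal (column sum) per feature."""
    return m.counts.sum(axis=0)


def bias_overlap(feature_set: Sequence, m: CountMatrix,
                 criterion: str = "expression") -> float:
    """Overlap of a feature set with the equally-sized top set by a
    technical criterion (total expression/openness or coverage)."""
    if criterion == "expression":
        values = feature_expression(m)
    elif criterion == "coverage":
        values = feature_coverage(m)
    else:
        raise ValueError("criterion must be 'expression' or 'coverage'")
    feature_set = list(feature_set)
    n = len(feature_set)
    if n > m.n_features:
        raise ValueError("feature set larger than the matrix")
    order = np.argsort(-values, kind="stable")[:n]
    top_ids = set(np.asarray(m.feature_ids)[order].astype(str))
    return len(set(map(str, feature_set)) & top_ids) / n


def stn_ratio(feature_set: Sequence, m: CountMatrix, labels: Sequence,
              cls) -> float:
    """Mean signal-to-noise ratio of the set's features for one class:
    (mean inside − mean outside) / (sd inside + sd outside + ε)."""
    labels = np.asarray(labels)
    mask = labels == cls
    if not mask.any():
        raise ValueError(f"class {cls!r} not present")
    ids = {str(f): j for j, f in enumerate(np.asarray(m.feature_ids).astype(str))}
    ratios = []
    for f in feature_set:
        j = ids[str(f)]
        col = m.counts[:, j]
        inside, outside = col[mask], col[~mask]
        ratios.append(
            (inside.mean() - outside.mean())
            / (inside.std() + outside.std() + _EPS)
        )
    return float(np.mean(ratios))


def xai_da_similarity(xaif: Sequence, daf: Sequence, n: int = 50,
                      jaccard: bool = False) -> float:
    """Overlap between explainer-derived and differential top-n feature sets
    (|A∩B|/n by default; Jaccard behind the flag)."""
    xaif, daf = set(map(str, xaif)), set(map(str, daf))
    if len(xaif) != n or len(daf) != n:
        raise ValueError("both sets must have size n")
    inter = len(xaif & daf)
    if jaccard:
        return inter / len(xaif | daf)
    return inter / n
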