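"""Seeded synthetic count matrices with planted structure.

Two generators cover the data regimes the pipeline assumes:

* :func:`generate_counts` — discrete cell types, each with a disjoint block
  of marker features whose negative-binomial mean is shifted by a known
  log2 fold-change; technical zeros added as independent per-entry dropout.
* :func:`generate_trajectory_counts` — cells along a continuous pseudotime
  on one or more branches, with branch-specific features following a
  sigmoidal mean profile; labels discretise branch × pseudotime bin.

The NB parameterisation is mean ``mu`` with inverse-dispersion ``theta``
(Var = mu + mu²/theta), shared with the NB reconstruction loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Set, Tuple

import numpy as np

from .containers import CountMatrix

__all__ = ["SyntheticSpec", "GroundTruth", "generate_counts",
           "generate_trajectory_counts"]


@dataclass
class SyntheticSpec:
    n_cells: int = 2000
    n_features: int = 500
    n_types: int = 4
    markers_per_type: int = 20
    effect_log2fc: float = 2.0
    base_mean: float = 2.0
    nb_dispersion: float = 2.0
    dropout_p: float = 0.3
    type_proportions: Optional[np.ndarray] = None
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1 or self.n_features < 1 or self.n_types < 1:
            raise ValueError("n_cells, n_features, n_types must be positive")
        if self.markers_per_type < 0:
            raise ValueError("markers_per_type must be non-negative")
        if self.effect_log2fc < 0:
            raise ValueError("effect_log2fc must be >= 0")
        if self.base_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("base_mean and nb_dispersion must be positive")
        if not 0.0 <= self.dropout_p <= 1.0:
            raise ValueError("dropout_p must be in [0, 1]")
        if self.markers_per_type * self.n_types > self.n_features:
            raise ValueError(
                "markers_per_type × n_types exceeds n_features; "
                "disjoint marker sets are impossible"
            )
        if self.type_proportions is None:
            self.type_proportions = np.full(self.n_types, 1.0 / self.n_types)
        self.type_proportions = np.asarray(self.type_proportions, dtype=np.float64)
        if len(self.type_proportions) != self.n_types:
            raise ValueError("type_proportions length must equal n_types")
        if (self.type_proportions <= 0).any():
            raise ValueError("type_proportions entries must be > 0")
        if abs(self.type_proportions.sum() - 1.0) > 1e-9:
            raise ValueError("type_proportions must sum to 1")


@dataclass
class GroundTruth:
    """Planted structure behind a synthetic matrix.

    ``marker_sets`` maps a group index (cell type, or branch for trajectory
    data) to a set of feature indices; sets are pairwise disjoint.
    """

    labels: np.ndarray
    marker_sets: Dict[int, Set[int]]
    mean_matrix: np.ndarray
    pseudotime: Optional[np.ndarray] = None
    branch: Optional[np.ndarray] = None

    def __post_init__(self):
        seen: Set[int] = set()
        for s in self.marker_sets.values():
            if seen & set(s):
                raise ValueError("marker sets must be pairwise disjoint")
            seen |= set(s)
        if len(np.unique(self.labels)) < 1:
            raise ValueError("labels must be non-empty")


def _allocate_labels(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """Deterministic largest-remainder allocation, then a seeded shuffle."""
    raw = spec.type_proportions * spec.n_cells
    counts = np.floor(raw).astype(int)
    counts = np.maximum(counts, 1)  # every type occurs at least once
    while counts.sum() > spec.n_cells:
        counts[np.argmax(counts)] -= 1
    rema = raw - np.floor(raw)
    order = np.argsort(-rema, kind="stable")
    i = 0
    while counts.sum() < spec.n_cells:
        counts[order[i % spec.n_types]] += 1
        i += 1
    labels = np.repeat(np.arange(spec.n_types), counts)
    rng.shuffle(labels)
    return labels


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p).astype(np.float64)


def generate_counts(spec: SyntheticSpec) -> Tuple[CountMatrix, GroundTruth]:
    """Sample a cells × features NB count matrix with planted marker blocks.

    Marker feature j of type c has NB mean ``base_mean · 2**effect_log2fc``
    in cells of type c and ``base_mean`` elsewhere; after sampling, each
    entry is independently zeroed with probability ``dropout_p``.
    """
    rng = np.random.default_rng(spec.seed)
    labels = _allocate_labels(spec, rng)

    mean_matrix = np.full((spec.n_types, spec.n_features), spec.base_mean)
    marker_sets: Dict[int, Set[int]] = {}
    fc = 2.0 ** spec.effect_log2fc
    for c in range(spec.n_types):
        block = range(c * spec.markers_per_type, (c + 1) * spec.markers_per_type)
        marker_sets[c] = set(block)
        mean_matrix[c, list(block)] = spec.base_mean * fc

    mu = mean_matrix[labels]
    counts = _nb_sample(rng, mu, spec.nb_dispersion)
    if spec.dropout_p > 0:
        drop = rng.random(counts.shape) < spec.dropout_p
        counts[drop] = 0.0

    m = CountMatrix(
        counts=counts,
        cell_ids=np.array([f"cell_{i}" for i in range(spec.n_cells)], dtype=object),
        feature_ids=np.array(
            [f"feat_{j}" for j in range(spec.n_features)], dtype=object
        ),
        labels=np.array([f"type_{c}" for c in labels], dtype=object),
        modality="GEX",
    )
    return m, GroundTruth(labels=labels, marker_sets=marker_sets,
                          mean_matrix=mean_matrix)


def generate_trajectory_counts(
    spec: SyntheticSpec,
    n_branches: int = 1,
    n_bins: int = 2,
    sigmoid_steepness: float = 10.0,
    nb_noise: bool = True,
) -> Tuple[CountMatrix, GroundTruth]:
    """Cells on 1-D pseudotime per branch with sigmoidal feature programmes.

    Each branch owns a disjoint block of ``markers_per_type`` features whose
    mean rises sigmoidally from ``base_mean`` to ``base_mean·2**effect_log2fc``
    along pseudotime for cells of that branch. Labels are branch ×
    pseudotime-bin. With ``nb_noise=False`` the rounded means are returned
    directly (a noise-free fixture; dropout still applies).
    """
    if n_branches < 1:
        raise ValueError("n_branches must be >= 1")
    if spec.markers_per_type * n_branches > spec.n_features:
        raise ValueError("branch feature blocks exceed n_features")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells
    branch = rng.integers(0, n_branches, size=n)
    pseudotime = rng.random(n)
    bins = np.minimum((pseudotime * n_bins).astype(int), n_bins - 1)
    labels = branch * n_bins + bins

    fc = 2.0 ** spec.effect_log2fc
    mu = np.full((n, spec.n_features), spec.base_mean)
    marker_sets: Dict[int, Set[int]] = {}
    for b in range(n_branches):
        block = np.arange(b * spec.markers_per_type, (b + 1) * spec.markers_per_type)
        marker_sets[b] = set(int(j) for j in block)
        on = branch == b
        s = 1.0 / (1.0 + np.exp(-sigmoid_steepness * (pseudotime[on] - 0.5)))
        mu[np.ix_(on, block)] = spec.base_mean * (1.0 + (fc - 1.0) * s)[:, None]

    counts = _nb_sample(rng, mu, spec.nb_dispersion) if nb_noise else np.round(mu)
    if spec.dropout_p > 0:
        drop = rng.random(counts.shape) < spec.dropout_p
        counts[drop] = 0.0

    n_labels = n_branches * n_bins
    mean_matrix = np.zeros((n_labels, spec.n_features))
    for lab in range(n_labels):
        sel = labels == lab
        mean_matrix[lab] = mu[sel].mean(axis=0) if sel.any() else spec.base_mean

    m = CountMatrix(
        counts=counts,
        cell_ids=np.array([f"cell_{i}" for i in range(n)], dtype=object),
        feature_ids=np.array(
            [f"feat_{j}" for j in range(spec.n_features)], dtype=object
        ),
        labels=np.array([f"b{b}_t{t}" for b, t in zip(branch, bins)], dtype=object),
        modality="GEX",
    )
    return m, GroundTruth(
        labels=labels,
        marker_sets=marker_sets,
        mean_matrix=mean_matrix,
        pseudotime=pseudotime,
        branch=branch,
    )
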