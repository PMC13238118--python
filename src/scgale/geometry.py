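"""Diffusion-potential manifold embedding (the geometric target Ξ).

The procedure follows the PHATE family of diffusion methods: an
adaptive-bandwidth alpha-decay kernel over pairwise Euclidean distances, a
row-stochastic diffusion operator raised to a power chosen at the knee of
the von Neumann entropy curve, log-potential distances, and metric MDS
(classical solution refined by SMACOF stress majorisation) down to ``p``
dimensions. The coordinates regularise the autoencoder latent space, so
``p`` defaults to the autoencoder's latent dimension.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .containers import CountMatrix, GeometryEmbedding

__all__ = [
    "GeometryParams", "alpha_decay_kernel", "diffusion_operator",
    "von_neumann_entropy", "knee_point", "potential_distances",
    "classical_mds", "phate_embed",
]


@dataclass
class GeometryParams:
    knn_bandwidth_k: int = 5
    alpha_decay: float = 40.0
    diffusion_time_t: int | str = "auto"
    t_max: int = 100
    mds_max_iter: int = 300
    seed: int = 0


def _pairwise(X: np.ndarray) -> np.ndarray:
    return squareform(pdist(np.asarray(X, dtype=np.float64)))


def alpha_decay_kernel(D: np.ndarray, k: int = 5, alpha: float = 40.0) -> np.ndarray:
    """Symmetric adaptive-bandwidth kernel
    K_ij = ½[exp(−(d_ij/σ_i)^α) + exp(−(d_ij/σ_j)^α)]
    with σ_i the distance to the k-th nearest neighbour (self excluded).
    Zero bandwidths (duplicate rows) are floored at the smallest positive
    pairwise distance; a fully degenerate distance matrix gives K = 1.
    """
    n = D.shape[0]
    if n <= k:
        raise ValueError("need more cells than knn_bandwidth_k")
    order = np.sort(D, axis=1)
    sigma = order[:, k]  # column 0 is the self-distance 0
    positive = D[D > 0]
    if positive.size == 0:
        return np.ones_like(D)
    floor = positive.min()
    sigma = np.maximum(sigma, floor)
    with np.errstate(over="ignore"):
        A = np.exp(-np.power(D / sigma[:, None], alpha))
        B = np.exp(-np.power(D / sigma[None, :], alpha))
    return 0.5 * (A + B)


def diffusion_operator(K: np.ndarray) -> np.ndarray:
    """Row-normalise a kernel into a row-stochastic diffusion operator."""
    rows = K.sum(axis=1)
    if (rows <= 0).any():
        raise ValueError("kernel has an all-zero row")
    return K / rows[:, None]


def _symmetric_spectrum(K: np.ndarray):
    """Eigendecomposition of the symmetric conjugate of P = D⁻¹K."""
    d = K.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    A = K * inv_sqrt[:, None] * inv_sqrt[None, :]
    A = 0.5 * (A + A.T)
    lam, V = np.linalg.eigh(A)
    return lam, V, inv_sqrt


def von_neumann_entropy(K: np.ndarray, t_max: int = 100) -> np.ndarray:
    """Entropy of the diffusion spectrum for t = 1..t_max."""
    lam, _, _ = _symmetric_spectrum(K)
    lam = np.abs(lam)
    H = np.empty(t_max)
    for i, t in enumerate(range(1, t_max + 1)):
        powed = lam ** t
        s = powed.sum()
        if s <= 0:
            H[i] = 0.0
            continue
        eta = powed / s
        nz = eta > 0
        H[i] = float(-(eta[nz] * np.log(eta[nz])).sum())
    return H


def knee_point(values: np.ndarray) -> int:
    """1-based index of the point farthest from the chord between endpoints."""
    n = len(values)
    x = np.arange(n, dtype=float)
    y = np.asarray(values, dtype=float)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    if norm == 0:
        return 1
    dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / norm
    return int(np.argmax(dist)) + 1


def potential_distances(
    X: np.ndarray, params: GeometryParams | None = None
) -> tuple[np.ndarray, int]:
    """Pairwise distances between rows of the log diffusion potential.

    Returns (distance matrix, diffusion time used).
    """
    params = params or GeometryParams()
    D = _pairwise(X)
    K = alpha_decay_kernel(D, k=params.knn_bandwidth_k, alpha=params.alpha_decay)
    lam, V, inv_sqrt = _symmetric_spectrum(K)
    if params.diffusion_time_t == "auto":
        H = von_neumann_entropy(K, t_max=params.t_max)
        t = knee_point(H)
    else:
        t = int(params.diffusion_time_t)
        if t < 1:
            raise ValueError("diffusion time must be >= 1")
    # P^t = D^{-1/2} V Λ^t Vᵀ D^{1/2}
    Pt = (V * (lam ** t)) @ V.T
    Pt = (inv_sqrt[:, None] * Pt) / inv_sqrt[None, :]
    eps = np.finfo(np.float64).eps
    U = -np.log(np.maximum(Pt, 0.0) + eps)
    return _pairwise(U), t


def classical_mds(D: np.ndarray, p: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    lam, V = np.linalg.eigh(B)
    idx = np.argsort(lam)[::-1][:p]
    lam_top = np.maximum(lam[idx], 0.0)
    return V[:, idx] * np.sqrt(lam_top)[None, :]


def phate_embed(
    m: CountMatrix | np.ndarray,
    p: int | None = None,
    params: GeometryParams | None = None,
) -> GeometryEmbedding:
    """Embed cells into ``p`` dimensions preserving diffusion geometry.

    ``p`` defaults to ⌈∛F⌉ so the coordinates are commensurate with the
    autoencoder latent space they regularise. Deterministic given the seed.
    """
    from sklearn.manifold import smacof

    params = params or GeometryParams()
    X = m.counts if isinstance(m, CountMatrix) else np.asarray(m, dtype=np.float64)
    n, F = X.shape
    if p is None:
        p = int(np.ceil(np.cbrt(F)))
    if n <= p:
        raise ValueError("need more cells than embedding dimensions")
    if not np.isfinite(X).all():
        raise ValueError("input contains non-finite values")

    PD, t = potential_distances(X, params)
    init = classical_mds(PD, p)
    if np.allclose(PD, 0.0):
        coords = np.zeros((n, p))
        stress = 0.0
    else:
        coords, stress = smacof(
            PD,
            n_components=p,
            init=init,
            n_init=1,
            metric=True,
            max_iter=params.mds_max_iter,
            random_state=params.seed,
            normalized_stress=False,
        )
    return GeometryEmbedding(
        coords=coords,
        params={
            "knn_bandwidth_k": params.knn_bandwidth_k,
            "alpha_decay": params.alpha_decay,
            "diffusion_time_t": t,
            "mds_max_iter": params.mds_max_iter,
            "seed": params.seed,
            "stress": float(stress),
            "p": p,
        },
    )
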