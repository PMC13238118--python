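"""Autoencoder embeddings: geometry-regularised AE, vanilla AE, VAE, PCA.

The geometry-regularised autoencoder minimises

    L = MSE(X, f⁻¹(f(X))) + λ · mean_i ‖ξ_i − f(x_i)‖²

where Ξ is the precomputed diffusion-geometry embedding. The geometric term
is averaged over cells so λ's scale does not depend on dataset size
(default λ = 0.1). Architecture for all nonlinear models: input d → hidden
⌈√d⌉ → latent ⌈∛d⌉ and the mirror decoder, LeakyReLU on hidden layers,
linear latent and output (inputs are log-scale reals). Training is
full-batch Adam with an 85/15 seeded (label-stratified when possible)
validation split, early stopping with patience on the validation loss, and
best-weight restoration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Tuple

import numpy as np

from ._autodiff import Adam, Tensor, no_grad
from .containers import CountMatrix, GeometryEmbedding

__all__ = [
    "EncoderSpec", "TrainConfig", "TrainedAutoencoder", "layer_sizes",
    "train_grae", "train_ae", "train_vae", "pca_embed", "reconstruct",
    "corrupt_dropout", "random_search_grae",
]


@dataclass
class EncoderSpec:
    input_dim: int
    hidden_dim: int
    latent_dim: int
    activation: str = "leaky_relu"

    def __post_init__(self):
        if self.input_dim < 1:
            raise ValueError("input_dim must be positive")
        if not (1 <= self.latent_dim and 1 <= self.hidden_dim):
            raise ValueError("layer sizes must be positive")


def layer_sizes(d: int) -> EncoderSpec:
    """Construction rule: hidden = ⌈√d⌉, latent = ⌈∛d⌉."""
    if d < 1:
        raise ValueError("d must be >= 1")
    hidden = math.isqrt(d)
    if hidden * hidden < d:
        hidden += 1
    latent = round(d ** (1.0 / 3.0))
    if latent ** 3 < d:
        latent += 1
    elif (latent - 1) ** 3 >= d:
        latent -= 1
    return EncoderSpec(input_dim=d, hidden_dim=hidden, latent_dim=latent)


@dataclass
class TrainConfig:
    lambda_geo: float = 0.1
    lr: float = 5e-3  # full-batch Adam: converges within the epoch budget
    weight_decay: float = 0.0
    max_epochs: int = 300
    patience: int = 30
    val_frac: float = 0.15
    seed: int = 0
    input_dropout: float = 0.0

    def __post_init__(self):
        if not 0 < self.val_frac < 1:
            raise ValueError("val_frac must be in (0, 1)")
        if self.patience > self.max_epochs:
            raise ValueError("patience must be <= max_epochs")
        if self.lambda_geo < 0:
            raise ValueError("lambda_geo must be non-negative")


@dataclass
class TrainedAutoencoder:
    spec: EncoderSpec
    kind: str  # GRAE | AE | VAE | PCA
    latent: np.ndarray
    history: List[dict]
    encode: Callable[[np.ndarray], np.ndarray]
    decode: Callable[[np.ndarray], np.ndarray]
    config: Optional[TrainConfig] = None

    def __post_init__(self):
        if not np.isfinite(self.latent).all():
            raise ValueError("latent matrix contains non-finite values")


# ---------------------------------------------------------------------------
# shared MLP machinery
# ---------------------------------------------------------------------------

def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    return rng.normal(0.0, scale, size=(fan_in, fan_out))


def _linear_params(rng, sizes) -> List[Tensor]:
    params = []
    for a, b in zip(sizes[:-1], sizes[1:]):
        params.append(Tensor(_glorot(rng, a, b), requires_grad=True))
        params.append(Tensor(np.zeros(b), requires_grad=True))
    return params


def _mlp(x: Tensor, params: List[Tensor], act_last: bool = False) -> Tensor:
    n_layers = len(params) // 2
    h = x
    for i in range(n_layers):
        h = h @ params[2 * i] + params[2 * i + 1]
        if i < n_layers - 1 or act_last:
            h = h.leaky_relu(0.2)
    return h


def _split_cells(n: int, val_frac: float, seed: int,
                 labels: Optional[np.ndarray]) -> Tuple[np.ndarray, np.ndarray]:
    """Seeded 85/15-style split, stratified by label when one is given."""
    rng = np.random.default_rng(seed)
    if labels is not None:
        val_idx = []
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            rng.shuffle(idx)
            n_val = max(1, int(round(val_frac * len(idx)))) if len(idx) > 1 else 0
            val_idx.append(idx[:n_val])
        val = np.sort(np.concatenate(val_idx)) if val_idx else np.array([], int)
    else:
        perm = rng.permutation(n)
        val = np.sort(perm[: max(1, int(round(val_frac * n)))])
    train = np.setdiff1d(np.arange(n), val)
    if len(train) == 0 or len(val) == 0:
        raise ValueError("validation split left a partition empty")
    return train, val


def _mse_value(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean((a - b) ** 2))


def _train_deterministic_ae(
    m: CountMatrix,
    cfg: TrainConfig,
    xi: Optional[GeometryEmbedding],
    variational: bool,
    kind: str,
) -> TrainedAutoencoder:
    X = np.asarray(m.counts, dtype=np.float64)
    n, d = X.shape
    spec = layer_sizes(d)
    if xi is not None:
        if xi.n_cells != n:
            raise ValueError("geometry embedding rows must match cells")
        if xi.p != spec.latent_dim:
            raise ValueError(
                f"geometry embedding dimension {xi.p} != latent {spec.latent_dim}"
            )
    lam = cfg.lambda_geo if xi is not None else 0.0
    xi_coords = None
    if xi is not None:
        # rescale the geometric target to [-1, 1] so the regulariser's
        # magnitude is comparable to the reconstruction MSE of log-scale data
        scale = np.abs(xi.coords).max()
        xi_coords = xi.coords / scale if scale > 0 else xi.coords

    rng = np.random.default_rng(cfg.seed)
    enc = _linear_params(rng, [d, spec.hidden_dim, spec.latent_dim])
    if variational:
        # second latent head for the log-variance
        enc_logvar = _linear_params(rng, [spec.hidden_dim, spec.latent_dim])
    dec = _linear_params(rng, [spec.latent_dim, spec.hidden_dim, d])
    params = enc + (enc_logvar if variational else []) + dec

    tr, va = _split_cells(n, cfg.val_frac, cfg.seed, m.labels)
    Xtr, Xva = X[tr], X[va]
    xi_tr = xi_coords[tr] if xi is not None else None
    xi_va = xi_coords[va] if xi is not None else None

    opt = Adam(params, lr=cfg.lr, weight_decay=cfg.weight_decay)

    def encode_hidden(x: Tensor) -> Tensor:
        return (x @ enc[0] + enc[1]).leaky_relu(0.2)

    def encode_t(x: Tensor) -> Tensor:
        return encode_hidden(x) @ enc[2] + enc[3]

    def decode_t(z: Tensor) -> Tensor:
        return _mlp(z, dec)

    def forward_losses(Xa: np.ndarray, xia, training: bool, epoch: int):
        """Returns (total, recon, geo, kl) loss tensors/values."""
        xin = Xa
        if training and cfg.input_dropout > 0:
            keep = rng.random(Xa.shape) >= cfg.input_dropout
            xin = Xa * keep / (1.0 - cfg.input_dropout)
        x = Tensor(xin)
        target = Tensor(Xa)
        if variational:
            h = encode_hidden(x)
            mu = h @ enc[2] + enc[3]
            logvar = _mlp(h, enc_logvar)
            if training:
                eps = Tensor(rng.standard_normal(mu.shape))
                z = mu + (logvar * 0.5).exp() * eps
            else:
                z = mu
            kl = ((mu * mu + logvar.exp() - logvar - 1.0) * 0.5).sum(axis=1).mean()
            beta = min(1.0, epoch / max(1.0, cfg.max_epochs / 2.0))
        else:
            z = encode_t(x)
            kl, beta = None, 0.0
        xhat = decode_t(z)
        diff = xhat - target
        recon = (diff * diff).mean()
        total = recon
        geo = None
        if xi is not None:
            gd = z - Tensor(xia)
            geo = (gd * gd).sum(axis=1).mean()
            total = total + lam * geo
        if variational:
            total = total + beta * kl
        return total, recon, geo, kl, beta

    history: List[dict] = []
    best_val = np.inf
    best_state = [p.data.copy() for p in params]
    since_best = 0
    for epoch in range(cfg.max_epochs):
        total, recon, geo, kl, beta = forward_losses(Xtr, xi_tr, True, epoch)
        if not np.isfinite(total.data):
            raise ValueError(f"non-finite training loss at epoch {epoch}")
        opt.zero_grad()
        total.backward()
        opt.step()

        with no_grad():
            v_total, v_recon, v_geo, v_kl, _ = forward_losses(Xva, xi_va,
                                                              False, epoch)
        rec = {
            "epoch": epoch,
            "train_total": float(total.data),
            "train_recon": float(recon.data),
            "train_geo": float(geo.data) if geo is not None else 0.0,
            "val_total": float(v_total.data),
            "val_recon": float(v_recon.data),
            "val_geo": float(v_geo.data) if v_geo is not None else 0.0,
            "lambda_geo": lam,
        }
        if variational:
            rec["train_kl"] = float(kl.data)
            rec["beta"] = beta
        history.append(rec)

        if rec["val_total"] < best_val - 1e-12:
            best_val = rec["val_total"]
            best_state = [p.data.copy() for p in params]
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break

    for p, s in zip(params, best_state):
        p.data = s

    def encode_fn(Xa: np.ndarray) -> np.ndarray:
        Xa = np.atleast_2d(np.asarray(Xa, dtype=np.float64))
        with no_grad():
            if variational:
                h = encode_hidden(Tensor(Xa))
                return (h @ enc[2] + enc[3]).data
            return encode_t(Tensor(Xa)).data

    def decode_fn(Z: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(Z, dtype=np.float64))
        with no_grad():
            return decode_t(Tensor(Z)).data

    return TrainedAutoencoder(
        spec=spec, kind=kind, latent=encode_fn(X), history=history,
        encode=encode_fn, decode=decode_fn, config=cfg,
    )


# ---------------------------------------------------------------------------
# public trainers
# ---------------------------------------------------------------------------

def train_grae(m: CountMatrix, xi: GeometryEmbedding,
               cfg: TrainConfig | None = None) -> TrainedAutoencoder:
    """Geometry-regularised autoencoder (reconstruction + λ·geometry)."""
    cfg = cfg or TrainConfig()
    return _train_deterministic_ae(m, cfg, xi, variational=False, kind="GRAE")


def train_ae(m: CountMatrix, cfg: TrainConfig | None = None) -> TrainedAutoencoder:
    """Vanilla autoencoder: reconstruction MSE only."""
    cfg = cfg or TrainConfig()
    return _train_deterministic_ae(m, cfg, None, variational=False, kind="AE")


def train_vae(m: CountMatrix, cfg: TrainConfig | None = None) -> TrainedAutoencoder:
    """Variational autoencoder with the KL weight linearly annealed 0→1 over
    the first half of ``max_epochs``."""
    cfg = cfg or TrainConfig()
    return _train_deterministic_ae(m, cfg, None, variational=True, kind="VAE")


def pca_embed(m: CountMatrix, latent_dim: int | None = None) -> TrainedAutoencoder:
    """Linear PCA baseline; decode is the inverse transform."""
    from sklearn.decomposition import PCA

    X = np.asarray(m.counts, dtype=np.float64)
    n, d = X.shape
    spec = layer_sizes(d)
    latent_dim = latent_dim or spec.latent_dim
    if latent_dim >= min(n, d):
        raise ValueError("latent_dim must be < min(n_cells, n_features) for PCA")
    pca = PCA(n_components=latent_dim, svd_solver="full", random_state=0)
    Z = pca.fit_transform(X)
    return TrainedAutoencoder(
        spec=EncoderSpec(d, spec.hidden_dim, latent_dim, activation="linear"),
        kind="PCA",
        latent=Z,
        history=[],
        encode=lambda Xa: pca.transform(np.atleast_2d(Xa)),
        decode=lambda Za: pca.inverse_transform(np.atleast_2d(Za)),
    )


def reconstruct(model: TrainedAutoencoder, m: CountMatrix) -> np.ndarray:
    """X̂ = f⁻¹(f(X))."""
    if m.n_features != model.spec.input_dim:
        raise ValueError(
            f"matrix has {m.n_features} features, model expects "
            f"{model.spec.input_dim}"
        )
    xhat = model.decode(model.encode(m.counts))
    if not np.isfinite(xhat).all():
        raise ValueError("reconstruction produced non-finite values")
    return xhat


def corrupt_dropout(m: CountMatrix, fraction: float, seed: int = 0):
    """Zero out ⌈fraction·F⌉ uniformly sampled feature columns.

    Returns (corrupted copy, sorted dropped column indices).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    out = m.copy()
    n_drop = int(np.ceil(fraction * m.n_features))
    if n_drop == 0:
        return out, np.array([], dtype=int)
    rng = np.random.default_rng(seed)
    dropped = np.sort(rng.choice(m.n_features, size=n_drop, replace=False))
    out.counts[:, dropped] = 0.0
    return out, dropped


def random_search_grae(
    m: CountMatrix,
    xi: GeometryEmbedding,
    n_trials: int = 25,
    seed: int = 0,
    max_epochs: int = 100,
) -> Tuple[TrainConfig, List[dict]]:
    """Simple seeded random search over lr, weight decay and λ.

    Returns the best configuration by final validation loss and the trial
    log. Defaults elsewhere are fixed, so this is opt-in tuning only.
    """
    rng = np.random.default_rng(seed)
    trials = []
    best_cfg, best_val = None, np.inf
    for i in range(n_trials):
        cfg = TrainConfig(
            lr=float(10 ** rng.uniform(-4, -2)),
            weight_decay=float(rng.uniform(0.0, 1e-3)),
            lambda_geo=float(10 ** rng.uniform(-2, 1)),
            max_epochs=max_epochs,
            patience=min(30, max_epochs),
            seed=seed + i,
        )
        model = train_grae(m, xi, cfg)
        val = model.history[-1]["val_total"]
        trials.append({"trial": i, "lr": cfg.lr, "weight_decay": cfg.weight_decay,
                       "lambda_geo": cfg.lambda_geo, "val_total": val})
        if val < best_val:
            best_val, best_cfg = val, cfg
    return best_cfg, trials
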