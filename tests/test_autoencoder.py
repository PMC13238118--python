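import numpy as np
import pytest

import scgale as sg
from scgale.autoencoder import (TrainConfig, corrupt_dropout, layer_sizes,
                                pca_embed, reconstruct, train_ae, train_grae,
                                train_vae)
from scgale.containers import CountMatrix, GeometryEmbedding


def _matrix(counts, labels=None):
    counts = np.asarray(counts, dtype=float)
    n, f = counts.shape
    m = CountMatrix(
        counts=counts,
        cell_ids=[f"c{i}" for i in range(n)],
        feature_ids=[f"g{j}" for j in range(f)],
        labels=labels,
    )
    m.is_normalised = m.is_log = True
    return m


class TestLayerSizes:
    @pytest.mark.parametrize("d,hidden,latent", [
        (1000, 32, 10),
        (10000, 100, 22),
        (27, 6, 3),
        (5, 3, 2),
    ])
    def test_construction_rule(self, d, hidden, latent):
        spec = layer_sizes(d)
        assert spec.hidden_dim == hidden
        assert spec.latent_dim == latent

    def test_ordering_for_d_at_least_5(self):
        for d in (5, 10, 100, 5000):
            spec = layer_sizes(d)
            assert spec.latent_dim < spec.hidden_dim < d


class TestCorruption:
    def test_zero_fraction_is_identity(self, processed):
        out, dropped = corrupt_dropout(processed, 0.0, seed=0)
        assert np.array_equal(out.counts, processed.counts)
        assert len(dropped) == 0

    def test_exact_column_count_zeroed(self):
        rng = np.random.default_rng(0)
        m = _matrix(rng.random((20, 100)) + 0.1)
        out, dropped = corrupt_dropout(m, 0.3, seed=1)
        assert len(dropped) == 30
        assert (out.counts[:, dropped] == 0).all()
        kept = np.setdiff1d(np.arange(100), dropped)
        assert np.array_equal(out.counts[:, kept], m.counts[:, kept])

    def test_mse_equals_dropped_column_energy(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.random((15, 40)))
        out, dropped = corrupt_dropout(m, 0.25, seed=3)
        expected = (m.counts[:, dropped] ** 2).sum() / m.counts.size
        assert np.isclose(sg.mse(m.counts, out.counts), expected)


class TestBaselines:
    def test_pca_exact_on_low_rank_data(self):
        rng = np.random.default_rng(1)
        basis = rng.standard_normal((3, 30))
        scores = rng.standard_normal((40, 3))
        m = _matrix(scores @ basis + 20.0)  # shift keeps counts non-negative
        model = pca_embed(m, latent_dim=3)
        xhat = reconstruct(model, m)
        assert sg.mse(m.counts, xhat) < 1e-8

    def test_pca_latent_dim_guard(self):
        m = _matrix(np.random.default_rng(0).random((10, 6)))
        with pytest.raises(ValueError):
            pca_embed(m, latent_dim=6)

    def test_vae_first_epoch_beta_zero(self):
        rng = np.random.default_rng(2)
        m = _matrix(rng.random((60, 30)))
        model = train_vae(m, TrainConfig(max_epochs=5, patience=5, seed=0))
        assert model.history[0]["beta"] == 0.0
        # first-epoch objective is the pure reconstruction form
        assert np.isclose(model.history[0]["train_total"],
                          model.history[0]["train_recon"], atol=1e-9)

    def test_ae_on_constant_matrix_reaches_zero_mse(self):
        m = _matrix(np.full((50, 20), 2.5))
        model = train_ae(m, TrainConfig(max_epochs=300, patience=300, seed=0))
        assert sg.mse(m.counts, reconstruct(model, m)) < 1e-3


class TestGRAE:
    def _setup(self, n=80, f=60, seed=0):
        rng = np.random.default_rng(seed)
        half = n // 2
        counts = np.vstack([rng.random((half, f)),
                            rng.random((n - half, f)) + 3.0])
        m = _matrix(counts)
        spec = layer_sizes(f)
        xi = GeometryEmbedding(
            coords=rng.standard_normal((n, spec.latent_dim)))
        return m, xi

    def test_loss_decomposition_every_epoch(self):
        m, xi = self._setup()
        model = train_grae(m, xi, TrainConfig(max_epochs=40, patience=40, seed=1))
        for rec in model.history:
            assert np.isclose(
                rec["train_total"],
                rec["train_recon"] + rec["lambda_geo"] * rec["train_geo"],
                atol=1e-6,
            )

    def test_lambda_zero_equals_vanilla_ae(self):
        m, xi = self._setup(seed=3)
        cfg = TrainConfig(max_epochs=30, patience=30, seed=5, lambda_geo=0.0)
        grae = train_grae(m, xi, cfg)
        ae = train_ae(m, cfg)
        for r1, r2 in zip(grae.history, ae.history):
            assert abs(r1["train_total"] - r2["train_total"]) < 1e-6
            assert abs(r1["val_total"] - r2["val_total"]) < 1e-6

    def test_large_lambda_shrinks_geometric_term(self):
        m, xi = self._setup(seed=4)
        cfg = TrainConfig(max_epochs=200, patience=200, seed=2, lambda_geo=1e6)
        model = train_grae(m, xi, cfg)
        assert model.history[-1]["train_geo"] * 10 <= model.history[0]["train_geo"]

    def test_epoch_cap_and_row_mismatch(self):
        m, xi = self._setup()
        model = train_grae(m, xi, TrainConfig(max_epochs=10, patience=5, seed=0))
        assert len(model.history) <= 10
        bad = GeometryEmbedding(coords=xi.coords[:-1])
        with pytest.raises(ValueError):
            train_grae(m, bad, TrainConfig(seed=0))

    def test_seed_determinism_of_history(self):
        m, xi = self._setup(seed=6)
        cfg = TrainConfig(max_epochs=20, patience=20, seed=9)
        h1 = train_grae(m, xi, cfg).history
        h2 = train_grae(m, xi, cfg).history
        assert h1 == h2

    def test_trained_model_beats_zero_predictor(self, processed, trained_setup):
        xhat = reconstruct(trained_setup["grae"], processed)
        assert sg.mse(processed.counts, xhat) < sg.mse(
            processed.counts, np.zeros_like(processed.counts))

    def test_reconstruct_shape_and_dim_guard(self, processed, trained_setup):
        xhat = reconstruct(trained_setup["grae"], processed)
        assert xhat.shape == processed.counts.shape
        small = _matrix(np.ones((5, 3)))
        with pytest.raises(ValueError):
            reconstruct(trained_setup["grae"], small)
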