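"""VAE: architecture shapes, ELBO closed forms, gradients, training behavior."""

from __future__ import annotations

import numpy as np
import pytest

import thermovae as tv
from thermovae import vae
from thermovae.preprocess import Patch, PatchSet
from thermovae.vae import (
    VaeConfig,
    VaeNetwork,
    _BlockConv,
    _BlockConvT,
    _SameConv4,
)


def _patchset(n, seed=0, mean=0.5, sigma=0.1):
    rng = np.random.default_rng(seed)
    X = np.clip(rng.normal(mean, sigma, (n, 8, 8)), 0.0, 1.0)
    return PatchSet([Patch(x, f"f{i}", 0, 0) for i, x in enumerate(X)], role="learning")


class TestArchitecture:
    def test_encoder_spatial_chain(self):
        """Stride-2 2x2 convolutions: 8x8 -> 4x4 -> 2x2, no padding."""
        rng = np.random.default_rng(0)
        c1, c2 = _BlockConv(1, 16, rng), _BlockConv(16, 32, rng)
        x = rng.random((3, 1, 8, 8))
        h1 = c1.forward(x, False)
        h2 = c2.forward(h1, False)
        assert h1.shape == (3, 16, 4, 4)
        assert h2.shape == (3, 32, 2, 2)

    def test_decoder_spatial_chain(self):
        """Transposed stride-2 then stride-1 same heads: 2 -> 4 -> 8 -> 8."""
        rng = np.random.default_rng(0)
        t1, t2 = _BlockConvT(32, 32, rng), _BlockConvT(32, 16, rng)
        head = _SameConv4(16, 1, rng)
        z = rng.random((3, 32, 2, 2))
        h1 = t1.forward(z, False)
        h2 = t2.forward(h1, False)
        y = head.forward(h2, False)
        assert h1.shape == (3, 32, 4, 4)
        assert h2.shape == (3, 16, 8, 8)
        assert y.shape == (3, 1, 8, 8)

    def test_latent_dimensions(self, trained_model):
        enc = tv.encode(np.full((8, 8), 0.5), trained_model)
        assert enc.mu_z.shape == (6,)
        assert enc.logvar_z.shape == (6,)

    def test_decoder_emits_paired_maps(self, trained_model):
        dec = tv.decode(np.zeros(6), trained_model)
        assert dec.mu_x.shape == (8, 8)
        assert dec.logvar_x.shape == (8, 8)
        floor = np.log(trained_model.config.variance_floor)
        assert (dec.logvar_x >= floor - 1e-6).all()

    def test_inference_deterministic(self, trained_model):
        x = np.random.default_rng(1).random((8, 8))
        a = tv.encode(x, trained_model)
        b = tv.encode(x, trained_model)
        assert np.array_equal(a.mu_z, b.mu_z)
        assert np.array_equal(a.logvar_z, b.logvar_z)

    def test_shape_mismatch_rejected(self, trained_model):
        with pytest.raises(ValueError, match="invalid-input"):
            tv.encode(np.zeros((7, 8)), trained_model)
        with pytest.raises(ValueError, match="invalid-input"):
            tv.decode(np.zeros(5), trained_model)


class TestReparameterize:
    def test_zero_variance_limit(self):
        enc = vae.EncoderOutput(mu_z=np.arange(6.0), logvar_z=np.full(6, -80.0))
        z = tv.reparameterize(enc, np.random.default_rng(0))
        assert np.allclose(z, np.arange(6.0), atol=1e-12)

    def test_standard_normal_moments(self):
        """With mu = 0, logvar = 0 the samples are standard normal."""
        enc = vae.EncoderOutput(mu_z=np.zeros(6), logvar_z=np.zeros(6))
        rng = np.random.default_rng(12)
        n = 100_000
        zs = np.stack([tv.reparameterize(enc, rng) for _ in range(n // 100)])
        # 1000 draws x 6 coords: mean within 4 / sqrt(n_eff) per coordinate
        n_eff = zs.shape[0]
        assert np.all(np.abs(zs.mean(axis=0)) < 4.0 / np.sqrt(n_eff))
        assert np.all(np.abs(zs.std(axis=0) - 1.0) < 0.15)

    def test_reproducible_under_seed(self):
        enc = vae.EncoderOutput(mu_z=np.zeros(6), logvar_z=np.zeros(6))
        a = tv.reparameterize(enc, np.random.default_rng(5))
        b = tv.reparameterize(enc, np.random.default_rng(5))
        assert np.array_equal(a, b)


class TestElbo:
    def test_perfect_reconstruction_prior_posterior_zero(self):
        x = np.random.default_rng(0).random((8, 8))
        enc = vae.EncoderOutput(mu_z=np.zeros(6), logvar_z=np.zeros(6))
        dec = vae.DecoderOutput(mu_x=x.copy(), logvar_x=np.zeros((8, 8)))
        assert tv.elbo_loss(x, enc, dec) == pytest.approx(0.0, abs=1e-12)

    def test_kl_closed_form_single_coordinate(self):
        x = np.zeros((8, 8))
        enc = vae.EncoderOutput(
            mu_z=np.array([1.0, 0, 0, 0, 0, 0]), logvar_z=np.zeros(6)
        )
        dec = vae.DecoderOutput(mu_x=x.copy(), logvar_x=np.zeros((8, 8)))
        assert tv.elbo_loss(x, enc, dec) == pytest.approx(0.5, abs=1e-12)

    def test_residual_doubling_quadruples_reconstruction(self):
        x = np.zeros((8, 8))
        enc = vae.EncoderOutput(mu_z=np.zeros(6), logvar_z=np.zeros(6))
        d1 = vae.DecoderOutput(mu_x=np.full((8, 8), 0.1), logvar_x=np.zeros((8, 8)))
        d2 = vae.DecoderOutput(mu_x=np.full((8, 8), 0.2), logvar_x=np.zeros((8, 8)))
        assert tv.elbo_loss(x, enc, d2) == pytest.approx(4 * tv.elbo_loss(x, enc, d1))

    def test_kl_nonnegative_randomized(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            mu = rng.normal(size=6)
            lv = rng.normal(size=6)
            kl = 0.5 * np.sum(mu**2 + np.exp(lv) - lv - 1.0)
            assert kl >= 0.0


def _network_loss(net, x, eps):
    """Float64 reference of the training objective for a fixed noise draw."""
    mu_z, logvar_z = net.encode_batch(x, train=True)
    z = mu_z + np.exp(0.5 * logvar_z) * eps
    mu_x, logvar_x = net.decode_batch(z, train=True)
    var_x = np.exp(logvar_x)
    recon = np.sum((mu_x - x) ** 2 / (2 * var_x) + 0.5 * logvar_x)
    kl = 0.5 * np.sum(mu_z**2 + np.exp(logvar_z) - logvar_z - 1.0)
    return (recon + kl) / x.shape[0]


def test_backprop_matches_finite_differences():
    """Analytic gradients of the full network agree with central differences."""
    cfg = VaeConfig(seed=0)
    rng = np.random.default_rng(0)
    net = VaeNetwork(cfg, rng)
    for m in net._modules():
        m.params = {k: v.astype(np.float64) for k, v in m.params.items()}
        m.grads = {k: np.zeros_like(v) for k, v in m.params.items()}
    x = rng.random((4, 1, 8, 8))
    eps = rng.standard_normal((4, cfg.latent_dim))

    # analytic pass
    mu_z, logvar_z = net.encode_batch(x, train=True)
    sigma_z = np.exp(0.5 * logvar_z)
    z = mu_z + sigma_z * eps
    mu_x, logvar_x = net.decode_batch(z, train=True)
    var_x = np.exp(logvar_x)
    n = x.shape[0]
    dmu_x = (mu_x - x) / var_x / n
    dlogvar_x = (0.5 - (mu_x - x) ** 2 / (2 * var_x)) / n
    dz = net.backward_decoder(dmu_x, dlogvar_x)
    dmu_z = mu_z / n + dz
    dlogvar_z = 0.5 * (np.exp(logvar_z) - 1.0) / n + dz * eps * 0.5 * sigma_z
    net.backward_encoder(dmu_z, dlogvar_z)

    check_rng = np.random.default_rng(99)
    mods = net._modules()
    h = 1e-6
    for mi in check_rng.choice(len(mods), size=6, replace=False):
        m = mods[mi]
        if not m.params:
            continue
        for name, p in m.params.items():
            idx = tuple(check_rng.integers(0, s) for s in p.shape)
            orig = p[idx]
            p[idx] = orig + h
            lp = _network_loss(net, x, eps)
            p[idx] = orig - h
            lm = _network_loss(net, x, eps)
            p[idx] = orig
            fd = (lp - lm) / (2 * h)
            assert m.grads[name][idx] == pytest.approx(fd, rel=5e-4, abs=1e-7), (
                f"module {mi} param {name} index {idx}"
            )


class TestTraining:
    def test_loss_history_length_and_trend(self, trained_model):
        hist = trained_model.training_loss_history
        assert len(hist) == trained_model.config.epochs == 15
        assert all(np.isfinite(hist))
        assert hist[-1] <= hist[0]

    def test_deterministic_under_seed(self):
        ps = _patchset(256, seed=1)
        cfg = VaeConfig(seed=3, epochs=2, n_candidates=1)
        h1 = tv.train_vae(ps, cfg).training_loss_history
        h2 = tv.train_vae(ps, cfg).training_loss_history
        assert h1 == h2

    def test_requires_full_batch(self):
        with pytest.raises(ValueError, match="invalid-input"):
            tv.train_vae(_patchset(64), VaeConfig())

    def test_requires_learning_role(self):
        ps = _patchset(256)
        ps.role = "scoring"
        with pytest.raises(ValueError, match="invalid-input"):
            tv.train_vae(ps, VaeConfig(epochs=1, n_candidates=1))

    def test_decoder_variance_tracks_texture_variance(self):
        """On i.i.d. uniform texture the learned sigma^2_x approaches the
        texture variance 1/12 (within a factor of two), given enough
        optimizer steps to descend the log-variance that far."""
        rng = np.random.default_rng(2)
        X = rng.random((2000, 8, 8))
        ps = PatchSet([Patch(x, f"f{i}", 0, 0) for i, x in enumerate(X)], role="learning")
        model = tv.train_vae(
            ps, VaeConfig(seed=1, n_candidates=1, epochs=30, learning_rate=5e-3)
        )
        mu_z, _ = model.network.encode_batch(X[:200, None])
        _, logvar_x = model.network.decode_batch(mu_z)
        med = float(np.median(np.exp(logvar_x)))
        target = 1.0 / 12.0
        assert target / 2 < med < target * 2

    def test_constant_texture_reconstructs_mean(self):
        """After training on near-constant patches the reconstruction mean
        approaches the patch mean (Gaussian-likelihood optimum), up to
        desk-scale optimization error."""
        ps = _patchset(2000, seed=4, mean=0.5, sigma=0.02)
        model = tv.train_vae(
            ps, VaeConfig(seed=2, n_candidates=1, epochs=30, learning_rate=3e-3)
        )
        enc = tv.encode(np.full((8, 8), 0.5), model)
        dec = tv.decode(enc.mu_z, model)
        assert np.abs(dec.mu_x - 0.5).mean() < 0.06
        assert np.abs(dec.mu_x - 0.5).max() < 0.15


def test_save_load_roundtrip(tmp_path, trained_model):
    vae.save_model(trained_model, tmp_path / "m")
    back = vae.load_model(tmp_path / "m")
    x = np.random.default_rng(0).random((8, 8))
    a, b = tv.encode(x, trained_model), tv.encode(x, back)
    assert np.allclose(a.mu_z, b.mu_z, atol=1e-7)
    da = tv.decode(a.mu_z, trained_model)
    db = tv.decode(b.mu_z, back)
    assert np.allclose(da.mu_x, db.mu_x, atol=1e-6)
    assert back.training_loss_history == trained_model.training_loss_history
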