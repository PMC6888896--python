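import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vflatent import (VAEConfig, decode, encode, load_checkpoint, loss, mmd,
                      save_checkpoint, sweep_latent_dims, train)
from vflatent.vae import _Autoencoder, _mmd_grad_x


def brute_force_mmd(x, y, sigma):
    """Explicit double-sum V-statistic (independent of the implementation)."""
    x, y = np.atleast_2d(x), np.atleast_2d(y)
    k = lambda a, b: np.exp(-np.sum((a - b) ** 2) / (2 * sigma ** 2))
    sxx = sum(k(a, b) for a in x for b in x) / (len(x) ** 2)
    syy = sum(k(a, b) for a in y for b in y) / (len(y) ** 2)
    sxy = sum(k(a, b) for a in x for b in y) / (len(x) * len(y))
    return sxx + syy - 2 * sxy


class TestMMD:
    def test_matches_brute_force_double_sum_on_3_point_samples(self):
        x = np.array([[0.0], [1.0], [2.5]])
        y = np.array([[-1.0], [0.5], [2.0]])
        for sigma in (0.7, 1.0, 3.0):
            assert mmd(x, y, sigma) == pytest.approx(
                brute_force_mmd(x, y, sigma), abs=1e-12)

    def test_zero_for_identical_samples(self):
        x = np.random.default_rng(0).normal(size=(6, 3))
        assert mmd(x, x, 1.0) == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=25)
    @given(st.integers(0, 10_000))
    def test_symmetric_and_nonnegative(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(4, 2))
        y = rng.normal(size=(5, 2)) + rng.uniform(-1, 1)
        m = mmd(x, y, 1.3)
        assert m >= -1e-12
        assert m == pytest.approx(mmd(y, x, 1.3), abs=1e-12)

    def test_rejects_empty_or_mismatched(self):
        with pytest.raises(ValueError):
            mmd(np.empty((0, 2)), np.ones((3, 2)), 1.0)
        with pytest.raises(ValueError):
            mmd(np.ones((3, 2)), np.ones((3, 3)), 1.0)

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=(5, 3)), rng.normal(size=(6, 3))
        g = _mmd_grad_x(x, y, 1.1)
        eps = 1e-6
        for i, j in [(0, 0), (2, 1), (4, 2)]:
            x[i, j] += eps
            up = mmd(x, y, 1.1)
            x[i, j] -= 2 * eps
            dn = mmd(x, y, 1.1)
            x[i, j] += eps
            assert g[i, j] == pytest.approx((up - dn) / (2 * eps), rel=1e-5, abs=1e-9)


class TestShapes:
    def test_network_shape_contract_12_6_3_L(self):
        """12x12 -> 6x6 -> 3x3 -> L -> 3x3 -> 6x6 -> 12x12 under 3x3/stride-2."""
        rng = np.random.default_rng(0)
        cfg = VAEConfig(latent_dim=5, encoder_channels=(4, 6))
        net = _Autoencoder(cfg, rng)
        x = rng.uniform(0, 1, (3, 12, 12))
        h1 = net.enc_a1.forward(net.enc_c1.forward(x[:, :, :, None]))
        assert h1.shape == (3, 6, 6, 4)
        h2 = net.enc_a2.forward(net.enc_c2.forward(h1))
        assert h2.shape == (3, 3, 3, 6)
        z = net.enc_f1.forward(h2.reshape(3, -1))
        assert z.shape == (3, 5)
        xhat = net.decode(z)
        assert xhat.shape == (3, 12, 12)

    def test_encode_shape_and_batch_consistency(self, tiny_model, small_images):
        z = encode(tiny_model, small_images[:7])
        assert z.shape == (7, 2)
        singles = np.vstack([encode(tiny_model, small_images[i])
                             for i in range(7)])
        np.testing.assert_allclose(z, singles, atol=1e-12)

    def test_encode_deterministic_on_identical_inputs(self, tiny_model, small_images):
        batch = np.repeat(small_images[:1], 4, axis=0)
        z = encode(tiny_model, batch)
        assert np.ptp(z, axis=0).max() == 0.0

    def test_decode_outputs_strictly_inside_unit_interval(self, tiny_model):
        z = np.random.default_rng(3).normal(size=(10, 2)) * 3
        out = decode(tiny_model, z)
        assert np.all(out > 0.0) and np.all(out < 1.0)

    def test_decode_rejects_wrong_latent_width(self, tiny_model):
        with pytest.raises(ValueError):
            decode(tiny_model, np.zeros((2, 5)))

    def test_encode_rejects_wrong_image_shape(self, tiny_model):
        with pytest.raises(ValueError):
            encode(tiny_model, np.zeros((3, 10, 10)))


class TestLoss:
    def test_components_sum_to_total(self, tiny_model, small_images):
        rng = np.random.default_rng(0)
        prior = rng.standard_normal((20, 2))
        total, recon, reg = loss(tiny_model, small_images[:20], prior_sample=prior)
        assert total == pytest.approx(recon + reg, abs=1e-6)
        # recompute both components independently
        z = encode(tiny_model, small_images[:20])
        xhat = decode(tiny_model, z)
        recon2 = np.mean((xhat - small_images[:20]) ** 2)
        reg2 = tiny_model.config.mmd_weight * brute_force_mmd(
            z, prior, tiny_model.config.sigma)
        assert recon == pytest.approx(recon2, abs=1e-9)
        assert reg == pytest.approx(reg2, abs=1e-6)

    def test_zero_mmd_weight_reduces_to_reconstruction(self, small_images):
        cfg = VAEConfig(latent_dim=2, encoder_channels=(4, 6), epochs=1,
                        batch_size=50, mmd_weight=0.0, seed=0)
        model = train(small_images[:100], small_images[100:120], cfg)
        total, recon, reg = loss(model, small_images[:20])
        assert reg == 0.0 and total == recon


class TestTraining:
    def test_selected_epoch_is_argmin_of_validation_loss(self, tiny_model):
        h = tiny_model.loss_history
        assert tiny_model.selected_epoch == int(h.loc[h.val_total.idxmin(), "epoch"])

    def test_defaults_follow_training_protocol(self):
        cfg = VAEConfig()
        assert cfg.epochs == 100 and cfg.batch_size == 100 and cfg.lr == 1e-4

    def test_training_reduces_loss_and_is_seed_deterministic(self, small_images):
        cfg = VAEConfig(latent_dim=2, encoder_channels=(6, 8), epochs=6,
                        batch_size=50, seed=7)
        m1 = train(small_images[:250], small_images[250:288], cfg)
        h = m1.loss_history
        assert h.val_reconstruction.iloc[-1] < h.val_reconstruction.iloc[0]
        m2 = train(small_images[:250], small_images[250:288], cfg)
        np.testing.assert_allclose(h.to_numpy(), m2.loss_history.to_numpy())

    def test_overfit_single_image_reconstructs_it(self, small_images):
        x = small_images[0]
        rep = np.repeat(x[None], 32, axis=0)
        cfg = VAEConfig(latent_dim=2, encoder_channels=(8, 12), epochs=150,
                        batch_size=32, lr=3e-3, mmd_weight=0.0, seed=0)
        model = train(rep, rep[:8], cfg)
        xhat = decode(model, encode(model, x[None]))[0]
        assert np.abs(xhat - x).mean() < 0.02

    def test_regularization_pulls_latents_toward_prior(self, small_images):
        """MMD to the prior shrinks relative to an untrained encoder."""
        cfg = VAEConfig(latent_dim=2, encoder_channels=(8, 12), epochs=25,
                        batch_size=50, seed=1)
        rng = np.random.default_rng(0)
        net0 = _Autoencoder(cfg, np.random.default_rng(cfg.seed))
        z0 = net0.encode(small_images[:200])
        model = train(small_images[:250], small_images[250:288], cfg)
        z1 = encode(model, small_images[:200])
        prior = rng.standard_normal((200, 2))
        assert mmd(z1, prior, cfg.sigma) < mmd(z0, prior, cfg.sigma)


def test_sweep_trains_one_model_per_dimension(small_images):
    cfg = VAEConfig(encoder_channels=(4, 6), epochs=2, batch_size=50, seed=0)
    models = sweep_latent_dims(small_images[:150], small_images[150:180],
                               dims=(1, 3), config=cfg)
    assert set(models) == {1, 3}
    for L, m in models.items():
        assert encode(m, small_images[:4]).shape == (4, L)


def test_capacity_grows_with_latent_dimension(small_images):
    """More latent features reconstruct at least as well as one (after training)."""
    cfg = VAEConfig(encoder_channels=(8, 12), epochs=25, batch_size=50,
                    mmd_weight=0.0, seed=2)
    models = sweep_latent_dims(small_images[:250], small_images[250:288],
                               dims=(1, 8), config=cfg)
    recon = {L: m.loss_history.val_reconstruction.iloc[-1]
             for L, m in models.items()}
    assert recon[8] <= recon[1] * 1.05


def test_checkpoint_roundtrip(tmp_path, tiny_model, small_images):
    p = tmp_path / "model.npz"
    save_checkpoint(tiny_model, p)
    back = load_checkpoint(p)
    np.testing.assert_allclose(encode(back, small_images[:5]),
                               encode(tiny_model, small_images[:5]), atol=1e-12)
    assert back.config == tiny_model.config
    assert back.selected_epoch == tiny_model.selected_epoch
    np.testing.assert_allclose(back.loss_history.to_numpy(),
                               tiny_model.loss_history.to_numpy())


def test_gradients_match_finite_differences():
    """Backprop through every layer agrees with central differences."""
    rng = np.random.default_rng(0)
    cfg = VAEConfig(latent_dim=2, encoder_channels=(3, 4), mmd_weight=0.0, seed=0)
    net = _Autoencoder(cfg, rng)
    x = rng.uniform(0, 1, (4, 12, 12))

    def objective():
        return float(np.mean((net.decode(net.encode(x)) - x) ** 2))

    xhat = net.decode(net.encode(x))
    resid = xhat - x
    net.encode_backward(net.decode_backward(2 * resid / resid.size))
    eps = 1e-6
    for layer in net.layers():
        idx = tuple(np.random.default_rng(1).integers(0, s) for s in layer.W.shape)
        g = layer.dW[idx]
        layer.W[idx] += eps
        up = objective()
        layer.W[idx] -= 2 * eps
        dn = objective()
        layer.W[idx] += eps
        assert g == pytest.approx((up - dn) / (2 * eps), rel=1e-4, abs=1e-10)
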