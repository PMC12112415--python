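"""Progressive frame GAN: shape contracts, fade-in algebra, WGAN-GP closed forms."""

import numpy as np
import pytest

from trajgan import (
    ConfigError,
    FrameGANConfig,
    InputError,
    build_frame_critic,
    build_frame_generator,
    extract_features,
    wgan_gp_losses,
)
from trajgan.autodiff import Tensor
from trajgan.frame_gan import gradient_penalty, train_frame_gan
from trajgan.synthetic_video import FrameDataset, SceneSpec, generate_tunnel


def _toy_config(**kwargs):
    defaults = dict(
        latent_dim=64,
        max_resolution=32,
        channels_schedule={4: 12, 8: 8, 16: 6, 32: 6},
        batch_schedule={4: 4, 8: 4, 16: 4, 32: 4},
        feature_dim=48,
        steps_per_phase=2,
    )
    defaults.update(kwargs)
    return FrameGANConfig(**defaults)


class TestConfig:
    def test_default_batch_schedule_follows_resolution_rule(self):
        cfg = FrameGANConfig(max_resolution=512, channels_schedule={r: 8 for r in (4, 8, 16, 32, 64, 128, 256, 512)})
        assert cfg.batch_schedule[256] == 8
        assert cfg.batch_schedule[512] == 4

    @pytest.mark.parametrize("bad", [
        {"max_resolution": 48},
        {"gp_lambda": -1.0},
        {"fade_fraction": 0.0},
        {"batch_schedule": {4: 0, 8: 4, 16: 4, 32: 4}},
    ])
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigError):
            _toy_config(**bad)


class TestBuilders:
    def test_generator_shape_contract_at_every_phase(self):
        cfg = _toy_config()
        gen = build_frame_generator(cfg, seed=0)
        z = np.random.default_rng(0).standard_normal((3, 64)).astype(np.float32)
        for res in cfg.resolutions:
            gen.set_phase(res, 1.0)
            out = gen(Tensor(z))
            assert out.shape == (3, 3, res, res)
            assert np.abs(out.data).max() <= 1.0

    def test_critic_maps_batch_to_scalars(self):
        cfg = _toy_config()
        critic = build_frame_critic(cfg, seed=0)
        critic.set_phase(16, 1.0)
        x = np.random.default_rng(1).uniform(-1, 1, size=(5, 3, 16, 16)).astype(np.float32)
        assert critic(Tensor(x)).shape == (5, 1)

    def test_fade_in_alpha_zero_reproduces_upsampled_previous_phase(self):
        cfg = _toy_config()
        gen = build_frame_generator(cfg, seed=0)
        z = np.random.default_rng(2).standard_normal((2, 64)).astype(np.float32)
        gen.set_phase(8, 1.0)
        low = gen(Tensor(z)).data
        gen.set_phase(16, 0.0)
        blended = gen(Tensor(z)).data
        upsampled = low.repeat(2, axis=2).repeat(2, axis=3)
        np.testing.assert_array_equal(blended, upsampled)

    def test_fade_in_output_is_continuous_in_alpha(self):
        cfg = _toy_config()
        gen = build_frame_generator(cfg, seed=0)
        z = np.random.default_rng(3).standard_normal((2, 64)).astype(np.float32)
        outs = []
        for alpha in (0.0, 1e-3, 0.5, 1.0 - 1e-3, 1.0):
            gen.set_phase(16, alpha)
            outs.append(gen(Tensor(z)).data)
        assert np.abs(outs[1] - outs[0]).max() < 1e-2
        assert np.abs(outs[4] - outs[3]).max() < 1e-2
        assert np.abs(outs[2] - outs[0]).max() > 0  # alpha actually does something

    def test_wrong_input_resolution_is_an_input_error(self):
        cfg = _toy_config()
        critic = build_frame_critic(cfg, seed=0)
        critic.set_phase(16, 1.0)
        with pytest.raises(InputError):
            critic(Tensor(np.zeros((2, 3, 8, 8))))


class TestExtractFeatures:
    def test_feature_width_matches_final_layer_input(self):
        cfg = _toy_config()
        critic = build_frame_critic(cfg, seed=0)
        critic.set_phase(32, 1.0)
        x = np.random.default_rng(0).uniform(-1, 1, (4, 3, 32, 32)).astype(np.float32)
        feats = extract_features(critic, x)
        assert feats.shape == (4, cfg.feature_dim)
        assert feats.shape[1] == critic.fc_score.in_dim
        assert np.isfinite(feats.data).all()

    def test_features_deterministic(self):
        cfg = _toy_config()
        critic = build_frame_critic(cfg, seed=0)
        critic.set_phase(16, 1.0)
        x = np.random.default_rng(0).uniform(-1, 1, (2, 3, 16, 16)).astype(np.float32)
        np.testing.assert_array_equal(extract_features(critic, x).data,
                                      extract_features(critic, x).data)


class _ConstantCritic:
    def __call__(self, x):
        return Tensor(np.full((x.shape[0], 1), 3.7))


class _LinearCritic:
    """f(x) = <w, x> with a chosen gradient norm."""

    def __init__(self, shape, norm):
        w = np.zeros(np.prod(shape), dtype=np.float32)
        w[0] = norm
        self.w = Tensor(w.reshape(-1, 1), requires_grad=True)
        self.n = int(np.prod(shape))

    def __call__(self, x):
        return x.reshape(x.shape[0], self.n) @ self.w


class TestWganGpClosedForms:
    def test_constant_critic_penalty_equals_lambda(self):
        rng = np.random.default_rng(0)
        real = rng.normal(size=(4, 1, 8, 8)).astype(np.float32)
        fake = rng.normal(size=(4, 1, 8, 8)).astype(np.float32)
        losses = wgan_gp_losses(_ConstantCritic(), real, fake, gp_lambda=10.0, seed=0)
        assert float(losses.penalty) == pytest.approx(10.0, rel=1e-4)
        assert float(losses.critic_loss) == pytest.approx(10.0, rel=1e-4)

    @pytest.mark.parametrize("gp_lambda,norm", [(10.0, 3.0), (5.0, 0.5), (10.0, 1.0)])
    def test_linear_critic_penalty_closed_form(self, gp_lambda, norm):
        rng = np.random.default_rng(1)
        shape = (2, 6, 6)
        real = rng.normal(size=(3, *shape)).astype(np.float32)
        fake = rng.normal(size=(3, *shape)).astype(np.float32)
        critic = _LinearCritic(shape, norm)
        pen = gradient_penalty(critic, real, fake, gp_lambda, np.random.default_rng(0))
        assert float(pen) == pytest.approx(gp_lambda * (norm - 1.0) ** 2, rel=1e-4, abs=1e-6)

    def test_linear_critic_gradient_norm_matches_finite_differences(self):
        shape = (1, 4, 4)
        critic = _LinearCritic(shape, 3.0)
        x = np.random.default_rng(2).normal(size=(1, *shape)).astype(np.float64)
        # finite-difference gradient norm of f at x
        eps, grads = 1e-4, []
        base = critic(Tensor(x)).data.item()
        flat = x.copy().reshape(-1)
        for i in range(flat.size):
            xp = flat.copy()
            xp[i] += eps
            grads.append((critic(Tensor(xp.reshape(1, *shape))).data.item() - base) / eps)
        assert np.linalg.norm(grads) == pytest.approx(3.0, rel=1e-3)

    def test_zero_lambda_means_zero_penalty(self):
        rng = np.random.default_rng(3)
        real = rng.normal(size=(2, 1, 4, 4)).astype(np.float32)
        fake = rng.normal(size=(2, 1, 4, 4)).astype(np.float32)
        losses = wgan_gp_losses(_ConstantCritic(), real, fake, gp_lambda=0.0, seed=0)
        assert float(losses.penalty) == 0.0

    def test_shape_mismatch_is_an_input_error(self):
        with pytest.raises(InputError):
            wgan_gp_losses(_ConstantCritic(), np.zeros((2, 1, 4, 4)), np.zeros((3, 1, 4, 4)), 10.0, 0)


class TestTraining:
    def test_toy_run_completes_with_finite_losses_and_batch_schedule(self):
        spec = SceneSpec(kind="tunnel", resolution=16, n_frames=4)
        ds = FrameDataset.from_clips(generate_tunnel(spec, 4, seed=0))
        cfg = FrameGANConfig(latent_dim=32, max_resolution=16,
                             channels_schedule={4: 8, 8: 6, 16: 6},
                             feature_dim=32, steps_per_phase=2)
        gen, critic, history = train_frame_gan(ds, cfg, seed=0)
        assert gen.trained and critic.trained
        assert len(history) == 2 * 5  # 5 phases x 2 steps
        assert all(np.isfinite([h["d_loss"], h["g_loss"], h["penalty"]]).all() for h in history)
        # default batch rule: 8 at every resolution <= 256 px
        assert all(h["batch_size"] == 8 for h in history)
        # phases run in the documented order with fade-ins between resolutions
        assert [h["resolution"] for h in history] == [4, 4, 8, 8, 8, 8, 16, 16, 16, 16]
        fades = [h for h in history if h["phase"] == "fade"]
        assert fades and all(0 < h["alpha"] <= 1 for h in fades)

    def test_training_is_seed_deterministic(self):
        spec = SceneSpec(kind="tunnel", resolution=8, n_frames=3)
        ds = FrameDataset.from_clips(generate_tunnel(spec, 3, seed=1))
        cfg = FrameGANConfig(latent_dim=16, max_resolution=8,
                             channels_schedule={4: 6, 8: 6}, feature_dim=16,
                             steps_per_phase=2)
        g1, _, h1 = train_frame_gan(ds, cfg, seed=42)
        g2, _, h2 = train_frame_gan(ds, cfg, seed=42)
        assert h1 == h2
        for (k1, p1), (k2, p2) in zip(sorted(g1.state_dict().items()),
                                      sorted(g2.state_dict().items())):
            assert k1 == k2
            np.testing.assert_array_equal(p1, p2)

    def test_empty_dataset_rejected(self):
        cfg = _toy_config()
        ds = FrameDataset(np.zeros((0, 32, 32, 3)), [])
        with pytest.raises(InputError):
            train_frame_gan(ds, cfg, seed=0)
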