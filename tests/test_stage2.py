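"""Stage-2 trainer: BCE arithmetic, clip sampling, backbone freezing."""

import math

import numpy as np
import pytest

from trajgan import (
    ConfigError,
    InputError,
    PluginConfig,
    Stage2Config,
    VideoCriticConfig,
    sample_real_clip_batch,
    stage2_step,
)
from trajgan.plugin import Plugin
from trajgan.stage2 import bce_with_logits, shuffle_frames, train_stage2
from trajgan.synthetic_video import SceneSpec, VideoClip, generate_tunnel
from trajgan.video_critic import VideoCritic
from trajgan.autodiff import Tensor


def _toy_plugin_config(latent_dim):
    return PluginConfig(z_dim=15, layer_widths=[15, 15, 15, latent_dim], out_dim=latent_dim)


def _toy_vc_config(feature_dim):
    return VideoCriticConfig(
        conv_layers=[(1, 4, (3, 4), (1, 2)), (4, 2, (3, 4), (1, 2)), (2, 1, (4, 3), (1, 1))],
        n_frames=8,
        feature_dim=feature_dim,
    )


class TestConfigValidation:
    @pytest.mark.parametrize("bad", [
        {"learning_rate": 0.0}, {"epochs": 0}, {"batch_clips": 0},
        {"generator_loss_form": "hinge"},
    ])
    def test_invalid_values_rejected(self, bad):
        with pytest.raises(ConfigError):
            Stage2Config(**bad)

    def test_reference_defaults(self):
        cfg = Stage2Config()
        assert (cfg.learning_rate, cfg.beta1, cfg.beta2, cfg.epochs) == (2e-4, 0.5, 0.999, 50)


class TestSampleRealClipBatch:
    def test_exact_length_video_always_returns_full_clip(self):
        clip = VideoClip(np.zeros((8, 8, 8, 1), dtype=np.float32), "v0")
        batch = sample_real_clip_batch([clip], 8, 5, np.random.default_rng(0))
        assert all(b.n_frames == 8 and b.frame_origin == 0 for b in batch)

    def test_seeded_reproducibility(self):
        clips = generate_tunnel(SceneSpec(kind="tunnel", resolution=8, n_frames=16), 4, seed=0)
        a = sample_real_clip_batch(clips, 8, 6, np.random.default_rng(5))
        b = sample_real_clip_batch(clips, 8, 6, np.random.default_rng(5))
        assert [(c.clip_id, c.frame_origin) for c in a] == [(c.clip_id, c.frame_origin) for c in b]

    def test_all_start_offsets_occur(self):
        clip = VideoClip(np.zeros((16, 8, 8, 1), dtype=np.float32), "v0")
        rng = np.random.default_rng(1)
        starts = {w.frame_origin for w in sample_real_clip_batch([clip], 8, 500, rng)}
        assert starts == set(range(9))

    def test_short_video_rejected_by_name(self):
        clips = [VideoClip(np.zeros((8, 8, 8, 1), dtype=np.float32), "ok"),
                 VideoClip(np.zeros((4, 8, 8, 1), dtype=np.float32), "too_short")]
        with pytest.raises(InputError) as err:
            sample_real_clip_batch(clips, 8, 1, np.random.default_rng(0))
        assert "too_short" in str(err.value)


class TestBce:
    def test_closed_form_at_zero_logits(self):
        logits = Tensor(np.zeros((5, 1)))
        assert float(bce_with_logits(logits, 1.0)) == pytest.approx(math.log(2), rel=1e-6)
        assert float(bce_with_logits(logits, 0.0)) == pytest.approx(math.log(2), rel=1e-6)

    def test_stable_at_large_logits(self):
        assert float(bce_with_logits(Tensor(np.array([[80.0]])), 1.0)) < 1e-6
        assert float(bce_with_logits(Tensor(np.array([[-80.0]])), 0.0)) < 1e-6


class TestStage2Step:
    def test_untrained_critic_at_half_probability_gives_two_ln_two(self, tiny_backbone):
        gen, critic, _, cfg = tiny_backbone
        gen.frozen = critic.frozen = True
        plugin = Plugin(_toy_plugin_config(cfg.latent_dim), seed=0)
        vcritic = VideoCritic(_toy_vc_config(cfg.feature_dim), seed=0)
        # zero the output layer so D(x) = 0.5 exactly everywhere
        vcritic.fc.weight.data[...] = 0.0
        vcritic.fc.bias.data[...] = 0.0
        clips = generate_tunnel(SceneSpec(kind="tunnel", resolution=16, n_frames=8), 4, seed=3)
        s2cfg = Stage2Config(batch_clips=4, epochs=1)
        rec = stage2_step(plugin, vcritic, gen, critic, clips, s2cfg, np.random.default_rng(0))
        assert rec["loss_D"] == pytest.approx(2 * math.log(2), rel=1e-5)
        assert rec["score_real"] == pytest.approx(0.5, abs=1e-6)

    def test_step_without_optimizers_changes_nothing(self, tiny_backbone):
        gen, critic, _, cfg = tiny_backbone
        gen.frozen = critic.frozen = True
        plugin = Plugin(_toy_plugin_config(cfg.latent_dim), seed=1)
        vcritic = VideoCritic(_toy_vc_config(cfg.feature_dim), seed=1)
        before = {**plugin.state_dict(), **vcritic.state_dict()}
        clips = generate_tunnel(SceneSpec(kind="tunnel", resolution=16, n_frames=8), 2, seed=4)
        rec = stage2_step(plugin, vcritic, gen, critic, clips,
                          Stage2Config(batch_clips=2, epochs=1), np.random.default_rng(0))
        after = {**plugin.state_dict(), **vcritic.state_dict()}
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])
        assert rec["loss_D"] >= 0.0 and rec["loss_plugin"] >= 0.0

    def test_backbone_bit_identical_across_step(self, tiny_backbone):
        gen, critic, _, cfg = tiny_backbone
        gen.frozen = critic.frozen = True
        gen.freeze()
        critic.freeze()
        h_before = gen.param_hash() + critic.param_hash()
        plugin = Plugin(_toy_plugin_config(cfg.latent_dim), seed=2)
        vcritic = VideoCritic(_toy_vc_config(cfg.feature_dim), seed=2)
        from trajgan import nn

        opt_d = nn.Adam(vcritic.parameters(), 2e-4, 0.5, 0.999)
        opt_p = nn.Adam(plugin.parameters(), 2e-4, 0.5, 0.999)
        clips = generate_tunnel(SceneSpec(kind="tunnel", resolution=16, n_frames=8), 2, seed=5)
        stage2_step(plugin, vcritic, gen, critic, clips,
                    Stage2Config(batch_clips=2, epochs=1), np.random.default_rng(1), opt_d, opt_p)
        assert gen.param_hash() + critic.param_hash() == h_before


class TestTrainStage2:
    def test_short_run_deterministic_and_finite(self, tiny_backbone):
        gen, critic, _, cfg = tiny_backbone
        clips = generate_tunnel(SceneSpec(kind="tunnel", resolution=16, n_frames=8), 8, seed=6)
        s2cfg = Stage2Config(epochs=2, batch_clips=4, seed=9)
        p1, v1, h1 = train_stage2(clips, gen, critic, _toy_plugin_config(cfg.latent_dim),
                                  _toy_vc_config(cfg.feature_dim), s2cfg)
        p2, v2, h2 = train_stage2(clips, gen, critic, _toy_plugin_config(cfg.latent_dim),
                                  _toy_vc_config(cfg.feature_dim), s2cfg)
        assert h1 == h2
        for k, arr in p1.state_dict().items():
            np.testing.assert_array_equal(arr, p2.state_dict()[k])
        assert all(np.isfinite(list(r.values())).all() for r in
                   ({k: v for k, v in rec.items() if isinstance(v, float)} for rec in h1))

    def test_incompatible_plugin_width_rejected(self, tiny_backbone):
        gen, critic, _, cfg = tiny_backbone
        clips = generate_tunnel(SceneSpec(kind="tunnel", resolution=16, n_frames=8), 2, seed=7)
        with pytest.raises(ConfigError):
            train_stage2(clips, gen, critic, _toy_plugin_config(cfg.latent_dim + 1),
                         _toy_vc_config(cfg.feature_dim), Stage2Config(epochs=1, batch_clips=2))


def test_shuffle_frames_is_a_permutation():
    clip = VideoClip(np.arange(5 * 4 * 4, dtype=np.float32).reshape(5, 4, 4, 1) / 100, "c")
    shuffled = shuffle_frames(clip, np.random.default_rng(0))
    assert shuffled.frames.shape == clip.frames.shape
    assert sorted(shuffled.frames.sum(axis=(1, 2, 3)).tolist()) == \
        sorted(clip.frames.sum(axis=(1, 2, 3)).tolist())
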