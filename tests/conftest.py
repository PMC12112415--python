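"""Shared fixtures: toy datasets, a tiny trained backbone, and one full
end-to-end pipeline run (built once per session, reused by several tests)."""

from __future__ import annotations

import numpy as np
import pytest
import yaml

from trajgan import (
    FrameDataset,
    FrameGANConfig,
    PluginConfig,
    SceneSpec,
    Stage2Config,
    VideoCriticConfig,
    generate_tunnel,
    train_frame_gan,
    train_stage2,
)

# toy architecture shared by the expensive fixtures; small enough to train on
# one CPU core in minutes while keeping the full two-stage structure
TOY_CHANNELS = {4: 16, 8: 12, 16: 8, 32: 6}
TOY_PLUGIN = dict(z_dim=127, layer_widths=[95, 79, 63, 64], out_dim=64)
TOY_VIDEO_CRITIC = dict(
    conv_layers=[
        (1, 16, (3, 6), (1, 2)),
        (16, 8, (3, 4), (1, 2)),
        (8, 4, (3, 4), (1, 2)),
        (4, 1, (2, 3), (1, 1)),
    ],
    n_frames=8,
    feature_dim=64,
)


def toy_run_config_dict() -> dict:
    """A complete, consistent toy configuration as a YAML-ready dict."""
    return {
        "seed": 0,
        "data": {"kind": "tunnel", "resolution": 32, "n_clips": 64, "n_frames": 16},
        "frame_gan": {
            "latent_dim": 64,
            "max_resolution": 32,
            "channels_schedule": TOY_CHANNELS,
            "batch_schedule": {4: 8, 8: 8, 16: 8, 32: 8},
            "feature_dim": 64,
            "steps_per_phase": 30,
        },
        "plugin": TOY_PLUGIN,
        "video_critic": {
            "conv_layers": [[ci, co, list(k), list(s)] for ci, co, k, s in TOY_VIDEO_CRITIC["conv_layers"]],
            "n_frames": 8,
            "feature_dim": 64,
        },
        "stage2": {"epochs": 50, "batch_clips": 8, "n_frames": 8},
        "evaluation": {"n_clips": 64, "clip_len": 16, "n_splits": 5},
    }


@pytest.fixture(scope="session")
def tunnel_clips():
    spec = SceneSpec(kind="tunnel", resolution=32, n_frames=16)
    return generate_tunnel(spec, 64, seed=0)


@pytest.fixture(scope="session")
def tiny_backbone():
    """A 16px backbone trained for a handful of steps (shape/semantic tests)."""
    spec = SceneSpec(kind="tunnel", resolution=16, n_frames=8)
    clips = generate_tunnel(spec, 8, seed=1)
    config = FrameGANConfig(
        latent_dim=32,
        max_resolution=16,
        channels_schedule={4: 12, 8: 8, 16: 6},
        batch_schedule={4: 4, 8: 4, 16: 4},
        feature_dim=32,
        steps_per_phase=3,
    )
    gen, critic, history = train_frame_gan(FrameDataset.from_clips(clips), config, seed=3)
    return gen, critic, history, config


@pytest.fixture(scope="session")
def trained_pipeline(tunnel_clips):
    """Full two-stage toy training: 32px backbone + 50-epoch stage 2.

    This is the expensive fixture (a few CPU-minutes); everything that needs
    a genuinely trained model shares it.
    """
    cfg = toy_run_config_dict()
    fg_cfg = FrameGANConfig(**cfg["frame_gan"])
    gen, critic, s1_history = train_frame_gan(
        FrameDataset.from_clips(tunnel_clips), fg_cfg, seed=1
    )
    p_cfg = PluginConfig(**TOY_PLUGIN)
    vc_cfg = VideoCriticConfig(**TOY_VIDEO_CRITIC)
    s2_cfg = Stage2Config(**cfg["stage2"], seed=2)
    plugin, vcritic, s2_history = train_stage2(
        tunnel_clips, gen, critic, p_cfg, vc_cfg, s2_cfg
    )
    return {
        "clips": tunnel_clips,
        "generator": gen,
        "frame_critic": critic,
        "plugin": plugin,
        "video_critic": vcritic,
        "stage1_history": s1_history,
        "stage2_history": s2_history,
        "configs": {"frame_gan": fg_cfg, "plugin": p_cfg, "video_critic": vc_cfg, "stage2": s2_cfg},
    }


@pytest.fixture()
def toy_config_file(tmp_path):
    path = tmp_path / "toy.yaml"
    path.write_text(yaml.safe_dump(toy_run_config_dict()))
    return path
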