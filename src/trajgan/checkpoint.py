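"""Single-file checkpoints: one ``.npz`` holding parameters + JSON metadata.

Layout (version 1): every parameter array is stored under
``<network>::<dotted parameter path>``; ``__meta__`` holds a JSON string with
the version, the configs needed to rebuild each network, phase pointers,
trained/frozen flags, optimizer state shapes and the RNG bit-generator state.
The stage-2 checkpoint embeds the full backbone so it is self-contained.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .errors import ConfigError, FormatError
from .frame_gan import Critic, FrameGANConfig, Generator
from .plugin import Plugin, PluginConfig
from .stage2 import Stage2Config
from .video_critic import VideoCritic, VideoCriticConfig

CHECKPOINT_VERSION = 1


def _pack(prefix: str, module) -> dict[str, np.ndarray]:
    return {f"{prefix}::{k}": v for k, v in module.state_dict().items()}


def _unpack(arrays: dict, prefix: str) -> dict[str, np.ndarray]:
    plen = len(prefix) + 2
    return {k[plen:]: arrays[k] for k in arrays.files if k.startswith(prefix + "::")}


def _rng_state(rng: np.random.Generator | None) -> dict | None:
    return None if rng is None else json.loads(json.dumps(rng.bit_generator.state))


def restore_rng(state: dict | None) -> np.random.Generator:
    rng = np.random.default_rng(0)
    if state is not None:
        rng.bit_generator.state = state
    return rng


def save_backbone(path, generator: Generator, critic: Critic,
                  rng: np.random.Generator | None = None, extra: dict | None = None) -> Path:
    path = Path(path)
    meta = {
        "version": CHECKPOINT_VERSION,
        "kind": "backbone",
        "config": generator.config.to_dict(),
        "generator": {"resolution": generator.current_resolution, "alpha": generator.alpha,
                      "trained": generator.trained, "frozen": generator.frozen},
        "critic": {"resolution": critic.current_resolution, "alpha": critic.alpha,
                   "trained": critic.trained, "frozen": critic.frozen},
        "rng_state": _rng_state(rng),
        "extra": extra or {},
    }
    arrays = {**_pack("gen", generator), **_pack("critic", critic)}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def _load_meta(data) -> dict:
    if "__meta__" not in data.files:
        raise FormatError("not a trajgan checkpoint: missing __meta__ entry")
    meta = json.loads(bytes(data["__meta__"]).decode())
    if meta.get("version") != CHECKPOINT_VERSION:
        raise FormatError(f"unsupported checkpoint version {meta.get('version')}")
    return meta


def _restore_backbone(data, meta) -> tuple[Generator, Critic]:
    config = FrameGANConfig(**meta["config"])
    gen = Generator(config, seed=0)
    critic = Critic(config, seed=0)
    gen.load_state_dict(_unpack(data, "gen"))
    critic.load_state_dict(_unpack(data, "critic"))
    for mod, m in ((gen, meta["generator"]), (critic, meta["critic"])):
        mod.set_phase(m["resolution"], m["alpha"])
        mod.trained = m["trained"]
        mod.frozen = m["frozen"]
        if mod.frozen:
            mod.freeze()
    return gen, critic


def load_backbone(path) -> tuple[Generator, Critic, dict]:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"checkpoint not found: {path}")
    with np.load(path) as data:
        meta = _load_meta(data)
        if meta["kind"] != "backbone":
            raise FormatError(f"expected a backbone checkpoint, got kind={meta['kind']!r}")
        gen, critic = _restore_backbone(data, meta)
    return gen, critic, meta


def save_stage2(path, plugin: Plugin, video_critic: VideoCritic, generator: Generator,
                frame_critic: Critic, stage2_config: Stage2Config,
                rng: np.random.Generator | None = None, extra: dict | None = None) -> Path:
    path = Path(path)
    meta = {
        "version": CHECKPOINT_VERSION,
        "kind": "stage2",
        "config": generator.config.to_dict(),
        "plugin_config": plugin.config.to_dict(),
        "video_critic_config": video_critic.config.to_dict(),
        "stage2_config": stage2_config.to_dict(),
        "generator": {"resolution": generator.current_resolution, "alpha": generator.alpha,
                      "trained": generator.trained, "frozen": generator.frozen},
        "critic": {"resolution": frame_critic.current_resolution, "alpha": frame_critic.alpha,
                   "trained": frame_critic.trained, "frozen": frame_critic.frozen},
        "backbone_hash": generator.param_hash() + frame_critic.param_hash(),
        "rng_state": _rng_state(rng),
        "extra": extra or {},
    }
    arrays = {
        **_pack("gen", generator),
        **_pack("critic", frame_critic),
        **_pack("plugin", plugin),
        **_pack("vcritic", video_critic),
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_stage2(path) -> tuple[Plugin, VideoCritic, Generator, Critic, dict]:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"checkpoint not found: {path}")
    with np.load(path) as data:
        meta = _load_meta(data)
        if meta["kind"] != "stage2":
            raise FormatError(f"expected a stage-2 checkpoint, got kind={meta['kind']!r}")
        gen, critic = _restore_backbone(data, meta)
        plugin = Plugin(PluginConfig(**meta["plugin_config"]), seed=0)
        plugin.load_state_dict(_unpack(data, "plugin"))
        vc_meta = dict(meta["video_critic_config"])
        vc_meta["conv_layers"] = [
            (ci, co, tuple(k), tuple(s)) for ci, co, k, s in vc_meta["conv_layers"]
        ]
        vcritic = VideoCritic(VideoCriticConfig(**vc_meta), seed=0)
        vcritic.load_state_dict(_unpack(data, "vcritic"))
        stored_hash = meta["backbone_hash"]
    if gen.param_hash() + critic.param_hash() != stored_hash:
        raise FormatError("backbone parameter hash mismatch in stage-2 checkpoint")
    return plugin, vcritic, gen, critic, meta
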