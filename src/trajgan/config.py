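"""Run configuration: strict YAML loading, defaults, cross-block invariants.

Precedence is defaults <- file <- explicit overrides.  Unknown keys anywhere
raise :class:`~trajgan.errors.ConfigError` naming the offending key path, and
cross-block consistency (plugin output width vs generator latent width, video
critic frame count vs stage-2 sampler, feature widths) is validated on every
resolve.  The defaults are the reference architecture.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError
from .frame_gan import FrameGANConfig
from .metrics import EvaluationConfig
from .plugin import PluginConfig
from .stage2 import Stage2Config
from .synthetic_video import SceneSpec
from .video_critic import VideoCriticConfig


@dataclass
class DataConfig:
    kind: str = "tunnel"
    resolution: int = 128
    n_clips: int = 64
    n_frames: int = 16
    motion_amplitude: float = 2.0
    texture_detail: int = 3
    channels: int = 3

    def scene_spec(self) -> SceneSpec:
        return SceneSpec(
            kind=self.kind,
            resolution=self.resolution,
            n_frames=self.n_frames,
            motion_amplitude=self.motion_amplitude,
            texture_detail=self.texture_detail,
            channels=self.channels,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs"
    data: DataConfig = field(default_factory=DataConfig)
    frame_gan: FrameGANConfig = field(default_factory=FrameGANConfig)
    plugin: PluginConfig = field(default_factory=PluginConfig)
    video_critic: VideoCriticConfig = field(default_factory=VideoCriticConfig)
    stage2: Stage2Config = field(default_factory=Stage2Config)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)

    def validate(self) -> "RunConfig":
        if self.plugin.out_dim != self.frame_gan.latent_dim:
            raise ConfigError(
                f"plugin.out_dim ({self.plugin.out_dim}) must equal "
                f"frame_gan.latent_dim ({self.frame_gan.latent_dim})"
            )
        if self.video_critic.n_frames != self.stage2.n_frames:
            raise ConfigError(
                f"video_critic.n_frames ({self.video_critic.n_frames}) must equal "
                f"stage2.n_frames ({self.stage2.n_frames})"
            )
        if self.video_critic.feature_dim != self.frame_gan.feature_dim:
            raise ConfigError(
                f"video_critic.feature_dim ({self.video_critic.feature_dim}) must equal "
                f"frame_gan.feature_dim ({self.frame_gan.feature_dim})"
            )
        if self.data.resolution != self.frame_gan.max_resolution:
            raise ConfigError(
                f"data.resolution ({self.data.resolution}) must equal "
                f"frame_gan.max_resolution ({self.frame_gan.max_resolution})"
            )
        return self

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out_dir": self.out_dir,
            "data": self.data.to_dict(),
            "frame_gan": self.frame_gan.to_dict(),
            "plugin": self.plugin.to_dict(),
            "video_critic": self.video_critic.to_dict(),
            "stage2": self.stage2.to_dict(),
            "evaluation": self.evaluation.to_dict(),
        }


_BLOCKS = {
    "data": DataConfig,
    "frame_gan": FrameGANConfig,
    "plugin": PluginConfig,
    "video_critic": VideoCriticConfig,
    "stage2": Stage2Config,
    "evaluation": EvaluationConfig,
}
_SCALARS = {"seed": int, "out_dir": str}


def _build_block(cls, values: dict, path: str, base: dict | None = None):
    allowed = {f.name for f in dataclasses.fields(cls)}
    merged = dict(base or {})
    for key, val in values.items():
        if key not in allowed:
            raise ConfigError(f"unknown key {path}.{key}")
        merged[key] = val
    if cls is VideoCriticConfig and "conv_layers" in merged:
        merged["conv_layers"] = [
            (ci, co, tuple(k), tuple(s)) for ci, co, k, s in merged["conv_layers"]
        ]
    try:
        return cls(**merged)
    except TypeError as exc:
        raise ConfigError(f"invalid block {path}: {exc}") from exc


def _merge(cfg_dict: dict, updates: dict, origin: str) -> dict:
    out = {k: dict(v) if isinstance(v, dict) else v for k, v in cfg_dict.items()}
    for key, val in updates.items():
        if key in _SCALARS:
            out[key] = _SCALARS[key](val)
        elif key in _BLOCKS:
            if not isinstance(val, dict):
                raise ConfigError(f"{origin}: block {key!r} must be a mapping")
            out.setdefault(key, {})
            for k2, v2 in val.items():
                out[key][k2] = v2
        else:
            raise ConfigError(f"unknown key {key} ({origin})")
    return out


def resolve_config(path: str | Path | None = None, overrides: dict | None = None) -> RunConfig:
    """defaults <- YAML file <- overrides, validated."""
    merged: dict = {k: {} for k in _BLOCKS}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        merged = _merge(merged, raw, f"file {path}")
    if overrides:
        merged = _merge(merged, overrides, "override")
    kwargs = {}
    for key in _SCALARS:
        if key in merged:
            kwargs[key] = merged[key]
    for name, cls in _BLOCKS.items():
        kwargs[name] = _build_block(cls, merged.get(name, {}), name)
    return RunConfig(**kwargs).validate()


def load_config(path: str | Path) -> RunConfig:
    if not Path(path).exists():
        raise ConfigError(f"config file not found: {path}")
    return resolve_config(path)


def write_config(config: RunConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))
    return path
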