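"""The plugin network: noise + frame index -> unit-norm latent trajectory.

A single Gaussian noise vector ``z`` is shared by all frames of a clip.  For
each frame index ``t`` the network concatenates an encoded time scalar onto
the running hidden vector and applies a linear layer; the first three layers
use ReLU, the fourth is linear, and the result is L2-normalized onto the
unit hypersphere.  Rows are therefore computable per frame independently,
which is what lets a frozen image generator decode them into a video of any
length.

At the reference scale the four layers are (2048->1535), (1536->1023),
(1024->511), (512->512): every hidden width is one less than a power of two
so that appending the time component restores a power-of-two input width.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .errors import ConfigError, InputError
from .frame_gan import Generator
from .synthetic_video import VideoClip

REFERENCE_LAYER_WIDTHS = [1535, 1023, 511, 512]


@dataclass
class PluginConfig:
    z_dim: int = 2047
    layer_widths: list[int] = field(default_factory=lambda: list(REFERENCE_LAYER_WIDTHS))
    time_encoding: str = "normalized_unit"  # or "raw_index"
    norm_epsilon: float = 1e-8
    out_dim: int = 512
    n_ref: int = 8  # frames mapped onto [0, 1] by the normalized encoding

    def __post_init__(self):
        if len(self.layer_widths) != 4:
            raise ConfigError(f"plugin must have exactly four layers, got {len(self.layer_widths)}")
        if self.z_dim < 1:
            raise ConfigError(f"z_dim must be >= 1, got {self.z_dim}")
        if self.layer_widths[-1] != self.out_dim:
            raise ConfigError(
                f"last layer width {self.layer_widths[-1]} must equal out_dim {self.out_dim}"
            )
        if self.time_encoding not in ("normalized_unit", "raw_index"):
            raise ConfigError(f"unknown time_encoding {self.time_encoding!r}")
        if self.norm_epsilon <= 0:
            raise ConfigError("norm_epsilon must be positive")
        if self.n_ref < 2:
            raise ConfigError("n_ref must be >= 2")

    @property
    def layer_in_widths(self) -> list[int]:
        """Input width of each linear layer (previous output + 1 time slot)."""
        return [self.z_dim + 1] + [w + 1 for w in self.layer_widths[:-1]]

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


class Plugin(nn.Module):
    """Four concat-then-linear layers; see module docstring."""

    def __init__(self, config: PluginConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.layers = [
            nn.Linear(cin, cout, rng)
            for cin, cout in zip(config.layer_in_widths, config.layer_widths)
        ]

    def encode_time(self, t_indices: np.ndarray) -> np.ndarray:
        t = np.asarray(t_indices, dtype=np.float64)
        if self.config.time_encoding == "normalized_unit":
            t = t / (self.config.n_ref - 1)
        return t.astype(np.float32)

    def __call__(self, z, timeline) -> Tensor:
        return plugin_forward(self, z, timeline)


def _validate_timeline(timeline) -> np.ndarray:
    t = np.asarray(timeline)
    if t.ndim != 1 or t.size < 1:
        raise InputError(f"timeline must be a non-empty 1-D sequence, got shape {t.shape}")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise InputError("timeline entries must be integers")
        t = np.round(t).astype(np.int64)
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise InputError(f"timeline must be strictly increasing, got {t.tolist()}")
    return t.astype(np.int64)


def sample_video_noise(seed: int | np.random.Generator, z_dim: int) -> np.ndarray:
    """One standard-normal noise vector per clip, shared across its frames."""
    if z_dim < 1:
        raise InputError(f"z_dim must be >= 1, got {z_dim}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.standard_normal(z_dim).astype(np.float32)


def plugin_forward(plugin: Plugin, z, timeline) -> Tensor:
    """Latent trajectory ``(n, out_dim)``; row i depends only on (t_i, z)."""
    cfg = plugin.config
    z = np.asarray(z.data if isinstance(z, Tensor) else z, dtype=np.float32)
    if z.shape != (cfg.z_dim,):
        raise InputError(f"noise vector must have shape ({cfg.z_dim},), got {z.shape}")
    t = _validate_timeline(timeline)
    enc = plugin.encode_time(t)
    # Rows are computed one frame at a time so that a single-frame call is
    # bit-identical to the corresponding row of a batched call (BLAS reduction
    # order depends on batch shape otherwise).
    rows = []
    zt = Tensor(z.reshape(1, cfg.z_dim))
    for ti in enc:
        tcol = Tensor(np.array([[ti]], dtype=np.float32))
        h: Tensor = zt
        for i, layer in enumerate(plugin.layers):
            h = layer(ad.concat([h, tcol], axis=1))
            if i < 3:
                h = ad.relu(h)
        norm = ad.sqrt((h * h).sum(axis=1, keepdims=True))
        rows.append(h * ad.pow_const(ad.clip_min_const(norm, cfg.norm_epsilon), -1.0))
    return rows[0] if len(rows) == 1 else ad.concat(rows, axis=0)


def generate_video(plugin: Plugin, generator: Generator, z, timeline,
                   clip_id: str | None = None, require_frozen: bool = True) -> VideoClip:
    """Decode the plugin trajectory through the frozen frame generator."""
    cfg = plugin.config
    if cfg.out_dim != generator.config.latent_dim:
        raise ConfigError(
            f"plugin out_dim {cfg.out_dim} != generator latent_dim {generator.config.latent_dim}"
        )
    if require_frozen and not (generator.frozen and generator.trained):
        raise ConfigError("generator must be trained and frozen before video generation")
    traj = plugin_forward(plugin, z, timeline)
    frames = generator(traj).data  # (n, C, H, W)
    frames = np.clip(np.transpose(frames, (0, 2, 3, 1)), -1.0, 1.0)
    if clip_id is None:
        digest = hashlib.sha1(np.asarray(z, dtype=np.float32).tobytes()).hexdigest()[:8]
        clip_id = f"gen_{digest}"
    return VideoClip(frames.astype(np.float32), clip_id)
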