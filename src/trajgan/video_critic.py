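"""The video discriminator: 2D convolutions over stacked frame features.

Instead of seeing raw pixel volumes, the video discriminator receives a
single-channel "image" whose rows are the frozen frame-critic's features of
consecutive frames (time on the height axis, feature index on the width
axis).  Four valid-mode Conv2D+ReLU layers reduce it, the result is
flattened through a linear layer sized automatically from the convolution
arithmetic, and a sigmoid yields the real-video probability.

At the reference scale (8 frames x 512 features) the conv stack
(1,16,(3,10),(1,2)) -> (16,8,(3,8),(1,2)) -> (8,4,(3,6),(1,2)) ->
(4,1,(2,6),(1,2)) shrinks heights 8->6->4->2->1 and widths
512->252->123->59->27, so the final linear layer is 27 -> 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .errors import ConfigError, InputError
from .frame_gan import Critic, extract_features
from .synthetic_video import VideoClip

REFERENCE_CONV_LAYERS = [
    (1, 16, (3, 10), (1, 2)),
    (16, 8, (3, 8), (1, 2)),
    (8, 4, (3, 6), (1, 2)),
    (4, 1, (2, 6), (1, 2)),
]


def conv_output_size(in_size: int, kernel: int, stride: int) -> int:
    """Number of valid windows: floor((in - k)/s) + 1."""
    if kernel < 1 or stride < 1:
        raise InputError(f"kernel and stride must be >= 1, got {kernel}, {stride}")
    if in_size < kernel:
        raise InputError(f"input size {in_size} smaller than kernel {kernel}")
    return (in_size - kernel) // stride + 1


@dataclass
class VideoCriticConfig:
    conv_layers: list[tuple] = field(default_factory=lambda: [tuple(l) for l in REFERENCE_CONV_LAYERS])
    n_frames: int = 8
    feature_dim: int = 512

    def __post_init__(self):
        self.conv_layers = [
            (int(ci), int(co), (int(k[0]), int(k[1])), (int(s[0]), int(s[1])))
            for ci, co, k, s in self.conv_layers
        ]
        if self.conv_layers[0][0] != 1:
            raise ConfigError("first conv layer must take 1 input channel")
        for i in range(len(self.conv_layers) - 1):
            if self.conv_layers[i][1] != self.conv_layers[i + 1][0]:
                raise ConfigError(
                    f"channel chain broken between conv layers {i} and {i + 1}: "
                    f"{self.conv_layers[i][1]} -> {self.conv_layers[i + 1][0]}"
                )
        for i, (_, _, k, s) in enumerate(self.conv_layers):
            if min(k) < 1 or min(s) < 1:
                raise ConfigError(f"conv layer {i}: kernel/stride entries must be >= 1")
        if self.n_frames < 1 or self.feature_dim < 1:
            raise ConfigError("n_frames and feature_dim must be >= 1")
        infer_flatten_dim(self)  # validates spatial sizes stay >= 1

    def to_dict(self) -> dict:
        return {
            "conv_layers": [[ci, co, list(k), list(s)] for ci, co, k, s in self.conv_layers],
            "n_frames": self.n_frames,
            "feature_dim": self.feature_dim,
        }


def infer_flatten_dim(config: VideoCriticConfig) -> int:
    """Size of the flattened conv output that feeds the final linear layer."""
    h, w = config.n_frames, config.feature_dim
    channels = 1
    for i, (ci, co, (kh, kw), (sh, sw)) in enumerate(config.conv_layers):
        try:
            h = conv_output_size(h, kh, sh)
            w = conv_output_size(w, kw, sw)
        except InputError as exc:
            raise ConfigError(f"conv layer {i} {(ci, co, (kh, kw), (sh, sw))}: {exc}") from exc
        channels = co
    return channels * h * w


class VideoCritic(nn.Module):
    """Conv stack + linear + sigmoid over a (1, n_frames, feature_dim) map."""

    def __init__(self, config: VideoCriticConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        self.convs = [
            nn.Conv2d(ci, co, k, rng, stride=s) for ci, co, k, s in config.conv_layers
        ]
        self.flatten_dim = infer_flatten_dim(config)
        self.fc = nn.Linear(self.flatten_dim, 1, rng, gain=1.0)

    def _check(self, fmap: Tensor):
        expected = (fmap.shape[0], 1, self.config.n_frames, self.config.feature_dim)
        if fmap.ndim != 4 or tuple(fmap.shape) != expected:
            raise InputError(
                f"feature map shape {tuple(fmap.shape)} does not match expected {expected}"
            )

    def logits(self, fmap) -> Tensor:
        fmap = fmap if isinstance(fmap, Tensor) else Tensor(fmap)
        self._check(fmap)
        h = fmap
        for conv in self.convs:
            h = ad.relu(conv(h))
        h = h.reshape(h.shape[0], self.flatten_dim)
        return self.fc(h)

    def __call__(self, fmap) -> Tensor:
        """Probability in (0, 1) that the clip is a real, correctly ordered video."""
        return ad.sigmoid(self.logits(fmap))


def video_critic_forward(critic: VideoCritic, fmap) -> Tensor:
    return critic(fmap)


def featurize_clip(frame_critic: Critic, clip: VideoClip, window) -> Tensor:
    """Stack frame-critic features of the windowed frames: (1, 1, n, F) map."""
    window = np.asarray(window, dtype=np.int64)
    if window.ndim != 1:
        raise InputError("window must be a 1-D sequence of frame indices")
    if window.min(initial=0) < 0 or window.max(initial=-1) >= clip.n_frames:
        raise InputError(
            f"window {window.tolist()} out of range for clip {clip.clip_id!r} "
            f"with {clip.n_frames} frames"
        )
    frames = np.transpose(clip.frames[window], (0, 3, 1, 2))  # (n, C, H, W)
    feats = extract_features(frame_critic, frames)  # (n, F)
    return feats.reshape(1, 1, len(window), feats.shape[1])


def featurize_frames(frame_critic: Critic, frames_nchw: Tensor, n_frames: int) -> Tensor:
    """Differentiable variant for generated batches: (B*n, C, H, W) -> (B, 1, n, F)."""
    feats = extract_features(frame_critic, frames_nchw)
    b = feats.shape[0] // n_frames
    return feats.reshape(b, 1, n_frames, feats.shape[1])
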