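"""Stage 2: adversarial training of the plugin against the video critic.

The frame generator and frame critic are frozen; only the plugin (playing
the generator role, through the frozen backbone) and the video critic are
updated.  Both sides use binary cross-entropy on the video critic's output
and Adam(lr=2e-4, beta1=0.5, beta2=0.999); the default run is 50 epochs.
The plugin's default loss is the non-saturating form (maximize log D(fake));
the saturating minimax form is available by configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .errors import ConfigError, InputError, NumericsError
from .frame_gan import Critic, Generator
from .plugin import Plugin, PluginConfig, plugin_forward
from .synthetic_video import VideoClip
from .video_critic import VideoCritic, VideoCriticConfig, featurize_clip, featurize_frames


@dataclass
class Stage2Config:
    learning_rate: float = 2e-4
    beta1: float = 0.5
    beta2: float = 0.999
    epochs: int = 50
    batch_clips: int = 8
    n_frames: int = 8
    generator_loss_form: str = "non_saturating"  # or "saturating"
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ConfigError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.epochs < 1:
            raise ConfigError(f"epochs must be >= 1, got {self.epochs}")
        if self.batch_clips < 1 or self.n_frames < 1:
            raise ConfigError("batch_clips and n_frames must be >= 1")
        if self.generator_loss_form not in ("non_saturating", "saturating"):
            raise ConfigError(f"unknown generator_loss_form {self.generator_loss_form!r}")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def bce_with_logits(logits: Tensor, target: float) -> Tensor:
    """Mean binary cross-entropy from raw logits (numerically stable)."""
    return (ad.softplus(logits) - logits * target).mean()


def sample_real_clip_batch(videos: Sequence[VideoClip], n_frames: int, batch_clips: int,
                           rng: np.random.Generator) -> list[VideoClip]:
    """Contiguous n-frame windows at uniform random starts of random videos."""
    for v in videos:
        if v.n_frames < n_frames:
            raise InputError(
                f"video {v.clip_id!r} has {v.n_frames} frames, fewer than n_frames={n_frames}"
            )
    batch = []
    for _ in range(batch_clips):
        v = videos[int(rng.integers(0, len(videos)))]
        start = int(rng.integers(0, v.n_frames - n_frames + 1))
        batch.append(v.window(start, n_frames))
    return batch


def _fake_feature_maps(plugin: Plugin, generator: Generator, frame_critic: Critic,
                       n_clips: int, n_frames: int, rng: np.random.Generator,
                       with_graph: bool = True) -> Tensor:
    """Generate n_clips fake clips (fresh z each) and featurize: (B, 1, n, F).

    With ``with_graph=False`` the latent trajectory is detached before the
    frozen backbone, so no backward graph is built (the discriminator update
    only needs fake samples, not their gradients).
    """
    timeline = np.arange(n_frames)
    trajs = [plugin_forward(plugin, rng.standard_normal(plugin.config.z_dim).astype(np.float32), timeline)
             for _ in range(n_clips)]
    latents = ad.concat(trajs, axis=0)  # (B*n, latent_dim)
    if not with_graph:
        latents = latents.detach()
    frames = generator(latents)  # (B*n, C, H, W)
    return featurize_frames(frame_critic, frames, n_frames)


def _real_feature_maps(frame_critic: Critic, real_batch: Sequence[VideoClip]) -> Tensor:
    maps = [featurize_clip(frame_critic, clip, np.arange(clip.n_frames)) for clip in real_batch]
    return ad.concat(maps, axis=0)


def stage2_step(plugin: Plugin, video_critic: VideoCritic, generator: Generator,
                frame_critic: Critic, real_batch: Sequence[VideoClip], config: Stage2Config,
                rng: np.random.Generator,
                opt_d: nn.Adam | None = None, opt_p: nn.Adam | None = None,
                real_fmaps: Tensor | None = None) -> dict:
    """One discriminator update followed by one plugin update.

    Without optimizers this only evaluates the two losses (no parameters
    change); with them it performs the updates.  Backbone parameters are
    never touched either way.  ``real_fmaps`` may carry precomputed real
    feature maps (the frame critic is frozen, so they are reusable).
    """
    n = config.n_frames
    # --- discriminator update ---
    fm_real = (_real_feature_maps(frame_critic, real_batch) if real_fmaps is None
               else real_fmaps).detach()
    batch = fm_real.shape[0]
    fm_fake = _fake_feature_maps(plugin, generator, frame_critic, batch, n, rng,
                                 with_graph=False).detach()
    logit_real = video_critic.logits(fm_real)
    logit_fake = video_critic.logits(fm_fake)
    loss_d = bce_with_logits(logit_real, 1.0) + bce_with_logits(logit_fake, 0.0)
    if opt_d is not None:
        opt_d.step(ad.grad(loss_d, video_critic.parameters()))
    # --- plugin update (fresh fakes) ---
    fm_fake2 = _fake_feature_maps(plugin, generator, frame_critic, batch, n, rng)
    logit_fake2 = video_critic.logits(fm_fake2)
    if config.generator_loss_form == "non_saturating":
        loss_p = bce_with_logits(logit_fake2, 1.0)
    else:
        loss_p = -bce_with_logits(logit_fake2, 0.0)
    if opt_p is not None:
        opt_p.step(ad.grad(loss_p, plugin.parameters()))
    rec = {
        "loss_D": float(loss_d),
        "loss_plugin": float(loss_p),
        "score_real": float(ad.sigmoid(logit_real).data.mean()),
        "score_fake": float(ad.sigmoid(logit_fake).data.mean()),
    }
    if not all(math.isfinite(v) for v in rec.values()):
        raise NumericsError(f"non-finite stage-2 losses: {rec}")
    return rec


def train_stage2(videos: Sequence[VideoClip], generator: Generator, frame_critic: Critic,
                 plugin_config: PluginConfig, video_critic_config: VideoCriticConfig,
                 config: Stage2Config) -> tuple[Plugin, VideoCritic, list[dict]]:
    """Full stage-2 run; the backbone is frozen and verified unchanged by hash."""
    if not videos:
        raise InputError("no training videos supplied")
    if not (generator.trained and frame_critic.trained):
        raise ConfigError("backbone must be trained before stage 2")
    if plugin_config.out_dim != generator.config.latent_dim:
        raise ConfigError(
            f"plugin out_dim {plugin_config.out_dim} != generator latent_dim "
            f"{generator.config.latent_dim}"
        )
    if video_critic_config.feature_dim != generator.config.feature_dim:
        raise ConfigError(
            f"video critic feature_dim {video_critic_config.feature_dim} != "
            f"frame critic feature width {generator.config.feature_dim}"
        )
    generator.frozen = True
    frame_critic.frozen = True
    generator.freeze()
    frame_critic.freeze()
    hash_before = generator.param_hash() + frame_critic.param_hash()

    rng = np.random.default_rng(config.seed)
    plugin = Plugin(plugin_config, seed=int(rng.integers(2**31)))
    vcritic = VideoCritic(video_critic_config, seed=int(rng.integers(2**31)))
    opt_d = nn.Adam(vcritic.parameters(), config.learning_rate, config.beta1, config.beta2)
    opt_p = nn.Adam(plugin.parameters(), config.learning_rate, config.beta1, config.beta2)

    # The frame critic is frozen, so every video's per-frame features can be
    # computed once up front; window feature maps are then cheap slices.
    from .frame_gan import extract_features

    feature_cache = []
    for v in videos:
        if v.n_frames < config.n_frames:
            raise InputError(
                f"video {v.clip_id!r} has {v.n_frames} frames, fewer than n_frames={config.n_frames}"
            )
        x = np.transpose(v.frames, (0, 3, 1, 2)).astype(np.float32)
        feature_cache.append(extract_features(frame_critic, x).data)

    steps_per_epoch = max(1, len(videos) // config.batch_clips)
    history: list[dict] = []
    for epoch in range(config.epochs):
        for step in range(steps_per_epoch):
            # mirrors sample_real_clip_batch, but reads the feature cache
            maps = []
            for _ in range(config.batch_clips):
                vi = int(rng.integers(0, len(videos)))
                start = int(rng.integers(0, videos[vi].n_frames - config.n_frames + 1))
                maps.append(feature_cache[vi][start : start + config.n_frames])
            fm_real = Tensor(np.stack(maps)[:, None, :, :])
            rec = stage2_step(plugin, vcritic, generator, frame_critic, [],
                              config, rng, opt_d, opt_p, real_fmaps=fm_real)
            rec.update(epoch=epoch, step=step)
            history.append(rec)
    hash_after = generator.param_hash() + frame_critic.param_hash()
    if hash_after != hash_before:
        raise NumericsError("backbone parameters changed during stage-2 training")
    return plugin, vcritic, history


def mean_score(video_critic: VideoCritic, frame_critic: Critic, clips: Sequence[VideoClip],
               window: np.ndarray | None = None) -> float:
    """Mean video-critic probability over clips (first n-frame window by default)."""
    n = video_critic.config.n_frames
    scores = []
    for clip in clips:
        w = np.arange(n) if window is None else window
        fm = featurize_clip(frame_critic, clip, w).detach()
        scores.append(video_critic(fm).data.item())
    return float(np.mean(scores))


def shuffle_frames(clip: VideoClip, rng: np.random.Generator) -> VideoClip:
    """Return the clip with its frames in random order (coherence control)."""
    perm = rng.permutation(clip.n_frames)
    return VideoClip(clip.frames[perm], clip.clip_id + "_shuffled", clip.frame_origin)
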