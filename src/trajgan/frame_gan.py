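"""Stage 1: progressive-growing frame generator and Wasserstein critic.

The generator starts at 4x4 and doubles resolution phase by phase; each new
block is faded in linearly (output = (1-alpha) * upsampled previous RGB +
alpha * new RGB).  The critic mirrors the generator and is trained with the
WGAN-GP objective.  After stage-1 training both networks are frozen; the
critic minus its final scalar layer then serves as the frame feature
extractor for the video discriminator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor
from .errors import ConfigError, InputError, NumericsError
from .synthetic_video import FrameDataset


def _resolutions(start: int, stop: int) -> list[int]:
    res, out = start, []
    while res <= stop:
        out.append(res)
        res *= 2
    return out


def default_channels(max_resolution: int, base: int = 512, cap: int = 512) -> dict[int, int]:
    """Reference-style channel schedule: wide at low res, halving above 32px."""
    sched = {}
    for r in _resolutions(4, max_resolution):
        sched[r] = int(min(cap, base * 32 // max(r, 32)))
    return sched


@dataclass
class FrameGANConfig:
    latent_dim: int = 512
    start_resolution: int = 4
    max_resolution: int = 128
    image_channels: int = 3
    channels_schedule: dict[int, int] = field(default_factory=dict)
    batch_schedule: dict[int, int] = field(default_factory=dict)
    feature_dim: int = 512  # critic penultimate width F
    gp_lambda: float = 10.0
    learning_rate: float = 1e-3
    beta1: float = 0.0
    beta2: float = 0.99
    steps_per_phase: int = 200
    fade_fraction: float = 0.5
    pixelnorm: bool = True
    equalized_lr: bool = True
    minibatch_stddev: bool = False
    drift_epsilon: float = 0.001

    def __post_init__(self):
        if self.start_resolution != 4:
            raise ConfigError(f"start_resolution must be 4, got {self.start_resolution}")
        r = self.max_resolution
        if r < 4 or (r & (r - 1)) != 0:
            raise ConfigError(f"max_resolution must be a power of two >= 4, got {r}")
        if not self.channels_schedule:
            self.channels_schedule = default_channels(self.max_resolution)
        self.channels_schedule = {int(k): int(v) for k, v in self.channels_schedule.items()}
        missing = [r for r in self.resolutions if r not in self.channels_schedule]
        if missing:
            raise ConfigError(f"channels_schedule missing resolutions {missing}")
        if not self.batch_schedule:
            self.batch_schedule = {r: (8 if r <= 256 else 4) for r in self.resolutions}
        self.batch_schedule = {int(k): int(v) for k, v in self.batch_schedule.items()}
        if any(b < 1 for b in self.batch_schedule.values()):
            raise ConfigError("batch sizes must be >= 1")
        if self.gp_lambda < 0:
            raise ConfigError(f"gp_lambda must be >= 0, got {self.gp_lambda}")
        if not (0 < self.fade_fraction <= 1):
            raise ConfigError(f"fade_fraction must be in (0, 1], got {self.fade_fraction}")
        if self.image_channels not in (1, 3):
            raise ConfigError(f"image_channels must be 1 or 3, got {self.image_channels}")

    @property
    def resolutions(self) -> list[int]:
        return _resolutions(self.start_resolution, self.max_resolution)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


class _GenBlock(nn.Module):
    def __init__(self, c_in, c_out, rng, eq):
        self.conv1 = nn.Conv2d(c_in, c_out, (3, 3), rng, padding=1, equalized=eq)
        self.conv2 = nn.Conv2d(c_out, c_out, (3, 3), rng, padding=1, equalized=eq)

    def __call__(self, x, use_pn: bool):
        x = ad.upsample_nearest2(x)
        x = ad.leaky_relu(self.conv1(x))
        if use_pn:
            x = nn.pixel_norm(x)
        x = ad.leaky_relu(self.conv2(x))
        if use_pn:
            x = nn.pixel_norm(x)
        return x


class Generator(nn.Module):
    """Progressive frame generator; output frames are tanh-bounded in [-1, 1]."""

    def __init__(self, config: FrameGANConfig, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.config = config
        cs = config.channels_schedule
        eq = config.equalized_lr
        c4 = cs[4]
        self.initial_fc = nn.Linear(config.latent_dim, c4 * 16, rng, equalized=eq)
        self.initial_conv = nn.Conv2d(c4, c4, (3, 3), rng, padding=1, equalized=eq)
        self.blocks = [
            _GenBlock(cs[r // 2], cs[r], rng, eq) for r in config.resolutions[1:]
        ]
        self.to_rgb = [
            nn.Conv2d(cs[r], config.image_channels, (1, 1), rng, equalized=eq, gain=1.0)
            for r in config.resolutions
        ]
        self.current_resolution = config.start_resolution
        self.alpha = 1.0
        self.frozen = False
        self.trained = False

    # -- phase control -------------------------------------------------------
    def set_phase(self, resolution: int, alpha: float) -> None:
        if resolution not in self.config.resolutions:
            raise ConfigError(f"resolution {resolution} not in schedule {self.config.resolutions}")
        if not (0.0 <= alpha <= 1.0):
            raise ConfigError(f"alpha must be in [0, 1], got {alpha}")
        if resolution == self.config.start_resolution and alpha != 1.0:
            raise ConfigError("no fade-in at the starting resolution")
        self.current_resolution = resolution
        self.alpha = float(alpha)

    def grow(self) -> None:
        """Advance to the next resolution, starting its fade-in at alpha=0."""
        self.set_phase(self.current_resolution * 2, 0.0)

    # -- forward -------------------------------------------------------------
    def __call__(self, z: Tensor) -> Tensor:
        z = z if isinstance(z, Tensor) else Tensor(z)
        if z.ndim != 2 or z.shape[1] != self.config.latent_dim:
            raise InputError(f"latent batch must be (B, {self.config.latent_dim}), got {z.shape}")
        cfg = self.config
        pn = cfg.pixelnorm
        x = nn.pixel_norm(z) if pn else z
        c4 = cfg.channels_schedule[4]
        h = ad.leaky_relu(self.initial_fc(x)).reshape(z.shape[0], c4, 4, 4)
        if pn:
            h = nn.pixel_norm(h)
        h = ad.leaky_relu(self.initial_conv(h))
        if pn:
            h = nn.pixel_norm(h)
        res_list = cfg.resolutions
        target = self.current_resolution
        idx = res_list.index(target)
        prev_h = h
        for i in range(idx):
            prev_h = h
            h = self.blocks[i](h, pn)
        rgb = ad.tanh(self.to_rgb[idx](h))
        if self.alpha < 1.0 and idx > 0:
            rgb_prev = ad.tanh(self.to_rgb[idx - 1](prev_h))
            rgb = ad.upsample_nearest2(rgb_prev) * (1.0 - self.alpha) + rgb * self.alpha
        return rgb


class _CriticBlock(nn.Module):
    def __init__(self, c_in, c_out, rng, eq):
        self.conv1 = nn.Conv2d(c_in, c_in, (3, 3), rng, padding=1, equalized=eq)
        self.conv2 = nn.Conv2d(c_in, c_out, (3, 3), rng, padding=1, equalized=eq)

    def __call__(self, x):
        x = ad.leaky_relu(self.conv1(x))
        x = ad.leaky_relu(self.conv2(x))
        return ad.avgpool2(x)


class Critic(nn.Module):
    """Progressive frame critic; its penultimate activations are the frame features."""

    def __init__(self, config: FrameGANConfig, seed: int = 0):
        rng = np.random.default_rng(seed + 1)
        self.config = config
        cs = config.channels_schedule
        eq = config.equalized_lr
        self.from_rgb = [
            nn.Conv2d(config.image_channels, cs[r], (1, 1), rng, equalized=eq)
            for r in config.resolutions
        ]
        self.blocks = [
            _CriticBlock(cs[r], cs[r // 2], rng, eq) for r in config.resolutions[1:]
        ]
        c4 = cs[4]
        extra = 1 if config.minibatch_stddev else 0
        self.final_conv = nn.Conv2d(c4 + extra, c4, (3, 3), rng, padding=1, equalized=eq)
        self.fc_features = nn.Linear(c4 * 16, config.feature_dim, rng, equalized=eq)
        self.fc_score = nn.Linear(config.feature_dim, 1, rng, equalized=eq, gain=1.0)
        self.current_resolution = config.start_resolution
        self.alpha = 1.0
        self.frozen = False
        self.trained = False

    def set_phase(self, resolution: int, alpha: float) -> None:
        if resolution not in self.config.resolutions:
            raise ConfigError(f"resolution {resolution} not in schedule {self.config.resolutions}")
        self.current_resolution = resolution
        self.alpha = float(alpha)

    def _trunk(self, x: Tensor) -> Tensor:
        cfg = self.config
        res_list = cfg.resolutions
        idx = res_list.index(self.current_resolution)
        if x.ndim != 4 or x.shape[2] != self.current_resolution or x.shape[3] != self.current_resolution:
            raise InputError(
                f"critic expects (B, {cfg.image_channels}, {self.current_resolution}, "
                f"{self.current_resolution}), got {x.shape}"
            )
        h = ad.leaky_relu(self.from_rgb[idx](x))
        if idx > 0:
            h = self.blocks[idx - 1](h)
            if self.alpha < 1.0:
                skip = ad.leaky_relu(self.from_rgb[idx - 1](ad.avgpool2(x)))
                h = skip * (1.0 - self.alpha) + h * self.alpha
            for i in range(idx - 2, -1, -1):
                h = self.blocks[i](h)
        if cfg.minibatch_stddev:
            h = nn.minibatch_stddev(h)
        h = ad.leaky_relu(self.final_conv(h))
        h = h.reshape(h.shape[0], cfg.channels_schedule[4] * 16)
        feats = ad.leaky_relu(self.fc_features(h))
        return feats

    def features(self, x: Tensor) -> Tensor:
        """Activations feeding the final scalar layer; the frame FeatureVector."""
        return self._trunk(x)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc_score(self._trunk(x))


def build_frame_generator(config: FrameGANConfig, seed: int = 0) -> Generator:
    return Generator(config, seed)


def build_frame_critic(config: FrameGANConfig, seed: int = 0) -> Critic:
    return Critic(config, seed)


def extract_features(critic: Critic, images) -> Tensor:
    """Frame features = critic activations just below its scalar output layer."""
    x = images if isinstance(images, Tensor) else Tensor(images)
    return critic.features(x)


# ---------------------------------------------------------------------------
# WGAN-GP losses
# ---------------------------------------------------------------------------

class WganGpLosses(NamedTuple):
    critic_loss: Tensor
    generator_loss: Tensor
    penalty: Tensor


def gradient_penalty(critic: Critic, real: np.ndarray, fake: np.ndarray,
                     gp_lambda: float, rng: np.random.Generator) -> Tensor:
    """lambda * E[(||grad_x critic(x_hat)|| - 1)^2] at random interpolates."""
    if real.shape != fake.shape:
        raise InputError(f"real/fake shape mismatch: {real.shape} vs {fake.shape}")
    if gp_lambda == 0:
        return Tensor(0.0)
    b = real.shape[0]
    u = rng.uniform(size=(b, 1, 1, 1)).astype(np.float32)
    xhat = Tensor(u * real + (1 - u) * fake, requires_grad=True)
    score = critic(xhat).sum()
    (gx,) = ad.grad(score, [xhat], create_graph=True)
    sq = (gx * gx).reshape(b, int(np.prod(real.shape[1:]))).sum(axis=1)
    norm = ad.sqrt(sq + 1e-12)
    return ((norm - 1.0) ** 2).mean() * gp_lambda


def wgan_gp_losses(critic: Critic, real_batch, fake_batch, gp_lambda: float,
                   seed: int | np.random.Generator = 0) -> WganGpLosses:
    """Wasserstein losses with gradient penalty.

    critic_loss = E[f(fake)] - E[f(real)] + penalty;  generator_loss = -E[f(fake)].
    """
    real = np.asarray(real_batch.data if isinstance(real_batch, Tensor) else real_batch, dtype=np.float32)
    fake_t = fake_batch if isinstance(fake_batch, Tensor) else Tensor(fake_batch)
    if real.shape != tuple(fake_t.shape):
        raise InputError(f"real/fake shape mismatch: {real.shape} vs {fake_t.shape}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    f_real = critic(Tensor(real)).mean()
    f_fake = critic(fake_t).mean()
    penalty = gradient_penalty(critic, real, fake_t.data, gp_lambda, rng)
    critic_loss = f_fake - f_real + penalty
    generator_loss = -f_fake
    return WganGpLosses(critic_loss, generator_loss, penalty)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def downsample_to(images_nchw: np.ndarray, resolution: int) -> np.ndarray:
    """Average-pool NCHW images down to ``resolution`` (a power-of-two factor)."""
    out = images_nchw
    while out.shape[-1] > resolution:
        n, c, h, w = out.shape
        out = out.reshape(n, c, h // 2, 2, w // 2, 2).mean(axis=(3, 5))
    return out.astype(np.float32)


def _phase_schedule(config: FrameGANConfig) -> list[tuple[int, str]]:
    phases = [(config.resolutions[0], "stable")]
    for r in config.resolutions[1:]:
        phases.append((r, "fade"))
        phases.append((r, "stable"))
    return phases


def train_frame_gan(dataset: FrameDataset, config: FrameGANConfig, seed: int = 0
                    ) -> tuple[Generator, Critic, list[dict]]:
    """Run the progressive phase schedule start -> max resolution.

    Returns trained (generator, critic, history); history is one record per
    step with losses, phase, alpha and batch size.
    """
    if len(dataset) == 0:
        raise InputError("training dataset is empty")
    images = np.transpose(dataset.images, (0, 3, 1, 2)).astype(np.float32)
    if images.shape[-1] != config.max_resolution:
        raise InputError(
            f"dataset frames are {images.shape[-1]}px but config.max_resolution is {config.max_resolution}"
        )
    rng = np.random.default_rng(seed)
    gen = Generator(config, seed=int(rng.integers(2**31)))
    critic = Critic(config, seed=int(rng.integers(2**31)))
    opt_g = nn.Adam(gen.parameters(), config.learning_rate, config.beta1, config.beta2)
    opt_d = nn.Adam(critic.parameters(), config.learning_rate, config.beta1, config.beta2)
    history: list[dict] = []
    pyramid = {r: downsample_to(images, r) for r in config.resolutions}
    step_global = 0
    for res, kind in _phase_schedule(config):
        batch = config.batch_schedule[res]
        data = pyramid[res]
        fade_steps = max(1, int(round(config.fade_fraction * config.steps_per_phase)))
        for step in range(config.steps_per_phase):
            alpha = min(1.0, (step + 1) / fade_steps) if kind == "fade" else 1.0
            gen.set_phase(res, alpha)
            critic.set_phase(res, alpha)
            idx = rng.integers(0, data.shape[0], size=batch)
            real = data[idx]
            # critic update
            z = rng.standard_normal((batch, config.latent_dim)).astype(np.float32)
            fake = gen(Tensor(z)).detach()
            losses = wgan_gp_losses(critic, real, fake, config.gp_lambda, rng)
            d_loss = losses.critic_loss
            if config.drift_epsilon > 0:
                d_loss = d_loss + config.drift_epsilon * (critic(Tensor(real)) ** 2).mean()
            d_grads = ad.grad(d_loss, critic.parameters())
            opt_d.step(d_grads)
            # generator update
            z2 = rng.standard_normal((batch, config.latent_dim)).astype(np.float32)
            fake2 = gen(Tensor(z2, requires_grad=False))
            g_loss = -critic(fake2).mean()
            g_grads = ad.grad(g_loss, gen.parameters())
            opt_g.step(g_grads)
            rec = {
                "step": step_global,
                "resolution": res,
                "phase": kind,
                "alpha": alpha,
                "batch_size": batch,
                "d_loss": float(d_loss),
                "g_loss": float(g_loss),
                "penalty": float(losses.penalty),
            }
            if not all(math.isfinite(v) for v in (rec["d_loss"], rec["g_loss"], rec["penalty"])):
                raise NumericsError(f"non-finite loss at step {step_global}: {rec}")
            history.append(rec)
            step_global += 1
    gen.set_phase(config.max_resolution, 1.0)
    critic.set_phase(config.max_resolution, 1.0)
    gen.trained = critic.trained = True
    return gen, critic, history
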