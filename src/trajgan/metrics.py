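"""Evaluation stack: Fréchet distances (FID/FVD), Inception Score, protocol.

Both FID and FVD are the Fréchet distance between Gaussians fitted to
embedded samples,

    d(A, B) = |mu_A - mu_B|^2 + Tr(S_A + S_B - 2 (S_A S_B)^{1/2}),

computed here through the symmetrized product sqrt(S_A)^T S_B sqrt(S_A)
(eigendecomposition with negative eigenvalues clipped at zero), which keeps
the whole computation real.  The Inception Score is
exp(E_x KL(p(y|x) || E_x p(y|x))) per split, natural log, reported as
mean +/- std over splits.

No pretrained Inception/I3D weights are bundled: embedders are pluggable.
The built-in choices are the frozen frame critic's features and a seeded
random projection, so the full evaluation runs offline; externally computed
feature matrices can be loaded from disk instead.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigError, InputError
from .frame_gan import Critic, Generator, extract_features
from .plugin import Plugin, generate_video
from .synthetic_video import VideoClip

# ---------------------------------------------------------------------------
# Gaussian summaries and the Fréchet distance
# ---------------------------------------------------------------------------


@dataclass
class GaussianSummary:
    mean: np.ndarray
    covariance: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.covariance = np.asarray(self.covariance, dtype=np.float64)
        f = self.mean.shape[0]
        if self.mean.ndim != 1 or self.covariance.shape != (f, f):
            raise InputError(
                f"inconsistent summary: mean {self.mean.shape}, cov {self.covariance.shape}"
            )
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
            raise InputError("covariance matrix is not symmetric within 1e-8")


def fit_gaussian(features: np.ndarray) -> GaussianSummary:
    """Sample mean and (N-1)-divisor covariance of an (N, F) feature matrix."""
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise InputError(f"fit_gaussian needs an (N>=2, F) matrix, got {x.shape}")
    mu = x.mean(axis=0)
    d = x - mu
    cov = d.T @ d / (x.shape[0] - 1)
    cov = (cov + cov.T) / 2.0
    return GaussianSummary(mu, cov)


def _psd_sqrt(mat: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((mat + mat.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    return (vecs * np.sqrt(vals)) @ vecs.T


def frechet_distance(a: GaussianSummary, b: GaussianSummary) -> float:
    """Fréchet distance between two Gaussian summaries (clamped at zero)."""
    if a.mean.shape != b.mean.shape:
        raise InputError(f"dimension mismatch: {a.mean.shape} vs {b.mean.shape}")
    sa = _psd_sqrt(a.covariance)
    inner = sa @ b.covariance @ sa
    vals = np.linalg.eigvalsh((inner + inner.T) / 2.0)
    tr_sqrt = np.sqrt(np.clip(vals, 0.0, None)).sum()
    diff = a.mean - b.mean
    d = float(diff @ diff + np.trace(a.covariance) + np.trace(b.covariance) - 2.0 * tr_sqrt)
    return max(d, 0.0)


# ---------------------------------------------------------------------------
# embedders
# ---------------------------------------------------------------------------


class Embedder:
    """Deterministic map from frames or clips to feature vectors.

    ``mode`` is "frame" (consumes (N, H, W, C) frames) or "clip" (consumes a
    list of clips).  Subclasses set ``name``, ``mode``, ``dim`` and implement
    ``_embed``.
    """

    name: str = "base"
    mode: str = "frame"
    dim: int = 0

    def __call__(self, batch) -> np.ndarray:
        out = np.asarray(self._embed(batch), dtype=np.float64)
        if out.ndim != 2 or out.shape[1] != self.dim:
            raise ConfigError(f"embedder {self.name} produced shape {out.shape}, expected (*, {self.dim})")
        return out

    def _embed(self, batch) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class CriticFrameEmbedder(Embedder):
    """Frame features from the frozen frame critic (the built-in FID embedder)."""

    def __init__(self, critic: Critic):
        self.critic = critic
        self.name = "critic_frames"
        self.mode = "frame"
        self.dim = critic.config.feature_dim

    def _embed(self, frames: np.ndarray) -> np.ndarray:
        x = np.transpose(np.asarray(frames, dtype=np.float32), (0, 3, 1, 2))
        chunks = [extract_features(self.critic, x[i : i + 64]).data for i in range(0, len(x), 64)]
        return np.concatenate(chunks, axis=0)


class CriticClipEmbedder(Embedder):
    """Clip embedding: frame features mean-pooled over time, augmented with the
    mean absolute temporal difference of consecutive frame features (so that
    frame order and motion statistics affect the embedding, as a video
    embedder's should)."""

    def __init__(self, critic: Critic, temporal_diff: bool = True):
        self.critic = critic
        self.temporal_diff = temporal_diff
        self.name = "critic_clips"
        self.mode = "clip"
        self.dim = critic.config.feature_dim * (2 if temporal_diff else 1)

    def _embed(self, clips: Sequence[VideoClip]) -> np.ndarray:
        out = []
        for clip in clips:
            x = np.transpose(clip.frames, (0, 3, 1, 2)).astype(np.float32)
            feats = extract_features(self.critic, x).data.astype(np.float64)
            emb = feats.mean(axis=0)
            if self.temporal_diff:
                if feats.shape[0] > 1:
                    diff = np.abs(np.diff(feats, axis=0)).mean(axis=0)
                else:
                    diff = np.zeros_like(emb)
                emb = np.concatenate([emb, diff])
            out.append(emb)
        return np.stack(out)


class RandomProjectionEmbedder(Embedder):
    """Seeded Gaussian projection of raw pixels; needs no trained weights."""

    def __init__(self, input_shape: tuple[int, int, int], dim: int = 64, seed: int = 0,
                 mode: str = "frame", temporal_diff: bool = True):
        if mode not in ("frame", "clip"):
            raise ConfigError(f"mode must be 'frame' or 'clip', got {mode!r}")
        self.input_shape = tuple(input_shape)
        self.seed = seed
        self.mode = mode
        self.temporal_diff = temporal_diff and mode == "clip"
        base_dim = dim if not self.temporal_diff else dim // 2
        n_in = int(np.prod(input_shape))
        rng = np.random.default_rng(seed)
        self.matrix = rng.standard_normal((n_in, base_dim)) / np.sqrt(n_in)
        self.dim = base_dim * (2 if self.temporal_diff else 1)
        self.name = f"random_projection_{mode}"

    def _project(self, frames: np.ndarray) -> np.ndarray:
        flat = np.asarray(frames, dtype=np.float64).reshape(len(frames), -1)
        if flat.shape[1] != self.matrix.shape[0]:
            raise InputError(
                f"embedder expects frames of shape {self.input_shape}, got {frames.shape[1:]}"
            )
        return flat @ self.matrix

    def _embed(self, batch) -> np.ndarray:
        if self.mode == "frame":
            return self._project(batch)
        out = []
        for clip in batch:
            proj = self._project(clip.frames)
            emb = proj.mean(axis=0)
            if self.temporal_diff:
                diff = np.abs(np.diff(proj, axis=0)).mean(axis=0) if len(proj) > 1 else np.zeros_like(emb)
                emb = np.concatenate([emb, diff])
            out.append(emb)
        return np.stack(out)


class FeatureFileEmbedder(Embedder):
    """Precomputed features from disk (e.g. an external Inception/I3D run).

    The file is a plain-text matrix (``np.savetxt`` format) with a JSON
    sidecar ``<file>.json`` recording the embedder name and mode; samples are
    matched by position, so the caller passes the same ordering it exported.
    """

    def __init__(self, path: str | Path):
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        self.features = np.loadtxt(path, ndmin=2)
        self.name = meta["name"]
        self.mode = meta["mode"]
        self.dim = self.features.shape[1]

    def _embed(self, batch) -> np.ndarray:
        n = len(batch)
        if n != self.features.shape[0]:
            raise InputError(
                f"feature file holds {self.features.shape[0]} rows but {n} samples were passed"
            )
        return self.features


def save_feature_file(path: str | Path, features: np.ndarray, name: str, mode: str) -> None:
    path = Path(path)
    np.savetxt(path, np.asarray(features, dtype=np.float64))
    path.with_suffix(path.suffix + ".json").write_text(json.dumps({"name": name, "mode": mode}))


# ---------------------------------------------------------------------------
# FID / FVD / IS
# ---------------------------------------------------------------------------


def fid(real_frames, fake_frames, embedder: Embedder) -> float:
    """Fréchet distance between embedded frame sets."""
    if embedder.mode != "frame":
        raise ConfigError(f"fid needs a frame-mode embedder, got {embedder.mode!r}")
    if len(real_frames) == 0 or len(fake_frames) == 0:
        raise InputError("fid requires non-empty frame sets")
    return frechet_distance(fit_gaussian(embedder(real_frames)), fit_gaussian(embedder(fake_frames)))


def fvd(real_clips, fake_clips, embedder: Embedder) -> float:
    """Fréchet distance between embedded clip sets."""
    if embedder.mode != "clip":
        raise ConfigError(f"fvd needs a clip-mode embedder, got {embedder.mode!r}")
    if len(real_clips) == 0 or len(fake_clips) == 0:
        raise InputError("fvd requires non-empty clip sets")
    return frechet_distance(fit_gaussian(embedder(real_clips)), fit_gaussian(embedder(fake_clips)))


def inception_score(probs: np.ndarray, n_splits: int = 5) -> tuple[float, float]:
    """exp(mean KL(p(y|x) || split marginal)) per split; (mean, std) over splits."""
    p = np.asarray(probs, dtype=np.float64)
    if p.ndim != 2:
        raise InputError(f"probs must be (N, K), got {p.shape}")
    if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
        raise InputError("probabilities must lie in [0, 1]")
    if not np.allclose(p.sum(axis=1), 1.0, atol=1e-8):
        raise InputError("probability rows must sum to 1 within 1e-8")
    if not (1 <= n_splits <= p.shape[0]):
        raise InputError(f"n_splits must be in [1, {p.shape[0]}], got {n_splits}")
    scores = []
    for part in np.array_split(p, n_splits):
        marginal = part.mean(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            logratio = np.where(part > 0, np.log(part) - np.log(marginal), 0.0)
        kl = (part * logratio).sum(axis=1)
        scores.append(np.exp(kl.mean()))
    return float(np.mean(scores)), float(np.std(scores))


class RandomSoftmaxHead:
    """Seeded linear-softmax class-probability head over raw pixels.

    Stands in for an external classifier so the Inception Score machinery is
    exercisable offline; it is a fixed random function, not a trained model.
    """

    def __init__(self, input_shape: tuple[int, int, int], n_classes: int = 8,
                 seed: int = 0, temperature: float = 4.0):
        n_in = int(np.prod(input_shape))
        rng = np.random.default_rng(seed)
        self.matrix = rng.standard_normal((n_in, n_classes)) / np.sqrt(n_in)
        self.temperature = temperature
        self.n_classes = n_classes
        self.input_shape = tuple(input_shape)

    def __call__(self, frames: np.ndarray) -> np.ndarray:
        flat = np.asarray(frames, dtype=np.float64).reshape(len(frames), -1)
        logits = self.temperature * (flat @ self.matrix)
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# evaluation protocol
# ---------------------------------------------------------------------------


def write_report_csv(reports: dict[str, dict], path: str | Path) -> Path:
    """Export evaluation reports as one CSV row per (dataset, method).

    ``reports`` maps a row label (e.g. "tunnel/trajgan") to a report dict from
    :func:`evaluation_protocol`; columns mirror the standard results-table
    shape (FVD, FID mean/std, IS fake and real mean/std).
    """
    import csv

    path = Path(path)
    fields = ["label", "FVD", "FID_mean", "FID_std",
              "IS_fake_mean", "IS_fake_std", "IS_real_mean", "IS_real_std"]
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        for label, rep in reports.items():
            writer.writerow({"label": label, **{k: rep[k] for k in fields[1:]}})
    return path


@dataclass
class EvaluationConfig:
    n_clips: int = 64
    clip_len: int = 16
    n_splits: int = 5
    seed: int = 0
    n_classes: int = 8

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def evaluation_protocol(generator: Generator, plugin: Plugin, frame_critic: Critic | None,
                        real_clips: Sequence[VideoClip], config: EvaluationConfig) -> dict:
    """Generate clips, compute FVD once and FID/IS as mean +/- std over splits.

    FVD compares whole clips; FID and IS pool every frame of every clip,
    randomly partition them into ``n_splits`` disjoint parts and report the
    per-part mean and standard deviation.
    """
    if not (generator.trained):
        raise ConfigError("generator must be trained before evaluation")
    if not real_clips:
        raise InputError("no real clips supplied")
    rng = np.random.default_rng(config.seed)
    timeline = np.arange(config.clip_len)
    fake_clips = []
    for i in range(config.n_clips):
        z = rng.standard_normal(plugin.config.z_dim).astype(np.float32)
        fake_clips.append(generate_video(plugin, generator, z, timeline,
                                         clip_id=f"fake_{i:05d}", require_frozen=False))
    res = generator.config.max_resolution
    shape = (res, res, generator.config.image_channels)
    if frame_critic is not None:
        frame_emb: Embedder = CriticFrameEmbedder(frame_critic)
        clip_emb: Embedder = CriticClipEmbedder(frame_critic)
    else:
        frame_emb = RandomProjectionEmbedder(shape, dim=64, seed=config.seed, mode="frame")
        clip_emb = RandomProjectionEmbedder(shape, dim=64, seed=config.seed, mode="clip")
    head = RandomSoftmaxHead(shape, n_classes=config.n_classes, seed=config.seed)

    fvd_value = fvd(list(real_clips), fake_clips, clip_emb)

    real_frames = np.concatenate([c.frames for c in real_clips], axis=0)
    fake_frames = np.concatenate([c.frames for c in fake_clips], axis=0)
    real_frames = real_frames[rng.permutation(len(real_frames))]
    fake_frames = fake_frames[rng.permutation(len(fake_frames))]

    fids, is_fake, is_real = [], [], []
    for rpart, fpart in zip(np.array_split(real_frames, config.n_splits),
                            np.array_split(fake_frames, config.n_splits)):
        fids.append(fid(rpart, fpart, frame_emb))
        is_fake.append(inception_score(head(fpart), 1)[0])
        is_real.append(inception_score(head(rpart), 1)[0])
    report = {
        "FVD": fvd_value,
        "FID_mean": float(np.mean(fids)),
        "FID_std": float(np.std(fids)),
        "IS_fake_mean": float(np.mean(is_fake)),
        "IS_fake_std": float(np.std(is_fake)),
        "IS_real_mean": float(np.mean(is_real)),
        "IS_real_std": float(np.std(is_real)),
        "n_clips": config.n_clips,
        "clip_len": config.clip_len,
        "n_splits": config.n_splits,
        "seed": config.seed,
        "embedder": frame_emb.name,
    }
    return report
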