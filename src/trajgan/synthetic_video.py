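"""Seeded synthetic video datasets and PNG frame-directory I/O.

Two scene families are provided, chosen so that clips have the temporal
coherence (adjacent frames more alike than random frame pairs) a video
generator is supposed to learn:

* ``moving_shapes`` — a handful of textured discs and squares drifting over a
  smooth background, bouncing off the frame edges (a stand-in for generic
  action-video footage);
* ``tunnel`` — a camera flying slowly through a reddish tube with receding
  concentric rings and radial texture, emulating the look and motion of
  endoscopic (colonoscopy) video: dark lumen in the centre, textured walls,
  slow drift of the viewing axis.

Frames are float arrays in ``[-1, 1]`` (matching a tanh-output generator);
PNG round trips quantize to 8 bits.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

from .errors import ConfigError, FormatError, InputError

_FRAME_RE = re.compile(r"^frame_(\d{5})\.png$")


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic scene family."""

    kind: str = "moving_shapes"  # or "tunnel"
    resolution: int = 32
    n_frames: int = 16
    motion_amplitude: float = 2.0  # pixels of apparent motion per frame
    texture_detail: int = 3
    channels: int = 3

    def __post_init__(self):
        if self.kind not in ("moving_shapes", "tunnel"):
            raise ConfigError(f"SceneSpec.kind must be 'moving_shapes' or 'tunnel', got {self.kind!r}")
        if not isinstance(self.resolution, int) or not _is_power_of_two(self.resolution) or self.resolution < 8:
            raise ConfigError(f"SceneSpec.resolution must be a power of two >= 8, got {self.resolution!r}")
        if not isinstance(self.n_frames, int) or self.n_frames < 1:
            raise ConfigError(f"SceneSpec.n_frames must be a positive integer, got {self.n_frames!r}")
        if not math.isfinite(self.motion_amplitude) or self.motion_amplitude < 0:
            raise ConfigError(f"SceneSpec.motion_amplitude must be finite and >= 0, got {self.motion_amplitude!r}")
        if not isinstance(self.texture_detail, int) or self.texture_detail < 0:
            raise ConfigError(f"SceneSpec.texture_detail must be a nonnegative integer, got {self.texture_detail!r}")
        if self.channels not in (1, 3):
            raise ConfigError(f"SceneSpec.channels must be 1 or 3, got {self.channels!r}")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "resolution": self.resolution,
            "n_frames": self.n_frames,
            "motion_amplitude": self.motion_amplitude,
            "texture_detail": self.texture_detail,
            "channels": self.channels,
        }


@dataclass
class VideoClip:
    """An ordered stack of same-shape frames with values in [-1, 1]."""

    frames: np.ndarray  # (n_frames, H, W, C) float32
    clip_id: str
    frame_origin: int = 0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float32)
        if self.frames.ndim != 4:
            raise InputError(f"clip {self.clip_id!r}: frames must be (n, H, W, C), got {self.frames.shape}")
        if np.abs(self.frames).max(initial=0.0) > 1.0 + 1e-6:
            raise InputError(f"clip {self.clip_id!r}: frame values outside [-1, 1]")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def resolution(self) -> int:
        return self.frames.shape[1]

    def window(self, start: int, length: int) -> "VideoClip":
        if start < 0 or start + length > self.n_frames:
            raise InputError(
                f"clip {self.clip_id!r}: window [{start}, {start + length}) outside 0..{self.n_frames}"
            )
        return VideoClip(self.frames[start : start + length], self.clip_id, self.frame_origin + start)


@dataclass
class FrameDataset:
    """Individual frames flattened from a clip collection (stage-1 input)."""

    images: np.ndarray  # (N, H, W, C)
    index: list[tuple[str, int]] = field(default_factory=list)

    @classmethod
    def from_clips(cls, clips: Sequence[VideoClip]) -> "FrameDataset":
        if not clips:
            raise InputError("FrameDataset requires at least one clip")
        shapes = {c.frames.shape[1:] for c in clips}
        if len(shapes) != 1:
            raise InputError(f"clips have mixed frame shapes: {sorted(shapes)}")
        images = np.concatenate([c.frames for c in clips], axis=0)
        index = [(c.clip_id, c.frame_origin + i) for c in clips for i in range(c.n_frames)]
        if len(set(index)) != len(index):
            raise InputError("duplicate (clip_id, frame_index) pairs in dataset")
        return cls(images, index)

    def __len__(self) -> int:
        return self.images.shape[0]


# ---------------------------------------------------------------------------
# scene generators
# ---------------------------------------------------------------------------

def _background(res: int, detail: int, rng: np.random.Generator, channels: int) -> np.ndarray:
    """Smooth low-frequency background in [-0.6, 0.6]."""
    yy, xx = np.mgrid[0:res, 0:res] / res
    bg = np.zeros((res, res), dtype=np.float64)
    for k in range(1, max(detail, 1) + 1):
        ax, ay, ph = rng.uniform(-1, 1), rng.uniform(-1, 1), rng.uniform(0, 2 * np.pi)
        bg += (0.5 / k) * np.sin(2 * np.pi * k * (ax * xx + ay * yy) + ph)
    bg = 0.6 * bg / max(np.abs(bg).max(), 1e-9)
    out = np.repeat(bg[:, :, None], channels, axis=2)
    if channels == 3:
        out *= rng.uniform(0.7, 1.0, size=3)
    return out


def generate_moving_shapes(spec: SceneSpec, n_clips: int, seed: int) -> list[VideoClip]:
    """Clips of textured discs/squares translating with reflecting boundaries."""
    if n_clips < 0:
        raise InputError(f"n_clips must be >= 0, got {n_clips}")
    rng = np.random.default_rng(seed)
    res, n, c = spec.resolution, spec.n_frames, spec.channels
    yy, xx = np.mgrid[0:res, 0:res].astype(np.float64)
    clips = []
    for ci in range(n_clips):
        bg = _background(res, spec.texture_detail, rng, c)
        n_shapes = int(rng.integers(2, 4))
        pos = rng.uniform(res * 0.2, res * 0.8, size=(n_shapes, 2))
        theta = rng.uniform(0, 2 * np.pi, size=n_shapes)
        vel = spec.motion_amplitude * np.stack([np.cos(theta), np.sin(theta)], axis=1)
        radius = rng.uniform(res * 0.08, res * 0.18, size=n_shapes)
        color = rng.uniform(-1, 1, size=(n_shapes, c))
        square = rng.random(n_shapes) < 0.5
        frames = np.empty((n, res, res, c), dtype=np.float32)
        for t in range(n):
            img = bg.copy()
            for s in range(n_shapes):
                cy, cx = pos[s]
                if square[s]:
                    mask = (np.abs(yy - cy) < radius[s]) & (np.abs(xx - cx) < radius[s])
                else:
                    mask = (yy - cy) ** 2 + (xx - cx) ** 2 < radius[s] ** 2
                img[mask] = 0.5 * img[mask] + 0.5 * color[s]
            frames[t] = np.clip(img, -1.0, 1.0)
            # advance with reflecting boundaries
            pos += vel
            for s in range(n_shapes):
                for d in range(2):
                    if pos[s, d] < 0:
                        pos[s, d] = -pos[s, d]
                        vel[s, d] = -vel[s, d]
                    elif pos[s, d] > res - 1:
                        pos[s, d] = 2 * (res - 1) - pos[s, d]
                        vel[s, d] = -vel[s, d]
        clips.append(VideoClip(frames, f"shapes_{ci:04d}"))
    return clips


def generate_tunnel(spec: SceneSpec, n_clips: int, seed: int) -> list[VideoClip]:
    """Fly-through of a textured tube: receding rings, radial texture, drift."""
    if n_clips < 0:
        raise InputError(f"n_clips must be >= 0, got {n_clips}")
    rng = np.random.default_rng(seed)
    res, n, c = spec.resolution, spec.n_frames, spec.channels
    yy, xx = (np.mgrid[0:res, 0:res] / (res - 1)) * 2 - 1  # [-1, 1] coords
    tint = np.array([1.0, 0.55, 0.45])[:c] if c == 3 else np.array([1.0])
    clips = []
    for ci in range(n_clips):
        phase0 = rng.uniform(0, 2 * np.pi)
        speed = 0.15 * spec.motion_amplitude + 0.05
        drift_dir = rng.uniform(0, 2 * np.pi)
        drift = 0.004 * spec.motion_amplitude
        ring_freq = rng.uniform(2.5, 3.5)
        ang_phase = rng.uniform(0, 2 * np.pi)
        frames = np.empty((n, res, res, c), dtype=np.float32)
        for t in range(n):
            cx = 0.15 * np.cos(drift_dir) * np.sin(0.3 * t * drift * 50)
            cy = 0.15 * np.sin(drift_dir) * np.sin(0.3 * t * drift * 50)
            r = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2) + 1e-3
            ang = np.arctan2(yy - cy, xx - cx)
            # rings recede toward the viewer: phase advances with t
            rings = 0.35 * np.sin(ring_freq * np.log(r) * 2.5 - (phase0 + speed * t) * 2 * np.pi / 4)
            folds = 0.0
            for k in range(1, spec.texture_detail + 1):
                folds += (0.18 / k) * np.sin((3 + 2 * k) * ang + ang_phase + 0.15 * t * speed)
            wall = np.tanh(2.2 * r) * 1.4 - 0.9  # dark lumen centre, bright walls
            base = np.clip(wall + rings + folds, -1.0, 1.0)
            img = base[:, :, None] * tint[None, None, :]
            frames[t] = np.clip(img, -1.0, 1.0).astype(np.float32)
        clips.append(VideoClip(frames, f"tunnel_{ci:04d}"))
    return clips


def generate(spec: SceneSpec, n_clips: int, seed: int) -> list[VideoClip]:
    if spec.kind == "moving_shapes":
        return generate_moving_shapes(spec, n_clips, seed)
    return generate_tunnel(spec, n_clips, seed)


def iid_noise_clips(spec: SceneSpec, n_clips: int, seed: int) -> list[VideoClip]:
    """Temporally incoherent control clips: every frame is fresh uniform noise."""
    rng = np.random.default_rng(seed)
    res, n, c = spec.resolution, spec.n_frames, spec.channels
    return [
        VideoClip(rng.uniform(-1, 1, size=(n, res, res, c)).astype(np.float32), f"noise_{ci:04d}")
        for ci in range(n_clips)
    ]


# ---------------------------------------------------------------------------
# temporal coherence
# ---------------------------------------------------------------------------

def temporal_coherence_score(clip: VideoClip, seed: int = 0) -> float:
    """Adjacent-frame mean |Δ| divided by that of random non-adjacent pairs.

    Values below 1 indicate temporal coherence.  A clip of identical frames
    yields the defined value 1.0 (the 0/0 convention).
    """
    n = clip.n_frames
    if n < 3:
        raise InputError(f"temporal_coherence_score needs >= 3 frames, got {n}")
    f = clip.frames.astype(np.float64)
    adj = np.mean([np.abs(f[i + 1] - f[i]).mean() for i in range(n - 1)])
    rng = np.random.default_rng(seed)
    pairs = []
    while len(pairs) < n - 1:
        i, j = rng.integers(0, n, size=2)
        if abs(int(i) - int(j)) >= 2:
            pairs.append((int(i), int(j)))
    far = np.mean([np.abs(f[i] - f[j]).mean() for i, j in pairs])
    if far == 0.0:
        return 1.0 if adj == 0.0 else float("inf")
    return float(adj / far)


# ---------------------------------------------------------------------------
# PNG frame-directory I/O
# ---------------------------------------------------------------------------

def _to_uint8(frame: np.ndarray) -> np.ndarray:
    # linear [-1, 1] -> [0, 255]; np.round is round-half-even
    return np.round((frame.astype(np.float64) + 1.0) * (255.0 / 2.0)).clip(0, 255).astype(np.uint8)


def _from_uint8(arr: np.ndarray) -> np.ndarray:
    return (arr.astype(np.float32) * (2.0 / 255.0) - 1.0).astype(np.float32)


def write_frame_dir(clips: Iterable[VideoClip], path: str | Path, manifest_extra: dict | None = None) -> Path:
    """Write clips as ``<clip_id>/frame_XXXXX.png`` plus a ``dataset.json`` manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for clip in clips:
        cdir = path / clip.clip_id
        cdir.mkdir(parents=True, exist_ok=True)
        for i in range(clip.n_frames):
            arr = _to_uint8(clip.frames[i])
            if arr.shape[2] == 1:
                img = Image.fromarray(arr[:, :, 0], mode="L")
            else:
                img = Image.fromarray(arr, mode="RGB")
            img.save(cdir / f"frame_{i:05d}.png")
        entries.append(
            {
                "clip_id": clip.clip_id,
                "n_frames": clip.n_frames,
                "resolution": clip.resolution,
                "channels": int(clip.frames.shape[3]),
            }
        )
    manifest = {"clips": entries}
    if manifest_extra:
        manifest.update(manifest_extra)
    (path / "dataset.json").write_text(json.dumps(manifest, indent=2))
    return path


def read_frame_dir(path: str | Path) -> list[VideoClip]:
    """Read a frame directory written by :func:`write_frame_dir`.

    Clip folders are taken in lexicographic order; frame order comes from the
    zero-padded file names, never from filesystem enumeration order.
    """
    path = Path(path)
    if not path.is_dir():
        raise FormatError(f"not a directory: {path}")
    clips = []
    for cdir in sorted(p for p in path.iterdir() if p.is_dir()):
        pngs = sorted(cdir.glob("*.png"))
        if not pngs:
            continue
        bad = [p.name for p in pngs if not _FRAME_RE.match(p.name)]
        if bad:
            raise FormatError(f"malformed frame names in {cdir}: {bad}")
        arrays = []
        for p in pngs:
            arr = np.asarray(Image.open(p))
            if arr.ndim == 2:
                arr = arr[:, :, None]
            arrays.append(_from_uint8(arr))
        shapes = {a.shape for a in arrays}
        if len(shapes) != 1:
            raise FormatError(f"mixed frame shapes in {cdir}: {sorted(shapes)}")
        clips.append(VideoClip(np.stack(arrays), cdir.name))
    return clips
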