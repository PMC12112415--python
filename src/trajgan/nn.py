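"""Layers, modules and the Adam optimizer used by both training stages.

Parameters are plain :class:`~trajgan.autodiff.Tensor` leaves; a module tree
exposes them recursively so optimizers and checkpoints can address every
parameter by a dotted path.
"""

from __future__ import annotations

import math
from typing import Iterator

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: children are discovered from instance attributes."""

    def _children(self) -> Iterator[tuple[str, "Module"]]:
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def _named_tensors(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, val in vars(self).items():
            if isinstance(val, Tensor):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child._named_tensors(prefix + cname + ".")

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self._named_tensors()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        flat = dict(self._named_tensors())
        if set(state) != set(flat):
            missing = set(flat) - set(state)
            extra = set(state) - set(flat)
            raise ValueError(f"state dict mismatch: missing={sorted(missing)} unexpected={sorted(extra)}")
        for key, arr in state.items():
            tensor = flat[key]
            arr = np.asarray(arr, dtype=ad.DTYPE)
            if tensor.data.shape != arr.shape:
                raise ValueError(f"shape mismatch for {key}: {tensor.data.shape} vs {arr.shape}")
            tensor.data = arr.copy()

    def freeze(self) -> None:
        for p in self.parameters():
            p.requires_grad = False

    def param_hash(self) -> str:
        """Order-stable SHA-256 digest of all parameter bytes."""
        import hashlib

        h = hashlib.sha256()
        state = self.state_dict()
        for key in sorted(state):
            h.update(key.encode())
            h.update(np.ascontiguousarray(state[key]).tobytes())
        return h.hexdigest()


class Linear(Module):
    """Fully connected layer, optionally with ProGAN equalized learning rate.

    With ``equalized=True`` weights are stored unit-variance and scaled by
    ``sqrt(2/fan_in)`` at run time; otherwise they are drawn at that scale
    directly (times ``init_scale``).
    """

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 equalized: bool = False, init_scale: float = 1.0, gain: float = 2.0):
        self.in_dim, self.out_dim = in_dim, out_dim
        self.equalized = equalized
        self.scale = math.sqrt(gain / in_dim)
        if equalized:
            w = rng.standard_normal((out_dim, in_dim))
        else:
            w = rng.standard_normal((out_dim, in_dim)) * self.scale * init_scale
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        w = self.weight * self.scale if self.equalized else self.weight
        return x @ w.T + self.bias


class Conv2d(Module):
    """Valid-mode convolution (optional symmetric zero padding), NCHW."""

    def __init__(self, in_ch: int, out_ch: int, kernel: tuple[int, int], rng: np.random.Generator,
                 stride: tuple[int, int] = (1, 1), padding: int = 0,
                 equalized: bool = False, init_scale: float = 1.0, gain: float = 2.0):
        kh, kw = kernel
        self.stride, self.padding = tuple(stride), padding
        fan_in = in_ch * kh * kw
        self.scale = math.sqrt(gain / fan_in)
        self.equalized = equalized
        if equalized:
            w = rng.standard_normal((out_ch, in_ch, kh, kw))
        else:
            w = rng.standard_normal((out_ch, in_ch, kh, kw)) * self.scale * init_scale
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        w = self.weight * self.scale if self.equalized else self.weight
        return ad.conv2d(x, w, self.bias, stride=self.stride, padding=self.padding)


def pixel_norm(x: Tensor, eps: float = 1e-8) -> Tensor:
    """Normalize each pixel's channel vector to unit average square."""
    return x * ad.pow_const((x * x).mean(axis=1, keepdims=True) + eps, -0.5)


def minibatch_stddev(x: Tensor) -> Tensor:
    """Append one feature map holding the batch-wide mean feature stddev."""
    mu = x.mean(axis=0, keepdims=True)
    var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
    sd = ad.sqrt(var + 1e-8).mean()
    n, _, h, w = x.shape
    extra = ad.broadcast_to(sd.reshape(1, 1, 1, 1), (n, 1, h, w))
    return ad.concat([x, extra], axis=1)


class Adam:
    """Adam with bias correction, operating on raw parameter arrays."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, grads: list[Tensor]) -> None:
        if len(grads) != len(self.params):
            raise ValueError("gradient list does not match parameter list")
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data
            m *= self.b1
            m += (1 - self.b1) * gd
            v *= self.b2
            v += (1 - self.b2) * gd * gd
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t, "m": [m.copy() for m in self.m], "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(m).copy() for m in state["m"]]
        self.v = [np.asarray(v).copy() for v in state["v"]]
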