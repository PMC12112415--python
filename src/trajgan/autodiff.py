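"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The package trains small adversarial networks on CPU, and the Wasserstein
critic's gradient penalty differentiates a loss that itself contains an input
gradient.  Every primitive here therefore expresses its vector-Jacobian
product through the same primitives, so the output of :func:`grad` carries its
own computation graph and can be differentiated again (double backprop).

Only the operations the networks in this package need are provided; this is
not a general tensor library.  All data is held as ``float32``.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np

DTYPE = np.float32


class Tensor:
    """A NumPy array with an optional backward graph.

    Construct leaf tensors with ``Tensor(data, requires_grad=True)`` for
    trainable parameters; all arithmetic produces internal nodes.
    """

    __slots__ = ("data", "requires_grad", "_parents", "_vjp")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        _parents: tuple = (),
        _vjp: Callable | None = None,
    ):
        self.data = np.asarray(data, dtype=DTYPE)
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._vjp = _vjp

    # -- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def __float__(self):
        return float(self.data)

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    # -- operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __neg__(self):
        return neg(self)

    def __sub__(self, other):
        return add(self, neg(_wrap(other)))

    def __rsub__(self, other):
        return add(_wrap(other), neg(self))

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _wrap(other)
        return mul(self, pow_const(other, -1.0))

    def __rtruediv__(self, other):
        return mul(_wrap(other), pow_const(self, -1.0))

    def __pow__(self, p):
        return pow_const(self, float(p))

    def __matmul__(self, other):
        return matmul(self, _wrap(other))

    def __getitem__(self, key):
        return getitem(self, key)

    # -- reductions / shaping ------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return reshape(self, shape)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        if not axes:
            axes = tuple(range(self.ndim))[::-1]
        return transpose(self, axes)

    @property
    def T(self):
        return self.transpose()


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents: Sequence[Tensor], vjp: Callable) -> Tensor:
    """Create an internal graph node; constant-fold if no parent needs grad."""
    if any(p.requires_grad for p in parents):
        t = Tensor(data, requires_grad=True, _parents=tuple(parents), _vjp=vjp)
        return t
    return Tensor(data)


# ---------------------------------------------------------------------------
# broadcasting helpers
# ---------------------------------------------------------------------------

def _sum_to(g: Tensor, shape: tuple) -> Tensor:
    """Reduce a broadcast gradient back down to ``shape``."""
    while g.ndim > len(shape):
        g = sum_(g, axis=0)
    axes = tuple(i for i, (gs, s) in enumerate(zip(g.shape, shape)) if s == 1 and gs != 1)
    if axes:
        g = sum_(g, axis=axes, keepdims=True)
    return g


def broadcast_to(x: Tensor, shape: tuple) -> Tensor:
    x = _wrap(x)
    if x.shape == tuple(shape):
        return x
    out = np.broadcast_to(x.data, shape)
    return _node(np.ascontiguousarray(out), (x,), lambda g: (_sum_to(g, x.shape),))


# ---------------------------------------------------------------------------
# arithmetic primitives
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    return _node(a.data + b.data, (a, b), lambda g: (_sum_to(g, a.shape), _sum_to(g, b.shape)))


def neg(a: Tensor) -> Tensor:
    return _node(-a.data, (a,), lambda g: (neg(g),))


def mul(a: Tensor, b: Tensor) -> Tensor:
    return _node(a.data * b.data, (a, b), lambda g: (_sum_to(mul(g, b), a.shape), _sum_to(mul(g, a), b.shape)))


def pow_const(a: Tensor, p: float) -> Tensor:
    return _node(a.data ** p, (a,), lambda g: (mul(g, mul(Tensor(p), pow_const(a, p - 1.0))),))


def exp(a: Tensor) -> Tensor:
    out = _node(np.exp(a.data), (a,), None)
    if out.requires_grad:
        out._vjp = lambda g: (mul(g, out),)
    return out


def log(a: Tensor) -> Tensor:
    return _node(np.log(a.data), (a,), lambda g: (mul(g, pow_const(a, -1.0)),))


def sqrt(a: Tensor) -> Tensor:
    out = _node(np.sqrt(a.data), (a,), None)
    if out.requires_grad:
        out._vjp = lambda g: (mul(g, mul(Tensor(0.5), pow_const(out, -1.0))),)
    return out


def tanh(a: Tensor) -> Tensor:
    out = _node(np.tanh(a.data), (a,), None)
    if out.requires_grad:
        out._vjp = lambda g: (mul(g, add(Tensor(1.0), neg(mul(out, out)))),)
    return out


def sigmoid(a: Tensor) -> Tensor:
    with np.errstate(over="ignore", invalid="ignore"):
        s = np.where(a.data >= 0, 1.0 / (1.0 + np.exp(-a.data)), np.exp(a.data) / (1.0 + np.exp(a.data)))
    # keep the output strictly inside (0, 1) at float32 precision
    s = np.clip(np.nan_to_num(s, nan=1.0), np.float32(1e-38), np.float32(1.0) - np.float32(2.0) ** -24)
    out = _node(s.astype(DTYPE), (a,), None)
    if out.requires_grad:
        out._vjp = lambda g: (mul(g, mul(out, add(Tensor(1.0), neg(out)))),)
    return out


def softplus(a: Tensor) -> Tensor:
    """log(1 + exp(x)), overflow-safe."""
    return _node(np.logaddexp(0.0, a.data).astype(DTYPE), (a,), lambda g: (mul(g, sigmoid(a)),))


def relu(a: Tensor) -> Tensor:
    mask = (a.data > 0).astype(DTYPE)
    return _node(a.data * mask, (a,), lambda g: (mul(g, Tensor(mask)),))


def leaky_relu(a: Tensor, alpha: float = 0.2) -> Tensor:
    slope = np.where(a.data > 0, 1.0, alpha).astype(DTYPE)
    return _node(a.data * slope, (a,), lambda g: (mul(g, Tensor(slope)),))


def clip_min_const(a: Tensor, c: float) -> Tensor:
    """max(x, c) against a scalar constant (subgradient 0 at the kink)."""
    mask = (a.data > c).astype(DTYPE)
    return _node(np.maximum(a.data, c), (a,), lambda g: (mul(g, Tensor(mask)),))


# ---------------------------------------------------------------------------
# linear algebra / shaping
# ---------------------------------------------------------------------------

def matmul(a: Tensor, b: Tensor) -> Tensor:
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError(f"matmul supports 2-D operands only, got {a.shape} @ {b.shape}")
    return _node(a.data @ b.data, (a, b), lambda g: (matmul(g, transpose(b, (1, 0))), matmul(transpose(a, (1, 0)), g)))


def sum_(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        axes = tuple(range(a.ndim))
    elif isinstance(axis, int):
        axes = (axis % a.ndim,)
    else:
        axes = tuple(ax % a.ndim for ax in axis)
    out_data = a.data.sum(axis=axes if axes else None, keepdims=keepdims)

    def vjp(g):
        if not keepdims:
            kshape = tuple(1 if i in axes else s for i, s in enumerate(a.shape))
            g = reshape(g, kshape)
        return (broadcast_to(g, a.shape),)

    return _node(out_data, (a,), vjp)


def mean(a: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = a.size
    elif isinstance(axis, int):
        n = a.shape[axis % a.ndim]
    else:
        n = int(np.prod([a.shape[ax % a.ndim] for ax in axis]))
    return mul(sum_(a, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def reshape(a: Tensor, shape: tuple) -> Tensor:
    return _node(a.data.reshape(shape), (a,), lambda g: (reshape(g, a.shape),))


def transpose(a: Tensor, axes: tuple) -> Tensor:
    inv = tuple(np.argsort(axes))
    return _node(a.data.transpose(axes), (a,), lambda g: (transpose(g, inv),))


def getitem(a: Tensor, key) -> Tensor:
    return _node(a.data[key], (a,), lambda g: (_scatter(g, key, a.shape),))


def _scatter(g: Tensor, key, shape: tuple) -> Tensor:
    out = np.zeros(shape, dtype=DTYPE)
    np.add.at(out, key, g.data)
    return _node(out, (g,), lambda gg: (getitem(gg, key),))


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    axis = axis % tensors[0].ndim
    out = np.concatenate([t.data for t in tensors], axis=axis)
    offsets = np.cumsum([0] + [t.shape[axis] for t in tensors])

    def vjp(g):
        grads = []
        for t, start, stop in zip(tensors, offsets[:-1], offsets[1:]):
            key = tuple(slice(None) for _ in range(axis)) + (slice(int(start), int(stop)),)
            grads.append(getitem(g, key))
        return tuple(grads)

    return _node(out, tuple(tensors), vjp)


def pad2d(a: Tensor, pad: int) -> Tensor:
    """Zero-pad the trailing two axes symmetrically by ``pad`` pixels."""
    if pad == 0:
        return a
    width = [(0, 0)] * (a.ndim - 2) + [(pad, pad), (pad, pad)]
    out = np.pad(a.data, width)
    key = tuple(slice(None) for _ in range(a.ndim - 2)) + (
        slice(pad, pad + a.shape[-2]),
        slice(pad, pad + a.shape[-1]),
    )
    return _node(out, (a,), lambda g: (getitem(g, key),))


# ---------------------------------------------------------------------------
# image-specific primitives (NCHW)
# ---------------------------------------------------------------------------

def _conv_geometry(h, w, kh, kw, sh, sw):
    ho = (h - kh) // sh + 1
    wo = (w - kw) // sw + 1
    return ho, wo


def unfold(a: Tensor, kh: int, kw: int, sh: int, sw: int) -> Tensor:
    """im2col: (N,C,H,W) -> (N, C*kh*kw, Ho*Wo) over valid windows."""
    n, c, h, w = a.shape
    ho, wo = _conv_geometry(h, w, kh, kw, sh, sw)
    win = np.lib.stride_tricks.sliding_window_view(a.data, (kh, kw), axis=(2, 3))
    win = win[:, :, ::sh, ::sw]  # (N,C,Ho,Wo,kh,kw)
    out = win.transpose(0, 1, 4, 5, 2, 3).reshape(n, c * kh * kw, ho * wo)
    return _node(out, (a,), lambda g: (fold(g, (n, c, h, w), kh, kw, sh, sw),))


def fold(a: Tensor, out_shape: tuple, kh: int, kw: int, sh: int, sw: int) -> Tensor:
    """col2im: adjoint of :func:`unfold` (overlapping windows accumulate)."""
    n, c, h, w = out_shape
    ho, wo = _conv_geometry(h, w, kh, kw, sh, sw)
    cols = a.data.reshape(n, c, kh, kw, ho, wo)
    out = np.zeros(out_shape, dtype=DTYPE)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i : i + sh * ho : sh, j : j + sw * wo : sw] += cols[:, :, i, j]
    return _node(out, (a,), lambda g: (unfold(g, kh, kw, sh, sw),))


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None, stride=(1, 1), padding: int = 0) -> Tensor:
    """Valid cross-correlation in NCHW layout; ``weight`` is (OC, IC, kh, kw)."""
    oc, ic, kh, kw = weight.shape
    if x.shape[1] != ic:
        raise ValueError(f"conv2d channel mismatch: input has {x.shape[1]}, weight expects {ic}")
    if padding:
        x = pad2d(x, padding)
    n, _, h, w = x.shape
    sh, sw = stride
    if h < kh or w < kw:
        raise ValueError(f"conv2d input {h}x{w} smaller than kernel {kh}x{kw}")
    ho, wo = _conv_geometry(h, w, kh, kw, sh, sw)
    cols = unfold(x, kh, kw, sh, sw)  # (N, IC*kh*kw, L)
    cols2 = reshape(transpose(cols, (1, 0, 2)), (ic * kh * kw, n * ho * wo))
    wmat = reshape(weight, (oc, ic * kh * kw))
    out = matmul(wmat, cols2)  # (OC, N*L)
    out = transpose(reshape(out, (oc, n, ho, wo)), (1, 0, 2, 3))
    if bias is not None:
        out = add(out, reshape(bias, (1, oc, 1, 1)))
    return out


def upsample_nearest2(a: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of the trailing two axes."""
    n, c, h, w = a.shape
    out = a.data.repeat(2, axis=2).repeat(2, axis=3)

    def vjp(g):
        g6 = reshape(g, (n, c, h, 2, w, 2))
        return (sum_(g6, axis=(3, 5)),)

    return _node(out, (a,), vjp)


def avgpool2(a: Tensor) -> Tensor:
    """2x2 average pooling (trailing axes must be even)."""
    n, c, h, w = a.shape
    return mean(reshape(a, (n, c, h // 2, 2, w // 2, 2)), axis=(3, 5))


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def _toposort(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order


def grad(output: Tensor, wrt: Sequence[Tensor], create_graph: bool = False) -> list[Tensor]:
    """Gradients of a scalar ``output`` w.r.t. each tensor in ``wrt``.

    With ``create_graph=True`` the returned tensors carry their own graph and
    may be differentiated again.
    """
    if output.size != 1:
        raise ValueError(f"grad expects a scalar output, got shape {output.shape}")
    wanted = {id(w) for w in wrt}
    grads: dict[int, Tensor] = {id(output): Tensor(np.ones(output.shape, dtype=DTYPE))}
    for node in reversed(_toposort(output)):
        g = grads[id(node)] if id(node) in grads else None
        if g is None:
            continue
        if id(node) not in wanted:
            del grads[id(node)]
        if node._vjp is None:
            continue
        for p, pg in zip(node._parents, node._vjp(g)):
            if pg is None or not p.requires_grad:
                continue
            if id(p) in grads:
                grads[id(p)] = add(grads[id(p)], pg)
            else:
                grads[id(p)] = pg
    result = []
    for w in wrt:
        g = grads.get(id(w))
        if g is None:
            g = Tensor(np.zeros(w.shape, dtype=DTYPE))
        elif not create_graph:
            g = g.detach()
        result.append(g)
    return result
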