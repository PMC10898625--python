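"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical backbone of the harmonization networks: a tape-based
tensor with exactly the operations the encoders, generator and discriminators
need (dense matmul, im2col 2-D convolution, instance normalization, pointwise
nonlinearities, reductions, slicing/concatenation, nearest-neighbour
upsampling) plus an ADAM optimizer.  Everything is float32 and fully
deterministic: no threading decisions are made here, and all randomness is
injected by callers through ``numpy.random.Generator`` objects.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32

_GRAD_ENABLED = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference / GAN fakes)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


class Tensor:
    """A numpy array plus the tape needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents: Sequence["Tensor"] = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = tuple(parents)
        self._backward = backward

    # -- introspection -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    # -- autograd ------------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this node (default seed: ones)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs here can exceed recursion depth
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.asarray(grad, dtype=DTYPE)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- operators -----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __sub__(self, other):
        return add(self, mul(as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul(self, 1.0 / other)
        return mul(self, pow_(as_tensor(other), -1.0))

    def __neg__(self):
        return mul(self, -1.0)

    def __pow__(self, p):
        return pow_(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def __getitem__(self, idx):
        return getitem(self, idx)

    def reshape(self, *shape):
        return reshape(self, shape)

    def mean(self, axis=None, keepdims=False):
        return mean(self, axis=axis, keepdims=keepdims)

    def sum(self, axis=None, keepdims=False):
        return sum_(self, axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(x)


def parameter(data, rng: np.random.Generator | None = None) -> Tensor:
    return Tensor(np.asarray(data, dtype=DTYPE), requires_grad=True)


def _node(data, parents, backward) -> Tensor:
    parents = tuple(parents)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        return Tensor(data, requires_grad=True, parents=parents, backward=backward)
    return Tensor(data)


def _accum(t: Tensor, g: np.ndarray, owned: bool = False) -> None:
    """Accumulate a gradient; ``owned=True`` marks ``g`` as freshly
    allocated by the caller so it can be adopted without a defensive copy."""
    if not t.requires_grad:
        return
    if t.grad is None:
        if owned and g.dtype == DTYPE and g.flags.writeable:
            t.grad = g
        else:
            t.grad = g.astype(DTYPE, copy=True) if g.dtype != DTYPE else g.copy()
    else:
        t.grad += g


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    if g.shape == shape:
        return g
    nd = g.ndim - len(shape)
    if nd > 0:
        g = g.sum(axis=tuple(range(nd)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- arithmetic ---------------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data

    def backward(g, a=a, b=b):
        _accum(a, _unbroadcast(g, a.data.shape))
        _accum(b, _unbroadcast(g, b.data.shape))

    out = _node(out_data, (a, b), None)
    out._backward = lambda g: backward(g)
    return out


def mul(a, b) -> Tensor:
    if isinstance(b, (int, float)):
        a = as_tensor(a)
        out = _node(a.data * DTYPE(b), (a,), None)
        out._backward = lambda g, a=a, s=DTYPE(b): _accum(a, g * s, owned=True)
        return out
    a, b = as_tensor(a), as_tensor(b)
    out = _node(a.data * b.data, (a, b), None)

    def backward(g, a=a, b=b):
        _accum(a, _unbroadcast(g * b.data, a.data.shape), owned=True)
        _accum(b, _unbroadcast(g * a.data, b.data.shape), owned=True)

    out._backward = backward
    return out


def pow_(a, p: float) -> Tensor:
    a = as_tensor(a)
    out = _node(a.data ** DTYPE(p), (a,), None)
    out._backward = lambda g, a=a, p=p: _accum(
        a, g * DTYPE(p) * a.data ** DTYPE(p - 1.0))
    return out


def matmul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = _node(a.data @ b.data, (a, b), None)

    def backward(g, a=a, b=b):
        _accum(a, g @ b.data.T, owned=True)
        _accum(b, a.data.T @ g, owned=True)

    out._backward = backward
    return out


# -- pointwise nonlinearities -------------------------------------------------

def relu(a) -> Tensor:
    a = as_tensor(a)
    out = _node(np.maximum(a.data, 0.0), (a,), None)
    out._backward = lambda g, a=a: _accum(a, g * (a.data > 0), owned=True)
    return out


def leaky_relu(a, alpha: float = 0.2) -> Tensor:
    a = as_tensor(a)
    pos = a.data > 0
    out = _node(np.where(pos, a.data, DTYPE(alpha) * a.data), (a,), None)
    out._backward = lambda g, a=a, pos=pos: _accum(
        a, g * np.where(pos, DTYPE(1.0), DTYPE(alpha)), owned=True)
    return out


def tanh(a) -> Tensor:
    a = as_tensor(a)
    y = np.tanh(a.data)
    out = _node(y, (a,), None)
    out._backward = lambda g, a=a, y=y: _accum(a, g * (1.0 - y * y), owned=True)
    return out


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    y = 1.0 / (1.0 + np.exp(-a.data))
    out = _node(y, (a,), None)
    out._backward = lambda g, a=a, y=y: _accum(a, g * y * (1.0 - y), owned=True)
    return out


def log(a) -> Tensor:
    a = as_tensor(a)
    out = _node(np.log(a.data), (a,), None)
    out._backward = lambda g, a=a: _accum(a, g / a.data, owned=True)
    return out


def abs_(a) -> Tensor:
    a = as_tensor(a)
    out = _node(np.abs(a.data), (a,), None)
    out._backward = lambda g, a=a: _accum(a, g * np.sign(a.data), owned=True)
    return out


def clamp(a, lo: float | None = None, hi: float | None = None) -> Tensor:
    a = as_tensor(a)
    y = np.clip(a.data, lo, hi)
    inside = np.ones_like(a.data, dtype=bool)
    if lo is not None:
        inside &= a.data > lo
    if hi is not None:
        inside &= a.data < hi
    out = _node(y, (a,), None)
    out._backward = lambda g, a=a, inside=inside: _accum(a, g * inside, owned=True)
    return out


# -- reductions / shape -------------------------------------------------------

def mean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    y = a.data.mean(axis=axis, keepdims=keepdims, dtype=DTYPE)
    if axis is None:
        denom = a.data.size
    else:
        axes = (axis,) if isinstance(axis, int) else tuple(axis)
        denom = int(np.prod([a.data.shape[ax] for ax in axes]))

    def backward(g, a=a, axis=axis, keepdims=keepdims, denom=denom):
        g = np.asarray(g, dtype=DTYPE)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape) / DTYPE(denom))

    out = _node(y, (a,), None)
    out._backward = backward
    return out


def sum_(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    y = a.data.sum(axis=axis, keepdims=keepdims, dtype=DTYPE)

    def backward(g, a=a, axis=axis, keepdims=keepdims):
        g = np.asarray(g, dtype=DTYPE)
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        _accum(a, np.broadcast_to(g, a.data.shape).astype(DTYPE))

    out = _node(y, (a,), None)
    out._backward = backward
    return out


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out = _node(a.data.reshape(shape), (a,), None)
    out._backward = lambda g, a=a: _accum(a, g.reshape(a.data.shape))
    return out


def getitem(a, idx) -> Tensor:
    a = as_tensor(a)
    out = _node(a.data[idx], (a,), None)

    def backward(g, a=a, idx=idx):
        da = np.zeros_like(a.data)
        da[idx] += g
        _accum(a, da, owned=True)

    out._backward = backward
    return out


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis),
                tensors, None)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, tensors=tensors, offsets=offsets, axis=axis):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            _accum(t, g[tuple(sl)])

    out._backward = backward
    return out


# -- convolution and friends --------------------------------------------------

def conv2d_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray | None,
                   stride: int = 1, pad: int = 0):
    """Plain-numpy conv (NCHW, weight FCHW).  Returns (y, cols, x_padded_shape).

    Shared by the autograd op and by grad-free users (e.g. the fixed FID
    embedding).
    """
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    B, C, H, W = x.shape
    F, _, kh, kw = w.shape
    Ho = (H - kh) // stride + 1
    Wo = (W - kw) // stride + 1
    v = sliding_window_view(x, (kh, kw), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5)).reshape(
        B * Ho * Wo, C * kh * kw)
    out = cols @ w.reshape(F, -1).T
    if b is not None:
        out += b
    y = out.reshape(B, Ho, Wo, F).transpose(0, 3, 1, 2)
    return np.ascontiguousarray(y), cols, x.shape


def conv2d(x, w, b=None, stride: int = 1, pad: int = 0) -> Tensor:
    x, w = as_tensor(x), as_tensor(w)
    b = as_tensor(b) if b is not None else None
    y, cols, padded_shape = conv2d_forward(x.data, w.data,
                                           b.data if b is not None else None,
                                           stride, pad)
    parents = (x, w) if b is None else (x, w, b)
    out = _node(y, parents, None)
    if not out.requires_grad:
        return out
    F, C, kh, kw = w.data.shape
    B, _, Ho, Wo = y.shape

    def backward(g):
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, F)
        _accum(w, (gm.T @ cols).reshape(F, C, kh, kw), owned=True)
        if b is not None:
            _accum(b, gm.sum(axis=0), owned=True)
        if x.requires_grad:
            # col2im in NHWC order: the channel axis stays contiguous in
            # both source and destination of every accumulation
            w_r = np.ascontiguousarray(
                w.data.transpose(0, 2, 3, 1)).reshape(F, kh * kw * C)
            dc = (gm @ w_r).reshape(B, Ho, Wo, kh, kw, C)
            Hp, Wp = padded_shape[2], padded_shape[3]
            dxp = np.zeros((B, Hp, Wp, C), dtype=DTYPE)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, i:i + stride * Ho:stride,
                        j:j + stride * Wo:stride, :] += dc[:, :, :, i, j, :]
            dxp = dxp.transpose(0, 3, 1, 2)
            if pad:
                dxp = dxp[:, :, pad:-pad, pad:-pad]
            _accum(x, np.ascontiguousarray(dxp), owned=True)

    out._backward = backward
    return out


def linear(x, w, b=None) -> Tensor:
    """x (B, din) @ w (din, dout) + b."""
    y = matmul(x, w)
    if b is not None:
        y = add(y, b)
    return y


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    axes = tuple(axes)
    inv = tuple(np.argsort(axes))
    out = _node(a.data.transpose(axes), (a,), None)
    out._backward = lambda g, a=a, inv=inv: _accum(
        a, np.ascontiguousarray(g.transpose(inv)), owned=True)
    return out


def depth_to_space2(a) -> Tensor:
    """(B, 4C, H, W) -> (B, C, 2H, 2W) sub-pixel rearrangement."""
    a = as_tensor(a)
    B, C4, H, W = a.shape
    C = C4 // 4
    y = reshape(a, (B, C, 2, 2, H, W))
    y = transpose(y, (0, 1, 4, 2, 5, 3))  # B, C, H, 2, W, 2
    return reshape(y, (B, C, 2 * H, 2 * W))


def upsample_nearest2(a) -> Tensor:
    a = as_tensor(a)
    y = a.data.repeat(2, axis=2).repeat(2, axis=3)
    out = _node(y, (a,), None)

    def backward(g, a=a):
        B, C, H2, W2 = g.shape
        _accum(a, g.reshape(B, C, H2 // 2, 2, W2 // 2, 2).sum(axis=(3, 5)), owned=True)

    out._backward = backward
    return out


def instance_norm(a, eps: float = 1e-5) -> Tensor:
    """Per-sample per-channel standardization over the spatial axes (no affine)."""
    a = as_tensor(a)
    x = a.data
    mu = x.mean(axis=(2, 3), keepdims=True, dtype=DTYPE)
    var = x.var(axis=(2, 3), keepdims=True, dtype=DTYPE)
    inv = 1.0 / np.sqrt(var + DTYPE(eps))
    y = (x - mu) * inv
    out = _node(y, (a,), None)
    n = x.shape[2] * x.shape[3]

    def backward(g, a=a, y=y, inv=inv, n=n):
        gm = g.mean(axis=(2, 3), keepdims=True, dtype=DTYPE)
        gym = (g * y).mean(axis=(2, 3), keepdims=True, dtype=DTYPE)
        _accum(a, inv * (g - gm - y * gym), owned=True)

    out._backward = backward
    return out


# -- losses helpers -----------------------------------------------------------

def l1_mean(a, b) -> Tensor:
    """Mean absolute difference (the reduction convention for every L1 term)."""
    return mean(abs_(add(as_tensor(a), mul(as_tensor(b), -1.0))))


# -- optimizer ----------------------------------------------------------------

class Adam:
    """Standard ADAM (β1=0.9, β2=0.999, ε=1e-8), float32 state."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = DTYPE(self.b1), DTYPE(self.b2)
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        lr_t = DTYPE(self.lr * np.sqrt(bc2) / bc1)
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            m, v = self.m[k], self.v[k]
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= lr_t * m / (np.sqrt(v) + DTYPE(self.eps))

    def state_arrays(self, prefix: str) -> dict[str, np.ndarray]:
        out = {}
        for k in self.params:
            out[f"{prefix}.m.{k}"] = self.m[k]
            out[f"{prefix}.v.{k}"] = self.v[k]
        return out

    def load_state_arrays(self, prefix: str, arrays) -> None:
        for k in self.params:
            self.m[k] = np.asarray(arrays[f"{prefix}.m.{k}"], dtype=DTYPE)
            self.v[k] = np.asarray(arrays[f"{prefix}.v.{k}"], dtype=DTYPE)
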