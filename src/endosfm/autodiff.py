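"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The engine implements exactly the operations the rest of the package needs:
elementwise arithmetic with broadcasting, reductions, slicing/concatenation,
2-D convolution, nearest-neighbour upsampling and pixel gathering (the
primitive behind differentiable bilinear sampling). Gradients are accumulated
by topologically-sorted reverse traversal of the dynamically built graph.

All arrays are float64. Graph construction is skipped entirely when no input
requires gradients, so inference costs a plain NumPy evaluation.
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "as_tensor",
    "concatenate",
    "where",
    "maximum",
    "exp",
    "log",
    "sqrt",
    "sin",
    "cos",
    "sigmoid",
    "softplus",
    "relu",
    "elu",
    "conv2d",
    "pad2d",
    "take_pixels",
    "upsample_nearest",
    "Module",
    "Conv2d",
    "Adam",
    "clip_grad_norm",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward",
                 "_grad_shared")

    # make ndarray <op> Tensor dispatch to the reflected Tensor dunders
    __array_ufunc__ = None

    def __init__(self, data, requires_grad: bool = False,
                 _parents: tuple = (), _backward: Callable | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = _parents
        self._backward = _backward
        self._grad_shared = False

    # ------------------------------------------------------------------ basic
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

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -------------------------------------------------------------- autograd
    def _accum(self, g: np.ndarray) -> None:
        # first contribution adopts the incoming array (producers hand over
        # freshly computed arrays); a second contribution allocates
        if self.grad is None:
            self.grad = g
            self._grad_shared = True
        elif self._grad_shared:
            self.grad = self.grad + g
            self._grad_shared = False
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        out = _make(self.data + other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g, other.shape))
            out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = as_tensor(other)
        out = _make(self.data * other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(g * self.data, other.shape))
            out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        other = as_tensor(other)
        out = _make(self.data / other.data, (self, other))
        if out.requires_grad:
            def bw(g):
                if self.requires_grad:
                    self._accum(_unbroadcast(g / other.data, self.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(-g * self.data / other.data ** 2,
                                              other.shape))
            out._backward = bw
        return out

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        out = _make(self.data ** p, (self,))
        if out.requires_grad:
            def bw(g):
                self._accum(_unbroadcast(g * p * self.data ** (p - 1), self.shape))
            out._backward = bw
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = _make(np.abs(self.data), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g * sign)
        return out

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out = _make(self.data.sum(axis=axis, keepdims=keepdims), (self,))
        if out.requires_grad:
            shape = self.shape

            def bw(g):
                if axis is None:
                    self._accum(np.broadcast_to(g, shape).copy()
                                if np.ndim(g) else np.full(shape, g))
                    return
                gg = g
                if not keepdims:
                    gg = np.expand_dims(gg, axis)
                self._accum(np.broadcast_to(gg, shape).copy())
            out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.size if axis is None else (
            np.prod([self.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # --------------------------------------------------------------- shaping
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out = _make(self.data.reshape(shape), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accum(g.reshape(self.shape))
        return out

    def transpose(self, *axes):
        out = _make(self.data.transpose(axes), (self,))
        if out.requires_grad:
            inv = np.argsort(axes)
            out._backward = lambda g: self._accum(g.transpose(inv))
        return out

    def __getitem__(self, idx):
        out = _make(self.data[idx], (self,))
        if out.requires_grad:
            def bw(g):
                full = np.zeros_like(self.data)
                if _is_fancy(idx):
                    np.add.at(full, idx, g)
                else:
                    full[idx] += g
                self._accum(full)
            out._backward = bw
        return out


def _is_fancy(idx) -> bool:
    if isinstance(idx, tuple):
        return any(isinstance(i, np.ndarray) for i in idx)
    return isinstance(idx, np.ndarray)


def _make(data: np.ndarray, parents: Sequence[Tensor]) -> Tensor:
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, _parents=tuple(parents) if req else ())


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ------------------------------------------------------------------ functions

def exp(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = _make(np.exp(x.data), (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accum(g * out.data)
    return out


def log(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = _make(np.log(x.data), (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accum(g / x.data)
    return out


def sqrt(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = _make(np.sqrt(x.data), (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accum(g * 0.5 / out.data)
    return out


def sin(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = _make(np.sin(x.data), (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accum(g * np.cos(x.data))
    return out


def cos(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = _make(np.cos(x.data), (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accum(-g * np.sin(x.data))
    return out


def sigmoid(x: Tensor) -> Tensor:
    x = as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = _make(s, (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accum(g * s * (1.0 - s))
    return out


def softplus(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = _make(np.logaddexp(0.0, x.data), (x,))
    if out.requires_grad:
        s = 1.0 / (1.0 + np.exp(-x.data))
        out._backward = lambda g: x._accum(g * s)
    return out


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    mask = x.data > 0
    out = _make(x.data * mask, (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accum(g * mask)
    return out


def elu(x: Tensor, alpha: float = 1.0) -> Tensor:
    x = as_tensor(x)
    neg = x.data <= 0
    e = np.where(neg, alpha * np.expm1(np.minimum(x.data, 0.0)), x.data)
    out = _make(e, (x,))
    if out.requires_grad:
        deriv = np.where(neg, e + alpha, 1.0)
        out._backward = lambda g: x._accum(g * deriv)
    return out


def where(mask: np.ndarray, a, b) -> Tensor:
    """Select with a constant (non-differentiated) boolean mask."""
    a, b = as_tensor(a), as_tensor(b)
    mask = np.asarray(mask, dtype=bool)
    out = _make(np.where(mask, a.data, b.data), (a, b))
    if out.requires_grad:
        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(np.where(mask, g, 0.0), a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(np.where(mask, 0.0, g), b.shape))
        out._backward = bw
    return out


def maximum(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    return where(a.data >= b.data, a, b)


def concatenate(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _make(np.concatenate([t.data for t in tensors], axis=axis), tensors)
    if out.requires_grad:
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(piece)
        out._backward = bw
    return out


def broadcast_to(x: Tensor, shape: tuple) -> Tensor:
    """Broadcast without copy; the backward pass sums over the new axes."""
    x = as_tensor(x)
    out = _make(np.broadcast_to(x.data, shape), (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accum(_unbroadcast(g, x.shape))
    return out


def pad2d(x: Tensor, p: int) -> Tensor:
    """Zero-pad the last two axes by `p` on each side."""
    x = as_tensor(x)
    if p == 0:
        return x
    pw = [(0, 0)] * (x.ndim - 2) + [(p, p), (p, p)]
    out = _make(np.pad(x.data, pw), (x,))
    if out.requires_grad:
        sl = (Ellipsis, slice(p, -p), slice(p, -p))
        out._backward = lambda g: x._accum(g[sl])
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), NCHW layout.

    Implemented as k*k shifted tensordots, which keeps both passes as dense
    BLAS calls — no im2col materialisation and no scatter-add in the backward
    pass hot loop.
    """
    x, w = as_tensor(x), as_tensor(w)
    n, cin, h, wd = x.shape
    cout, cin_w, k, _ = w.shape
    if cin != cin_w:
        raise ValueError(f"conv2d channel mismatch: input {cin}, weight {cin_w}")
    xp = np.pad(x.data, [(0, 0), (0, 0), (padding, padding), (padding, padding)])
    ho = (h + 2 * padding - k) // stride + 1
    wo = (wd + 2 * padding - k) // stride + 1
    # im2col via stride tricks -> one dense matmul
    sn, sc, sh, sw = xp.strides
    patches = np.lib.stride_tricks.as_strided(
        xp, shape=(n, cin, k, k, ho, wo),
        strides=(sn, sc, sh, sw, sh * stride, sw * stride))
    cols = np.ascontiguousarray(
        patches.transpose(0, 4, 5, 1, 2, 3)).reshape(n * ho * wo, cin * k * k)
    wmat = w.data.reshape(cout, cin * k * k)
    out_d = cols @ wmat.T
    if b is not None:
        out_d += b.data
    out_d = np.ascontiguousarray(
        out_d.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2))
    parents = (x, w) if b is None else (x, w, b)
    out = _make(out_d, parents)
    if out.requires_grad:
        def bw(g):
            gmat = np.ascontiguousarray(
                g.transpose(0, 2, 3, 1)).reshape(n * ho * wo, cout)
            if b is not None and b.requires_grad:
                b._accum(gmat.sum(axis=0))
            if w.requires_grad:
                w._accum((gmat.T @ cols).reshape(w.shape))
            if x.requires_grad:
                gcols = (gmat @ wmat).reshape(n, ho, wo, cin, k, k) \
                    .transpose(0, 3, 4, 5, 1, 2)
                gxp = np.zeros_like(xp)
                for di in range(k):
                    for dj in range(k):
                        gxp[:, :, di:di + stride * ho:stride,
                            dj:dj + stride * wo:stride] += gcols[:, :, di, dj]
                if padding:
                    gxp = gxp[:, :, padding:-padding, padding:-padding]
                x._accum(gxp)
        out._backward = bw
    return out


def take_pixels(f: Tensor, iy: np.ndarray, ix: np.ndarray) -> Tensor:
    """Gather f[n, :, iy[n,i,j], ix[n,i,j]] -> (N, C, Ho, Wo).

    Indices are integer constants (already clipped in-bounds); gradients flow
    only into `f`, by per-channel bincount scatter-add.
    """
    f = as_tensor(f)
    n, c, h, w = f.shape
    bidx = np.arange(n)[:, None, None]
    vals = f.data[bidx, :, iy, ix]          # (N, Ho, Wo, C)
    out = _make(np.ascontiguousarray(vals.transpose(0, 3, 1, 2)), (f,))
    if out.requires_grad:
        flat = ((bidx * h + iy) * w + ix).ravel()

        def bw(g):
            gf = np.empty((n, c, h, w))
            for ch in range(c):
                gf[:, ch] = np.bincount(
                    flat, weights=g[:, ch].ravel(),
                    minlength=n * h * w).reshape(n, h, w)
            f._accum(gf)
        out._backward = bw
    return out


_box_count_cache: dict = {}


def box3_mean(x: Tensor) -> Tensor:
    """3x3 local mean over the last two axes with shrink-at-border
    normalisation (windows are clipped at the image edge). Self-adjoint up
    to the per-pixel window counts, which gives a one-call backward pass.
    """
    from scipy.ndimage import uniform_filter

    x = as_tensor(x)
    h, w = x.shape[-2:]
    key = (h, w)
    if key not in _box_count_cache:
        ones = np.ones((h, w))
        _box_count_cache[key] = uniform_filter(
            ones, size=3, mode="constant") * 9.0
    count = _box_count_cache[key]
    size = (1,) * (x.ndim - 2) + (3, 3)
    s = uniform_filter(x.data, size=size, mode="constant") * 9.0
    out = _make(s / count, (x,))
    if out.requires_grad:
        def bw(g):
            x._accum(uniform_filter(g / count, size=size,
                                    mode="constant") * 9.0)
        out._backward = bw
    return out


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    """Nearest-neighbour upsampling of the last two axes by an integer factor."""
    x = as_tensor(x)
    if factor == 1:
        return x
    d = x.data.repeat(factor, axis=-2).repeat(factor, axis=-1)
    out = _make(d, (x,))
    if out.requires_grad:
        n, c, h, w = x.shape

        def bw(g):
            g = g.reshape(n, c, h, factor, w, factor).sum(axis=(3, 5))
            x._accum(g)
        out._backward = bw
    return out


# ---------------------------------------------------------------- parameters

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Container with recursive parameter discovery and flat state dicts."""

    def named_parameters(self, prefix: str = "") -> "OrderedDict[str, Parameter]":
        out: OrderedDict[str, Parameter] = OrderedDict()
        for name, attr in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(attr, Parameter):
                out[full] = attr
            elif isinstance(attr, Module):
                out.update(attr.named_parameters(full + "."))
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        out.update(item.named_parameters(f"{full}.{i}."))
                    elif isinstance(item, Parameter):
                        out[f"{full}.{i}"] = item
        return out

    def parameters(self) -> list:
        return list(self.named_parameters().values())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        return OrderedDict((k, v.data.copy())
                           for k, v in self.named_parameters().items())

    def load_state_dict(self, state: dict) -> None:
        params = self.named_parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, p in params.items():
            p.data = np.asarray(state[k], dtype=np.float64).reshape(p.shape).copy()


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, padding: int | None = None,
                 zero_init: bool = False, bias_init: float = 0.0):
        if padding is None:
            padding = k // 2
        self.stride = stride
        self.padding = padding
        if zero_init:
            w = np.zeros((cout, cin, k, k))
        else:
            scale = np.sqrt(2.0 / (cin * k * k))
            w = rng.normal(0.0, scale, size=(cout, cin, k, k))
        self.weight = Parameter(w)
        self.bias = Parameter(np.full(cout, float(bias_init)))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class Adam:
    """Adam with exact state export for deterministic checkpoint resume."""

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-4,
                 betas: tuple = (0.9, 0.99), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1.0 - self.b1) * p.grad
            v *= self.b2
            v += (1.0 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t, "lr": self.lr,
                "m": [m.copy() for m in self.m],
                "v": [v.copy() for v in self.v]}

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.lr = float(state["lr"])
        self.m = [np.asarray(m, dtype=np.float64).copy() for m in state["m"]]
        self.v = [np.asarray(v, dtype=np.float64).copy() for v in state["v"]]


def clip_grad_norm(params: Iterable[Parameter], max_norm: float) -> float:
    params = [p for p in params if p.grad is not None]
    total = np.sqrt(sum(float((p.grad ** 2).sum()) for p in params))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for p in params:
            p.grad *= scale
    return total
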