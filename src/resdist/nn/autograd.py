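"""Minimal reverse-mode automatic differentiation on numpy arrays.

Supports exactly the operations the residual networks need: broadcasting
arithmetic, matmul, same-padding 2-D convolution (im2col), ReLU/sigmoid,
axis reductions, reshape/transpose/concat, grouped channel max (Maxout),
log-softmax, and dropout. Gradients are verified against central finite
differences in the test suite.
"""

from __future__ import annotations

from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum out broadcast dimensions so grad matches the original shape."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """Array node in the autograd graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- graph -----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad needs a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = grad
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            # free intermediate grads to cap memory
            if node._parents and not node.requires_grad:
                node.grad = None

    def zero_grad(self) -> None:
        self.grad = None

    # -- helpers ---------------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.copy() if grad.base is not None else grad
        else:
            self.grad = self.grad + grad

    def item(self) -> float:
        return float(self.data)

    # -- operators ---------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, mul(_as_tensor(other), -1.0))

    def __rsub__(self, other):
        return add(_as_tensor(other), mul(self, -1.0))

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = _as_tensor(other)
        return mul(self, power(other, -1.0))

    def __pow__(self, p):
        return power(self, p)

    def __matmul__(self, other):
        return matmul(self, other)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)])
        return mul(tsum(self, axis=axis, keepdims=keepdims), 1.0 / float(n))

    def reshape(self, *shape):
        return reshape(self, shape)

    def transpose(self, *axes):
        return transpose(self, axes)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out._parents = parents
        out._backward = backward
    return out


# ---------------------------------------------------------------------------
# elementwise / arithmetic

def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def power(a, p: float) -> Tensor:
    a = _as_tensor(a)
    data = a.data ** p

    def backward(g):
        a._accumulate(g * p * a.data ** (p - 1.0))

    return _make(data, (a,), backward)


def sqrt(a) -> Tensor:
    return power(a, 0.5)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    data = a.data * mask

    def backward(g):
        a._accumulate(g * mask)

    return _make(data, (a,), backward)


def sigmoid(a) -> Tensor:
    a = _as_tensor(a)
    data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accumulate(g * data * (1.0 - data))

    return _make(data, (a,), backward)


def exp(a) -> Tensor:
    a = _as_tensor(a)
    data = np.exp(a.data)

    def backward(g):
        a._accumulate(g * data)

    return _make(data, (a,), backward)


def log(a) -> Tensor:
    a = _as_tensor(a)
    data = np.log(a.data)

    def backward(g):
        a._accumulate(g / a.data)

    return _make(data, (a,), backward)


# ---------------------------------------------------------------------------
# shape / reductions

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = _as_tensor(a)
    data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        if axis is None:
            grad = np.broadcast_to(g, a.data.shape)
        elif keepdims:
            grad = np.broadcast_to(g, a.data.shape)
        else:
            grad = np.broadcast_to(np.expand_dims(g, axis), a.data.shape)
        a._accumulate(np.ascontiguousarray(grad))

    return _make(data, (a,), backward)


def reshape(a, shape) -> Tensor:
    a = _as_tensor(a)
    old = a.data.shape
    data = a.data.reshape(shape)

    def backward(g):
        a._accumulate(g.reshape(old))

    return _make(data, (a,), backward)


def transpose(a, axes) -> Tensor:
    a = _as_tensor(a)
    axes = tuple(axes)
    data = a.data.transpose(axes)
    inv = tuple(np.argsort(axes))

    def backward(g):
        a._accumulate(g.transpose(inv))

    return _make(data, (a,), backward)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accumulate(g[tuple(sl)])

    return _make(data, tuple(tensors), backward)


def matmul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data @ b.data

    def backward(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    return _make(data, (a, b), backward)


def channel_group_max(a, groups: int) -> Tensor:
    """Maxout: max over ``groups`` consecutive channels of a (C, H, W) map."""
    a = _as_tensor(a)
    C, H, W = a.data.shape
    if C % groups != 0:
        raise ValueError(f"channels {C} not divisible by groups {groups}")
    out_c = C // groups
    view = a.data.reshape(out_c, groups, H, W)
    arg = view.argmax(axis=1)
    data = np.take_along_axis(view, arg[:, None], axis=1)[:, 0]

    def backward(g):
        gv = np.zeros((out_c, groups, H, W))
        np.put_along_axis(gv, arg[:, None], g[:, None], axis=1)
        a._accumulate(gv.reshape(C, H, W))

    return _make(data, (a,), backward)


def log_softmax(a, axis: int = 0) -> Tensor:
    a = _as_tensor(a)
    x = a.data
    m = x.max(axis=axis, keepdims=True)
    z = x - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    data = z - lse

    def backward(g):
        sm = np.exp(data)
        a._accumulate(g - sm * g.sum(axis=axis, keepdims=True))

    return _make(data, (a,), backward)


def dropout(a, rate: float, rng: np.random.Generator,
            training: bool) -> Tensor:
    if not training or rate <= 0.0:
        return _as_tensor(a)
    a = _as_tensor(a)
    mask = (rng.random(a.data.shape) >= rate) / (1.0 - rate)
    return mul(a, Tensor(mask))


# ---------------------------------------------------------------------------
# convolution

def _im2col(xp: np.ndarray, kh: int, kw: int) -> np.ndarray:
    C, Hp, Wp = xp.shape
    H, W = Hp - kh + 1, Wp - kw + 1
    s = xp.strides
    cols = np.lib.stride_tricks.as_strided(
        xp, (C, kh, kw, H, W), (s[0], s[1], s[2], s[1], s[2]))
    return np.ascontiguousarray(cols).reshape(C * kh * kw, H * W)


def conv2d(x, weight, bias) -> Tensor:
    """Same-padding stride-1 convolution.

    ``x``: (C_in, H, W); ``weight``: (C_out, C_in, kh, kw) with odd kh, kw;
    ``bias``: (C_out,). Output (C_out, H, W).
    """
    x, weight, bias = _as_tensor(x), _as_tensor(weight), _as_tensor(bias)
    c_out, c_in, kh, kw = weight.data.shape
    C, H, W = x.data.shape
    if C != c_in:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {c_in}")
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x.data, ((0, 0), (ph, ph), (pw, pw)))
    cols = _im2col(xp, kh, kw)  # (C_in*kh*kw, H*W)
    wm = weight.data.reshape(c_out, c_in * kh * kw)
    data = (wm @ cols + bias.data[:, None]).reshape(c_out, H, W)

    def backward(g):
        gflat = g.reshape(c_out, H * W)
        weight._accumulate((gflat @ cols.T).reshape(weight.data.shape))
        bias._accumulate(gflat.sum(axis=1))
        dcols = (wm.T @ gflat).reshape(c_in, kh, kw, H, W)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, i:i + H, j:j + W] += dcols[:, i, j]
        x._accumulate(dxp[:, ph:ph + H, pw:pw + W])

    return _make(data, (x, weight, bias), backward)
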