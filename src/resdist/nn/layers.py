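"""Network building blocks: convolution, RCIN normalization, Maxout, SE.

Internal layout is channels-first: feature maps are (C, L, L).
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor

EPS = 1e-6


class Module:
    """Base class; collects parameters from attributes and sub-modules."""

    training: bool = False

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for obj in self.__dict__.values():
            found: list[Tensor] = []
            if isinstance(obj, Tensor) and obj.requires_grad:
                found = [obj]
            elif isinstance(obj, Module):
                found = obj.parameters()
            elif isinstance(obj, (list, tuple)):
                for item in obj:
                    if isinstance(item, Module):
                        found.extend(item.parameters())
            for p in found:
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for obj in self.__dict__.values():
            if isinstance(obj, Module):
                mods.extend(obj.modules())
            elif isinstance(obj, (list, tuple)):
                for item in obj:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


def he_normal(rng: np.random.Generator, shape: tuple[int, ...],
              fan_in: int) -> np.ndarray:
    """He/Kaiming normal initialization."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """Same-padding stride-1 convolution with He-normal init."""

    def __init__(self, c_in: int, c_out: int, kh: int, kw: int | None = None,
                 rng: np.random.Generator | None = None):
        kw = kh if kw is None else kw
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * kh * kw
        self.weight = Tensor(he_normal(rng, (c_out, c_in, kh, kw), fan_in),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias)


def _normalize(x: Tensor, axes: tuple[int, ...]) -> Tensor:
    mu = x.mean(axis=axes, keepdims=True)
    centered = x - mu
    var = (centered * centered).mean(axis=axes, keepdims=True)
    return centered * ag.power(var + EPS, -0.5)


def instance_norm(x: Tensor) -> Tensor:
    """Per-channel normalization over the full L x L map."""
    return _normalize(x, (1, 2))


def row_norm(x: Tensor) -> Tensor:
    """Per-channel, per-row normalization (statistics along axis 2)."""
    return _normalize(x, (2,))


def col_norm(x: Tensor) -> Tensor:
    """Per-channel, per-column normalization (statistics along axis 1)."""
    return _normalize(x, (1,))


class RCIN(Module):
    """Instance + row + column normalization, fused by 1x1 conv, then ReLU.

    The three normalized views are concatenated channelwise (3C) and mixed
    back down to C channels; this preserves all three signals while keeping
    residual shapes.
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        self.fuse = Conv2d(3 * channels, channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        views = ag.concat([instance_norm(x), row_norm(x), col_norm(x)], axis=0)
        return ag.relu(self.fuse(views))


class Maxout(Module):
    """1x1 conv expansion followed by max over channel groups."""

    def __init__(self, c_in: int, c_out: int, groups: int = 2,
                 rng: np.random.Generator | None = None):
        self.groups = groups
        self.expand = Conv2d(c_in, c_out * groups, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return ag.channel_group_max(self.expand(x), self.groups)


class SEBlock(Module):
    """Squeeze-and-excitation channel gating (global pool -> bottleneck)."""

    def __init__(self, channels: int, reduction: int = 16,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        hidden = max(1, channels // reduction)
        self.w1 = Tensor(he_normal(rng, (channels, hidden), channels),
                         requires_grad=True)
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.w2 = Tensor(he_normal(rng, (hidden, channels), hidden),
                         requires_grad=True)
        self.b2 = Tensor(np.zeros(channels), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        c = x.shape[0]
        z = x.mean(axis=(1, 2)).reshape(1, c)  # squeeze
        h = ag.relu(z @ self.w1 + self.b1)
        s = ag.sigmoid(h @ self.w2 + self.b2)  # (1, C) gates in (0, 1)
        return x * s.reshape(c, 1, 1)


class Dropout(Module):
    def __init__(self, rate: float):
        self.rate = rate
        self.rng = np.random.default_rng(0)

    def forward(self, x: Tensor) -> Tensor:
        return ag.dropout(x, self.rate, self.rng, self.training)
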