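"""The four residual convolutional branch networks with dual output heads.

Each network maps an (L, L, C) branch input to a ``DualPrediction``: a
real-value distance map (ReLU head) and a 25-bin distogram (softmax head).
Default geometries: trunk width 64; 16 residual blocks for the COV and PRE
branches, 20 for PLM, 22 for OTHER. All forward passes are length-agnostic.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import RCIN, Conv2d, Dropout, Maxout, Module, SEBlock, instance_norm

N_BINS = 25

DEFAULT_BLOCKS = {"COV": 16, "PLM": 20, "PRE": 16, "OTHER": 22}
DEFAULT_DROPOUT = {"COV": 0.0, "PLM": 0.2, "PRE": 0.2, "OTHER": 0.0}


class BuildError(ValueError):
    """Raised when a NetworkSpec is inconsistent with its branch."""


@dataclass
class NetworkSpec:
    """Architecture description for one branch network."""

    branch: str
    input_channels: int
    trunk_width: int = 64
    residual_blocks: int | None = None
    dropout_rate: float | None = None
    se_reduction: int = 16
    seed: int = 0
    heads: dict = field(default_factory=lambda: {"regression": 1,
                                                 "classification": N_BINS})

    def __post_init__(self) -> None:
        if self.branch not in DEFAULT_BLOCKS:
            raise BuildError(f"unknown branch {self.branch!r}")
        if self.residual_blocks is None:
            self.residual_blocks = DEFAULT_BLOCKS[self.branch]
        if self.dropout_rate is None:
            self.dropout_rate = DEFAULT_DROPOUT[self.branch]
        if self.input_channels < 1 or self.trunk_width < 1:
            raise BuildError("channel counts must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise BuildError("dropout_rate must be in [0, 1)")


@dataclass
class DualPrediction:
    """Symmetrized prediction pair: Å distances and per-pair bin probabilities."""

    real_distance: np.ndarray  # (L, L), >= 0
    distogram: np.ndarray  # (L, L, 25), rows sum to 1


class _ResBlockCOV(Module):
    """RCIN, 3x3 conv, RCIN, 3x3 conv, SE; skip add; ReLU."""

    def __init__(self, width: int, se_reduction: int, rng):
        self.n1 = RCIN(width, rng)
        self.c1 = Conv2d(width, width, 3, rng=rng)
        self.n2 = RCIN(width, rng)
        self.c2 = Conv2d(width, width, 3, rng=rng)
        self.se = SEBlock(width, se_reduction, rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.c1(self.n1(x))
        y = self.c2(self.n2(y))
        return ag.relu(x + self.se(y))


class _ResBlockPLM(Module):
    """Bottleneck-style: 1x1 then 3x3, 7x1, 1x7 convs, three RCINs, SE, dropout."""

    def __init__(self, width: int, se_reduction: int, dropout: float, rng):
        self.n1 = RCIN(width, rng)
        self.c1 = Conv2d(width, width, 1, rng=rng)
        self.n2 = RCIN(width, rng)
        self.c2 = Conv2d(width, width, 3, rng=rng)
        self.c3 = Conv2d(width, width, 7, 1, rng=rng)
        self.c4 = Conv2d(width, width, 1, 7, rng=rng)
        self.n3 = RCIN(width, rng)
        self.se = SEBlock(width, se_reduction, rng)
        self.drop = Dropout(dropout)

    def forward(self, x: Tensor) -> Tensor:
        y = self.c1(self.n1(x))
        y = self.c2(self.n2(y))
        y = self.c4(self.c3(y))
        y = self.drop(self.se(self.n3(y)))
        return ag.relu(x + y)


class _SubBlockPRE(Module):
    """Conv 3x3, RCIN, dropout, SE, with its own shortcut connection."""

    def __init__(self, width: int, se_reduction: int, dropout: float, rng):
        self.conv = Conv2d(width, width, 3, rng=rng)
        self.norm = RCIN(width, rng)
        self.drop = Dropout(dropout)
        self.se = SEBlock(width, se_reduction, rng)

    def forward(self, x: Tensor) -> Tensor:
        y = self.se(self.drop(self.norm(self.conv(x))))
        return ag.relu(x + y)


class _ResBlockPRE(Module):
    """Two stacked sub-blocks, each carrying its own shortcut."""

    def __init__(self, width: int, se_reduction: int, dropout: float, rng):
        self.sub1 = _SubBlockPRE(width, se_reduction, dropout, rng)
        self.sub2 = _SubBlockPRE(width, se_reduction, dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.sub2(self.sub1(x))


class BranchNetwork(Module):
    """One branch network: stem -> residual trunk -> dual heads."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        w = spec.trunk_width
        cin = spec.input_channels
        b = spec.branch

        if b == "COV":
            self.stem_norm = RCIN(cin, rng)
            self.stem = Maxout(cin, w, groups=2, rng=rng)
            make = lambda: _ResBlockCOV(w, spec.se_reduction, rng)
        elif b == "PLM":
            self.stem_norm = None  # plain instance norm, no parameters
            self.stem = Maxout(cin, w, groups=2, rng=rng)
            make = lambda: _ResBlockPLM(w, spec.se_reduction,
                                        spec.dropout_rate, rng)
        else:  # PRE / OTHER
            self.stem_norm = None
            self.stem_conv = Conv2d(cin, w, 1, rng=rng)
            self.stem_rcin = RCIN(w, rng)
            self.stem = None
            make = lambda: _ResBlockPRE(w, spec.se_reduction,
                                        spec.dropout_rate, rng)
        self.blocks = [make() for _ in range(spec.residual_blocks)]
        self.final_conv = Conv2d(w, w, 1, rng=rng)
        self.head_reg = Conv2d(w, 1, 1, rng=rng)
        # start the ReLU regression head inside the supervised < 16 A range
        self.head_reg.bias.data[:] = 8.0
        self.head_cls = Conv2d(w, spec.heads["classification"], 1, rng=rng)
        # dropout layers get per-instance deterministic streams
        for i, m in enumerate(self.modules()):
            if isinstance(m, Dropout):
                m.rng = np.random.default_rng(spec.seed * 100003 + i)

    # -- forward ----------------------------------------------------------
    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """(C, L, L) input -> (regression map (1,L,L), class logits (25,L,L))."""
        b = self.spec.branch
        if b == "COV":
            h = self.stem(self.stem_norm(x))
        elif b == "PLM":
            h = self.stem(instance_norm(x))
        else:
            h = self.stem_rcin(self.stem_conv(instance_norm(x)))
        for block in self.blocks:
            h = block(h)
        h = instance_norm(self.final_conv(h))
        reg = ag.relu(self.head_reg(h))
        logits = self.head_cls(h)
        return reg, logits

    def predict(self, branch_tensor: np.ndarray) -> DualPrediction:
        """Inference on an (L, L, C) branch input; symmetrized outputs."""
        self.eval()
        x = Tensor(branch_tensor.transpose(2, 0, 1))
        with ag.no_grad():
            reg, logits = self.forward(x)
            logp = ag.log_softmax(logits, axis=0)
        dist = reg.data[0]
        dist = 0.5 * (dist + dist.T)
        probs = np.exp(logp.data).transpose(1, 2, 0)  # (L, L, 25)
        probs = 0.5 * (probs + probs.transpose(1, 0, 2))
        probs /= probs.sum(axis=2, keepdims=True)
        return DualPrediction(real_distance=dist, distogram=probs)

    # -- introspection ----------------------------------------------------
    def summary(self) -> dict:
        """Architecture report used by structural tests and the CLI."""
        return {
            "branch": self.spec.branch,
            "input_channels": self.spec.input_channels,
            "trunk_width": self.spec.trunk_width,
            "residual_blocks": len(self.blocks),
            "dropout_rate": self.spec.dropout_rate,
            "regression_head_channels": 1,
            "classification_head_channels":
                self.head_cls.weight.data.shape[0],
            "n_parameters": int(sum(p.data.size for p in self.parameters())),
        }

    def summary_text(self) -> str:
        return "\n".join(f"{k}: {v}" for k, v in self.summary().items())


def build_network(spec: NetworkSpec) -> BranchNetwork:
    """Construct the branch network described by ``spec``."""
    return BranchNetwork(spec)


# ---------------------------------------------------------------------------
# checkpoints

def save_checkpoint(model: BranchNetwork, path: str | os.PathLike) -> None:
    """Serialize weights (.npz) plus the embedded NetworkSpec (JSON)."""
    params = model.parameters()
    arrays = {f"p{i}": p.data for i, p in enumerate(params)}
    np.savez(path if str(path).endswith(".npz") else f"{path}.npz", **arrays)
    spec_path = str(path).removesuffix(".npz") + ".spec.json"
    with open(spec_path, "w") as fh:
        json.dump(asdict(model.spec), fh, indent=1)


def load_checkpoint(path: str | os.PathLike) -> BranchNetwork:
    base = str(path).removesuffix(".npz")
    with open(base + ".spec.json") as fh:
        spec = NetworkSpec(**json.load(fh))
    model = build_network(spec)
    with np.load(base + ".npz") as data:
        params = model.parameters()
        if len(data.files) != len(params):
            raise BuildError("checkpoint does not match the network spec")
        for i, p in enumerate(params):
            arr = data[f"p{i}"]
            if arr.shape != p.data.shape:
                raise BuildError("checkpoint parameter shape mismatch")
            p.data = arr.astype(np.float64)
    return model
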