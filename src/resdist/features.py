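"""1-D sequence features and assembly of per-branch input tensors.

Branch channel contracts (fixed by the printed input dimensions):

* COV branch: 441 covariance + 40 expanded profile + 1 contact score
  + 1 Pearson correlation = 483 channels
* PLM branch: 441 couplings + 40 expanded profile + 1 Pearson = 482
* PRE branch: 441 precision + 40 expanded profile + 1 joint entropy
  + 2 expanded column entropy = 484
* OTHER branch (configurable, default 53): 40 expanded profile
  + 6 expanded secondary structure + 2 expanded solvent accessibility
  + MI, normalized MI, joint entropy, entropy sum, Pearson.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import GAP_INDEX, HYDROPATHY
from .coevolution import (PairChannelBlock, column_entropy,
                          coupling_contact_score, covariance_tensor,
                          information_statistics, precision_tensor,
                          plm_tensor)
from .msa import MSA, column_frequencies

BRANCHES = ("COV", "PLM", "PRE", "OTHER")
BRANCH_CHANNELS = {"COV": 483, "PLM": 482, "PRE": 484, "OTHER": 53}


class AssemblyError(ValueError):
    """Raised when feature blocks cannot be stacked into a branch input."""


@dataclass
class SequenceFeatureSet:
    """Per-residue 1-D features: profile, optional SS and accessibility."""

    profile: np.ndarray  # (L, 20)
    secondary_structure: np.ndarray | None = None  # (L, 3)
    solvent_accessibility: np.ndarray | None = None  # (L, 1)
    source: str = "msa-derived"

    def __post_init__(self) -> None:
        if self.profile.ndim != 2 or self.profile.shape[1] != 20:
            raise ValueError("profile must be (L, 20)")


@dataclass
class BranchInput:
    """L x L x C input tensor for one network branch with a channel manifest."""

    branch: str
    tensor: np.ndarray
    channel_manifest: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tensor.ndim != 3:
            raise AssemblyError("branch tensor must be L x L x C")
        if len(self.channel_manifest) != self.tensor.shape[2]:
            raise AssemblyError(
                f"manifest length {len(self.channel_manifest)} != channel "
                f"count {self.tensor.shape[2]}")
        expected = BRANCH_CHANNELS.get(self.branch)
        if self.branch != "OTHER" and expected is not None \
                and self.tensor.shape[2] != expected:
            raise AssemblyError(
                f"{self.branch} branch requires {expected} channels, "
                f"got {self.tensor.shape[2]}")


def msa_profile(msa: MSA, log_odds: bool = False) -> SequenceFeatureSet:
    """Weighted per-column frequencies over the 20 residues (gap excluded).

    Columns that are all-gap get a uniform profile row. With ``log_odds``,
    rows become log((f + eps) / background) against a uniform background.
    """
    if msa.weights is None:
        raise ValueError("compute_weights must run before msa_profile")
    fi, _ = column_frequencies(msa, pseudocount=0.0)
    f20 = fi[:, :GAP_INDEX]
    totals = f20.sum(axis=1, keepdims=True)
    prof = np.where(totals > 0, f20 / np.where(totals > 0, totals, 1.0),
                    1.0 / 20.0)
    if log_odds:
        prof = np.log((prof + 1e-4) / (1.0 / 20.0))
    return SequenceFeatureSet(profile=prof)


def msa_feature_substitutes(msa: MSA) -> SequenceFeatureSet:
    """MSA-derived stand-ins for external PSI-BLAST/PSIPRED features.

    Secondary structure defaults to uniform 1/3 probabilities; solvent
    accessibility to min-max-scaled mean column hydropathy (buried ~ 0).
    Documented placeholders so the pipeline runs with no external binaries.
    """
    fs = msa_profile(msa)
    L = fs.profile.shape[0]
    ss = np.full((L, 3), 1.0 / 3.0)
    hyd = fs.profile @ HYDROPATHY[:20]
    rng_ = hyd.max() - hyd.min()
    sa = ((hyd - hyd.min()) / rng_ if rng_ > 0 else np.full(L, 0.5))
    return SequenceFeatureSet(profile=fs.profile, secondary_structure=ss,
                              solvent_accessibility=sa[:, None])


def pairwise_expand(onedim: np.ndarray) -> np.ndarray:
    """Expand an (L, k) feature to (L, L, 2k): cell (i, j) = [f(i), f(j)]."""
    onedim = np.atleast_2d(np.asarray(onedim, dtype=float))
    if onedim.ndim != 2:
        raise ValueError("input must be (L, k)")
    L, k = onedim.shape
    left = np.broadcast_to(onedim[:, None, :], (L, L, k))
    right = np.broadcast_to(onedim[None, :, :], (L, L, k))
    return np.concatenate([left, right], axis=2)


def read_pssm_table(path: str) -> SequenceFeatureSet:
    """Whitespace-table adapter for external PSI-BLAST-style profiles (L x 20)."""
    arr = np.loadtxt(path)
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 20:
        raise ValueError(f"profile table must have 20 columns, got {arr.shape[1]}")
    return SequenceFeatureSet(profile=arr, source="external-file")


def read_ss_table(path: str) -> np.ndarray:
    """Whitespace-table adapter for 3-state secondary-structure probabilities."""
    arr = np.atleast_2d(np.loadtxt(path))
    if arr.shape[1] != 3:
        raise ValueError("secondary-structure table must have 3 columns")
    return arr


def _stack(named: list[tuple[str, np.ndarray]]) -> tuple[np.ndarray, list[str]]:
    Ls = {a.shape[0] for _, a in named} | {a.shape[1] for _, a in named}
    if len(Ls) != 1:
        raise AssemblyError(f"inconsistent L among blocks: {sorted(Ls)}")
    manifest: list[str] = []
    parts: list[np.ndarray] = []
    for name, arr in named:
        if arr.ndim == 2:
            arr = arr[:, :, None]
        parts.append(arr)
        c = arr.shape[2]
        manifest.extend([name] if c == 1 else [f"{name}[{i}]" for i in range(c)])
    tensor = np.concatenate(parts, axis=2)
    if not np.all(np.isfinite(tensor)):
        raise AssemblyError("non-finite values in assembled tensor")
    return tensor, manifest


def assemble_branch_input(branch: str, *, pair_block: PairChannelBlock | None,
                          features: SequenceFeatureSet,
                          stats: dict[str, PairChannelBlock],
                          contact_score: PairChannelBlock | None = None,
                          column_entropy_values: np.ndarray | None = None
                          ) -> BranchInput:
    """Stack the blocks a branch network expects, in manifest order."""
    if branch not in BRANCHES:
        raise AssemblyError(f"unknown branch {branch!r}")
    prof2d = pairwise_expand(features.profile)
    named: list[tuple[str, np.ndarray]]
    if branch == "COV":
        if pair_block is None or contact_score is None:
            raise AssemblyError("COV branch needs the COV block and contact score")
        named = [("COV", pair_block.as_channels()),
                 ("profile", prof2d),
                 ("contact_score", contact_score.values),
                 ("pearson", stats["pearson_correlation"].values)]
    elif branch == "PLM":
        if pair_block is None:
            raise AssemblyError("PLM branch needs the PLM block")
        named = [("PLM", pair_block.as_channels()),
                 ("profile", prof2d),
                 ("pearson", stats["pearson_correlation"].values)]
    elif branch == "PRE":
        if pair_block is None or column_entropy_values is None:
            raise AssemblyError("PRE branch needs the PRE block and entropies")
        named = [("PRE", pair_block.as_channels()),
                 ("profile", prof2d),
                 ("joint_entropy", stats["joint_entropy"].values),
                 ("entropy", pairwise_expand(column_entropy_values[:, None]))]
    else:  # OTHER
        L = features.profile.shape[0]
        ss = (features.secondary_structure
              if features.secondary_structure is not None
              else np.full((L, 3), 1.0 / 3.0))
        sa = (features.solvent_accessibility
              if features.solvent_accessibility is not None
              else np.full((L, 1), 0.5))
        named = [("profile", prof2d),
                 ("ss", pairwise_expand(ss)),
                 ("sa", pairwise_expand(sa)),
                 ("mi", stats["mutual_information"].values),
                 ("nmi", stats["normalized_mi"].values),
                 ("joint_entropy", stats["joint_entropy"].values),
                 ("entropy_sum", stats["shannon_entropy_sum"].values),
                 ("pearson", stats["pearson_correlation"].values)]
    tensor, manifest = _stack(named)
    return BranchInput(branch=branch, tensor=tensor, channel_manifest=manifest)


def compute_branch_inputs(msa: MSA, branches: tuple[str, ...] = BRANCHES,
                          pseudocount: float = 1.0,
                          features: SequenceFeatureSet | None = None,
                          shrinkage: float = 0.1,
                          plm_budget: int = 100,
                          ) -> dict[str, BranchInput]:
    """End-to-end feature pipeline: MSA -> all requested branch inputs."""
    if msa.weights is None:
        raise ValueError("compute_weights must run before feature assembly")
    fi, fij = column_frequencies(msa, pseudocount=pseudocount)
    stats = information_statistics(fi, fij, msa)
    if features is None:
        features = msa_feature_substitutes(msa)
    ent = column_entropy(fi)
    out: dict[str, BranchInput] = {}
    cov = covariance_tensor(fi, fij) if {"COV", "PRE"} & set(branches) else None
    plm = (plm_tensor(msa, optimizer_budget=plm_budget)
           if {"COV", "PLM"} & set(branches) else None)
    score = coupling_contact_score(plm) if plm is not None else None
    for b in branches:
        if b == "COV":
            out[b] = assemble_branch_input("COV", pair_block=cov,
                                           features=features, stats=stats,
                                           contact_score=score)
        elif b == "PLM":
            out[b] = assemble_branch_input("PLM", pair_block=plm,
                                           features=features, stats=stats)
        elif b == "PRE":
            pre = precision_tensor(cov, shrinkage=shrinkage)
            out[b] = assemble_branch_input("PRE", pair_block=pre,
                                           features=features, stats=stats,
                                           column_entropy_values=ent)
        else:
            out[b] = assemble_branch_input("OTHER", pair_block=None,
                                           features=features, stats=stats)
    return out
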