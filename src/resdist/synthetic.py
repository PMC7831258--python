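"""Synthetic fixtures: compact toy backbones and covariation-bearing MSAs.

Structures are seeded self-avoiding chains (~3.8 Å steps) confined to a
sphere so that long-range contacts exist. MSAs are sampled from a 21-state
Potts model whose couplings are planted only on selected long-range contact
pairs of the structure, so recovery by DCA-style features is unambiguous.

All randomness flows from one seed through a documented splitting scheme
(``numpy`` ``SeedSequence.spawn`` per target / per component).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .alphabet import GAP_INDEX, N_STATES
from .distmaps import DEFAULT_BINS
from .features import BranchInput, compute_branch_inputs
from .msa import MSA, compute_weights
from .training import TrainingTarget

STEP_LENGTH = 3.8
MIN_STEP, MAX_STEP = 3.0, 4.5
SELF_AVOID = 3.0
CONTACT_CUTOFF = 8.0

#: Gibbs sampling defaults: independent parallel chains, each burnt in.
BURN_IN_SWEEPS = 200
THIN = 5


@dataclass
class ToyStructure:
    """Toy backbone: Cβ coordinates, derived distance map and contact set."""

    length: int
    coordinates: np.ndarray  # (L, 3) Å
    seed: int

    @property
    def distance_map(self) -> np.ndarray:
        diff = self.coordinates[:, None, :] - self.coordinates[None, :, :]
        return np.sqrt((diff ** 2).sum(axis=2))

    def contacts(self, threshold: float = CONTACT_CUTOFF,
                 min_sep: int = 1) -> list[tuple[int, int]]:
        d = self.distance_map
        L = self.length
        return [(i, j) for i in range(L) for j in range(i + min_sep, L)
                if d[i, j] <= threshold]


@dataclass
class PottsModel:
    """Pairwise 21-state model with couplings planted on selected pairs."""

    fields: np.ndarray  # (L, 21)
    couplings: dict[tuple[int, int], np.ndarray]  # {(i<j): (21, 21)}
    coupling_strength: float
    seed: int = 0

    def __post_init__(self) -> None:
        for (i, j), J in self.couplings.items():
            if i >= j:
                raise ValueError("coupling keys must satisfy i < j")
            if J.shape != (N_STATES, N_STATES):
                raise ValueError("couplings must be 21 x 21")


def generate_structure(L: int, seed: int, retry_budget: int = 200
                       ) -> ToyStructure:
    """Seeded self-avoiding chain confined to a compact sphere.

    Consecutive distances stay within [3.0, 4.5] Å; non-adjacent residues
    keep >= 3.0 Å separation. The confinement radius ~ 3.4 * L^(1/3) makes
    long-range contacts common, mimicking globular packing.
    """
    if L < 5:
        raise ValueError("L must be >= 5")
    radius = 3.4 * L ** (1.0 / 3.0)
    rng = np.random.default_rng(np.random.SeedSequence((seed, L, 0xC0DE)))
    for _ in range(retry_budget):
        coords = np.zeros((L, 3))
        ok = True
        for r in range(1, L):
            placed = False
            for _ in range(300):
                step = rng.normal(size=3)
                step *= STEP_LENGTH / np.linalg.norm(step)
                cand = coords[r - 1] + step
                # soft pull toward the sphere to keep the chain compact
                if np.linalg.norm(cand) > radius:
                    continue
                if r >= 2:
                    d = np.linalg.norm(coords[:r - 1] - cand, axis=1)
                    if d.min() < SELF_AVOID:
                        continue
                coords[r] = cand
                placed = True
                break
            if not placed:
                ok = False
                break
        if ok:
            return ToyStructure(length=L, coordinates=coords, seed=seed)
    raise RuntimeError(
        "structure placement failed; increase retry_budget or L")


def _planted_coupling(strength: float) -> np.ndarray:
    """Low-rank favored-pair coupling: two mutually attracted symbol groups.

    Non-gap states split into two halves; same-group pairs get +strength,
    cross-group pairs -strength, gap states 0. Symmetric under the
    (i,a) <-> (j,b) transpose rule by construction.
    """
    g = np.zeros(N_STATES)
    g[:10] = 1.0
    g[10:20] = -1.0  # gap stays 0
    return strength * np.outer(g, g)


def build_potts(structure: ToyStructure, coupling_strength: float,
                n_planted: int | None = None, seed: int = 0,
                min_sep: int = 6, prefer_sep: int = 24) -> PottsModel:
    """Potts model with couplings planted on the structure's contacts.

    Long-range contacts (separation >= ``prefer_sep``) are planted first so
    the covariation signal is visible to long-range evaluation metrics;
    shorter-range contacts (>= ``min_sep``) fill any remainder.
    """
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xAB)))
    far = structure.contacts(min_sep=prefer_sep)
    near = [c for c in structure.contacts(min_sep=min_sep) if c not in set(far)]
    rng.shuffle(far)
    rng.shuffle(near)
    contacts = far + near
    if n_planted is not None:
        contacts = contacts[:n_planted]
    J = _planted_coupling(coupling_strength)
    couplings = {(i, j): J.copy() for i, j in contacts}
    h = 0.1 * rng.normal(size=(structure.length, N_STATES))
    h[:, GAP_INDEX] = -4.0  # keep gaps rare
    return PottsModel(fields=h, couplings=couplings,
                      coupling_strength=coupling_strength, seed=seed)


def sample_potts(model: PottsModel, n_sequences: int, seed: int,
                 burn_in: int = BURN_IN_SWEEPS, thin: int = THIN
                 ) -> np.ndarray:
    """Gibbs sampling: ``n_sequences`` independent parallel chains.

    Each chain is burnt in for ``burn_in`` full sweeps and its final state
    taken as one sample (``thin`` extra sweeps separate repeated draws if a
    chain must produce more than one sample; with parallel chains it never
    does). Deterministic per seed.
    """
    L = model.fields.shape[0]
    rng = np.random.default_rng(np.random.SeedSequence((seed, n_sequences, L)))
    # partner lists per site
    partners: list[list[tuple[int, np.ndarray]]] = [[] for _ in range(L)]
    for (i, j), J in model.couplings.items():
        partners[i].append((j, J))
        partners[j].append((i, J.T))
    rows = rng.integers(0, N_STATES - 1, size=(n_sequences, L))  # no gaps init
    for _ in range(burn_in):
        for i in range(L):
            logits = np.broadcast_to(model.fields[i],
                                     (n_sequences, N_STATES)).copy()
            for j, J in partners[i]:
                logits += J[:, rows[:, j]].T
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random(n_sequences)
            rows[:, i] = (p.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return rows.astype(np.int8)


def simulate_msa(structure: ToyStructure, n_sequences: int,
                 coupling_strength: float, seed: int,
                 n_planted: int | None = None,
                 burn_in: int = BURN_IN_SWEEPS) -> tuple[MSA, PottsModel]:
    """MSA whose covarying column pairs are exactly the planted pairs."""
    if n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    model = build_potts(structure, coupling_strength,
                        n_planted=n_planted, seed=seed)
    rows = sample_potts(model, n_sequences, seed=seed + 1, burn_in=burn_in)
    msa = MSA(identifiers=[f"s{i}" for i in range(n_sequences)], rows=rows)
    return compute_weights(msa), model


def potts_marginals(model: PottsModel, site: int) -> np.ndarray:
    """Exact single-site marginal for an uncoupled site: softmax(h_i)."""
    h = model.fields[site]
    e = np.exp(h - h.max())
    return e / e.sum()


@dataclass
class DatasetManifest:
    seed: int
    targets: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({"seed": self.seed, "targets": self.targets},
                          indent=1, sort_keys=True)


def make_dataset(n_targets: int, L_range: tuple[int, int] = (30, 30),
                 n_sequences: int = 80, coupling_strength: float = 1.5,
                 n_planted: int = 10, seed: int = 0,
                 branches: tuple[str, ...] = ("COV",),
                 burn_in: int = 50, plm_budget: int = 60, pseudocount: float = 1.0
                 ) -> tuple[list[dict[str, BranchInput]], list[TrainingTarget],
                            DatasetManifest]:
    """Deterministic paired (branch inputs, training target) fixtures.

    Per-target seeds derive from the master seed via SeedSequence.spawn;
    the manifest records them so any target is independently reproducible.
    """
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0]) % (2 ** 31)
                   for s in ss.spawn(n_targets)]
    rng = np.random.default_rng(ss)
    inputs: list[dict[str, BranchInput]] = []
    targets: list[TrainingTarget] = []
    manifest = DatasetManifest(seed=seed)
    for t, tseed in enumerate(child_seeds):
        L = int(rng.integers(L_range[0], L_range[1] + 1))
        structure = generate_structure(L, seed=tseed)
        msa, model = simulate_msa(structure, n_sequences, coupling_strength,
                                  seed=tseed, n_planted=n_planted,
                                  burn_in=burn_in)
        binputs = compute_branch_inputs(msa, branches=branches,
                                        pseudocount=pseudocount,
                                        plm_budget=plm_budget)
        d = structure.distance_map
        targets.append(TrainingTarget.from_distances(d, DEFAULT_BINS))
        inputs.append(binputs)
        manifest.targets.append({
            "index": t, "seed": tseed, "L": L, "n_sequences": n_sequences,
            "coupling_strength": coupling_strength,
            "n_planted_pairs": len(model.couplings),
        })
    return inputs, targets, manifest
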