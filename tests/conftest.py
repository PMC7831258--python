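"""Shared fixtures. Heavy synthetic-data / training fixtures are
session-scoped so the acceptance tests and property tests share one
computation."""

from __future__ import annotations

import numpy as np
import pytest

from resdist.features import compute_branch_inputs
from resdist.msa import MSA, compute_weights
from resdist.nn.networks import NetworkSpec, build_network
from resdist.synthetic import generate_structure, make_dataset, simulate_msa
from resdist.training import Schedule, train


def msa_from_strings(seqs: list[str]) -> MSA:
    from resdist.alphabet import encode, sanitize
    rows = np.stack([encode(sanitize(s)) for s in seqs])
    return MSA(identifiers=[f"s{i}" for i in range(len(seqs))], rows=rows)


@pytest.fixture()
def toy_msa() -> MSA:
    return compute_weights(msa_from_strings(
        ["ACDEF", "ACDEF", "ACDGH", "KLMNP"]))


@pytest.fixture(scope="session")
def random_small_msa() -> MSA:
    rng = np.random.default_rng(123)
    rows = rng.integers(0, 21, size=(12, 8))
    return compute_weights(MSA(identifiers=[f"r{i}" for i in range(12)],
                               rows=rows))


@pytest.fixture(scope="session")
def potts_fixture():
    """L=30 structure + 500-sequence planted-coupling MSA (seeded)."""
    structure = generate_structure(30, seed=1)
    msa, model = simulate_msa(structure, 500, coupling_strength=1.5,
                              seed=2, n_planted=10)
    return structure, msa, model


@pytest.fixture(scope="session")
def potts_plm(potts_fixture):
    from resdist.coevolution import plm_tensor
    _, msa, _ = potts_fixture
    return plm_tensor(msa, optimizer_budget=100)


@pytest.fixture(scope="session")
def feature_msa_fixture():
    """Small MSA plus all four assembled branch inputs."""
    structure = generate_structure(16, seed=3)
    msa, _ = simulate_msa(structure, 40, coupling_strength=1.0, seed=4,
                          burn_in=30)
    binputs = compute_branch_inputs(msa, plm_budget=40)
    return msa, binputs


@pytest.fixture(scope="session")
def synthetic_dataset():
    """13 targets (L=30): inputs 0-9 train, 10-12 held out."""
    inputs, targets, manifest = make_dataset(
        13, L_range=(30, 30), n_sequences=80, coupling_strength=1.5,
        n_planted=10, seed=42, branches=("COV",), burn_in=50, plm_budget=60)
    dataset = [(bi["COV"], tg) for bi, tg in zip(inputs, targets)]
    return dataset, manifest


@pytest.fixture(scope="session")
def trained_tiny_model(synthetic_dataset):
    """Reduced COV model (width 16, 2 blocks) trained 20 epochs on 10 targets."""
    dataset, _ = synthetic_dataset
    train_set, val_set = dataset[:10], dataset[10:]
    spec = NetworkSpec(branch="COV", input_channels=483, trunk_width=16,
                       residual_blocks=2, seed=3)
    model = build_network(spec)
    result = train(model, train_set, Schedule(epochs=20, seed=7),
                   validation=val_set)
    return model, result, train_set, val_set
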