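import numpy as np
import pytest

from resdist.alphabet import ALPHABET, GAP_INDEX
from resdist.coevolution import (PairChannelBlock, apc_correct,
                                 column_entropy, coupling_contact_score,
                                 covariance_tensor, information_statistics,
                                 load_contact_potential, plm_tensor,
                                 precision_tensor, _plm_objective)
from resdist.msa import MSA, column_frequencies, compute_weights
from conftest import msa_from_strings

Q = 21


# ---------------------------------------------------------------------------
# COV

def test_cov_zero_for_identical_rows():
    msa = compute_weights(msa_from_strings(["ACDE"] * 4))
    fi, fij = column_frequencies(msa, pseudocount=0.0)
    cov = covariance_tensor(fi, fij)
    np.testing.assert_allclose(cov.values, 0.0, atol=1e-12)


def test_cov_hand_arithmetic():
    # two perfectly correlated columns in a 2-row MSA
    msa = compute_weights(msa_from_strings(["AC", "DE"]))
    fi, fij = column_frequencies(msa, pseudocount=0.0)
    cov = covariance_tensor(fi, fij)
    a, c = ALPHABET.index("A"), ALPHABET.index("C")
    # f_12(A,C)=0.5, f_1(A)=0.5, f_2(C)=0.5 -> 0.5 - 0.25 = 0.25
    assert cov.values[0, 1, a, c] == pytest.approx(0.25)


def test_cov_matches_elementwise_oracle(random_small_msa):
    fi, fij = column_frequencies(random_small_msa, pseudocount=0.3)
    cov = covariance_tensor(fi, fij)
    L = fi.shape[0]
    for i in range(L):
        for j in range(L):
            np.testing.assert_allclose(
                cov.values[i, j], fij[i, j] - np.outer(fi[i], fi[j]),
                atol=1e-12)


def test_cov_transpose_symmetry(random_small_msa):
    fi, fij = column_frequencies(random_small_msa, pseudocount=0.3)
    covariance_tensor(fi, fij).check()


# ---------------------------------------------------------------------------
# PRE

def _block_from_matrix(M: np.ndarray, L: int) -> PairChannelBlock:
    v = M.reshape(L, Q, L, Q).transpose(0, 2, 1, 3)
    return PairChannelBlock("COV", v, "pair-state")


def test_pre_identity_inverse():
    L = 2
    cov = _block_from_matrix(np.eye(L * Q), L)
    pre = precision_tensor(cov, shrinkage=0.0)
    np.testing.assert_allclose(
        pre.values.transpose(0, 2, 1, 3).reshape(L * Q, L * Q), np.eye(L * Q),
        atol=1e-12)


def test_pre_diagonal_closed_form():
    L = 2
    cov = _block_from_matrix(2.0 * np.eye(L * Q), L)
    pre = precision_tensor(cov, shrinkage=0.0)
    M = pre.values.transpose(0, 2, 1, 3).reshape(L * Q, L * Q)
    np.testing.assert_allclose(np.diag(M), 0.5, atol=1e-12)


def test_pre_inverse_consistency_toy_msa():
    msa = compute_weights(msa_from_strings(["AC", "AD", "CE", "CA"]))
    fi, fij = column_frequencies(msa, pseudocount=1.0)
    cov = covariance_tensor(fi, fij)
    lam = 0.1
    pre = precision_tensor(cov, shrinkage=lam)
    L = 2
    C = cov.values.transpose(0, 2, 1, 3).reshape(L * Q, L * Q)
    shrunk = (1 - lam) * C + lam * np.diag(np.diag(C))
    P = pre.values.transpose(0, 2, 1, 3).reshape(L * Q, L * Q)
    np.testing.assert_allclose(shrunk @ P, np.eye(L * Q), atol=1e-8)


def test_pre_singular_raises():
    L = 2
    cov = _block_from_matrix(np.zeros((L * Q, L * Q)), L)
    with pytest.raises(np.linalg.LinAlgError, match="shrinkage"):
        precision_tensor(cov, shrinkage=0.0)


# ---------------------------------------------------------------------------
# PLM

def test_plm_gradient_matches_finite_differences():
    rng = np.random.default_rng(9)
    msa = compute_weights(MSA(identifiers=list("abcde"),
                              rows=rng.integers(0, 21, size=(5, 3))))
    n, L = 5, 3
    onehot = np.zeros((n, L, Q))
    onehot[np.arange(n)[:, None], np.arange(L)[None, :], msa.rows] = 1.0
    onehot_flat = onehot.reshape(n, L * Q)
    mask = np.ones((L, L)) - np.eye(L)
    mask_flat = np.repeat(np.repeat(mask, Q, axis=0), Q, axis=1)
    theta = 0.1 * rng.normal(size=L * Q + (L * Q) ** 2)
    theta[L * Q:] *= mask_flat.ravel()
    f0, g = _plm_objective(theta, onehot_flat, msa.weights, L, 0.01, 0.2,
                           mask_flat)
    eps = 1e-5
    idxs = rng.choice(theta.size, size=60, replace=False)
    for i in idxs:
        t = theta.copy()
        t[i] += eps
        fp = _plm_objective(t, onehot_flat, msa.weights, L, 0.01, 0.2,
                            mask_flat)[0]
        t[i] -= 2 * eps
        fm = _plm_objective(t, onehot_flat, msa.weights, L, 0.01, 0.2,
                            mask_flat)[0]
        fd = (fp - fm) / (2 * eps)
        assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)


def test_plm_objective_non_increasing():
    rng = np.random.default_rng(3)
    msa = compute_weights(MSA(identifiers=[str(i) for i in range(30)],
                              rows=rng.integers(0, 21, size=(30, 4))))
    _, trace = plm_tensor(msa, optimizer_budget=40, return_trace=True)
    assert len(trace) > 2
    assert all(b <= a + 1e-9 for a, b in zip(trace, trace[1:]))


def test_plm_null_vs_planted(potts_fixture):
    # i.i.d. uniform columns: couplings stay regularization-dominated,
    # strictly below the planted-coupling maximum
    rng = np.random.default_rng(7)
    lam = 0.2 * (30 - 1)  # match the planted case so the bound is comparable
    null = compute_weights(MSA(identifiers=[str(i) for i in range(200)],
                               rows=rng.integers(0, 20, size=(200, 6))))
    null_plm = plm_tensor(null, l2_couplings=lam, optimizer_budget=80)
    null_norms = np.sqrt((null_plm.values ** 2).sum(axis=(2, 3)))

    plm = plm_tensor(potts_fixture[1], l2_couplings=lam,
                     optimizer_budget=100)
    norms = np.sqrt((plm.values ** 2).sum(axis=(2, 3)))
    assert null_norms.max() < norms.max()


def test_plm_symmetry(potts_plm):
    potts_plm.check()


def test_planted_pair_has_largest_coupling(potts_fixture, potts_plm):
    _, _, model = potts_fixture
    norms = np.sqrt((potts_plm.values ** 2).sum(axis=(2, 3)))
    np.fill_diagonal(norms, 0.0)
    i, j = np.unravel_index(norms.argmax(), norms.shape)
    assert (min(i, j), max(i, j)) in model.couplings


def test_apc_recovery_precision(potts_fixture, potts_plm):
    """Top-L/5 APC coupling-score precision >= 0.6 on planted contacts,
    strictly above the expected random precision."""
    structure, _, model = potts_fixture
    score = coupling_contact_score(potts_plm, apc=True).values
    L = 30
    truth = structure.distance_map
    iu, ju = np.triu_indices(L, k=6)
    order = np.argsort(-score[iu, ju])[: L // 5]
    hits = truth[iu[order], ju[order]] <= 8.0
    random_precision = (truth[iu, ju] <= 8.0).mean()
    assert hits.mean() >= 0.6
    assert hits.mean() > random_precision


# ---------------------------------------------------------------------------
# APC / contact score

def test_contact_score_zero_couplings():
    L = 4
    plm = PairChannelBlock("PLM", np.zeros((L, L, Q, Q)), "pair-state")
    assert np.all(coupling_contact_score(plm).values == 0)


def test_apc_annihilates_rank_one():
    u = np.array([1.0, 2.0, 3.0, 4.0])
    S = np.outer(u, u)
    np.testing.assert_allclose(apc_correct(S), 0.0, atol=1e-12)


def test_apc_hand_arithmetic():
    S = np.array([[0.0, 1.0, 2.0],
                  [1.0, 0.0, 3.0],
                  [2.0, 3.0, 0.0]])
    expected = S - np.outer(S.sum(1), S.sum(0)) / S.sum()
    np.testing.assert_allclose(apc_correct(S), expected, atol=1e-12)


# ---------------------------------------------------------------------------
# information statistics

def test_mi_zero_for_independent_columns():
    # product frequencies constructed directly
    rng = np.random.default_rng(0)
    L = 3
    fi = rng.dirichlet(np.ones(Q), size=L)
    fij = fi[:, None, :, None] * fi[None, :, None, :]
    for i in range(L):
        fij[i, i] = np.diag(fi[i])
    stats = information_statistics(fi, fij)
    mi = stats["mutual_information"].values
    off = mi[~np.eye(L, dtype=bool)]
    np.testing.assert_allclose(off, 0.0, atol=1e-12)


def test_mi_identical_two_state_columns():
    msa = compute_weights(msa_from_strings(["AA", "CC"]))
    fi, fij = column_frequencies(msa, pseudocount=0.0)
    stats = information_statistics(fi, fij, msa)
    assert stats["mutual_information"].values[0, 1] == pytest.approx(np.log(2))
    assert stats["joint_entropy"].values[0, 1] == pytest.approx(np.log(2))
    assert stats["normalized_mi"].values[0, 1] == pytest.approx(1.0)


def test_mi_matches_brute_force(random_small_msa):
    fi, fij = column_frequencies(random_small_msa, pseudocount=0.5)
    stats = information_statistics(fi, fij, random_small_msa)
    L = fi.shape[0]
    i, j = 1, 5
    mi = 0.0
    for a in range(Q):
        for b in range(Q):
            p = fij[i, j, a, b]
            if p > 0:
                mi += p * np.log(p / (fi[i, a] * fi[j, b]))
    assert stats["mutual_information"].values[i, j] == pytest.approx(
        mi, abs=1e-12)


def test_mi_bounds(random_small_msa):
    fi, fij = column_frequencies(random_small_msa, pseudocount=0.5)
    stats = information_statistics(fi, fij, random_small_msa)
    mi = stats["mutual_information"].values
    Hi = column_entropy(fi)
    assert np.all(mi >= 0)
    bound = np.minimum(Hi[:, None], Hi[None, :]) + 1e-9
    off = ~np.eye(fi.shape[0], dtype=bool)
    assert np.all(mi[off] <= bound[off])


def test_all_stat_blocks_symmetric(random_small_msa):
    fi, fij = column_frequencies(random_small_msa, pseudocount=0.5)
    for block in information_statistics(fi, fij, random_small_msa).values():
        block.check()


def test_contact_potential_table():
    U = load_contact_potential()
    assert U.shape == (20, 20)
    np.testing.assert_allclose(U, U.T, atol=1e-12)
    # hydrophobic pair (I, I) attractive; opposite signs repel
    i = ALPHABET.index("I")
    d = ALPHABET.index("D")
    assert U[i, i] < 0
    assert U[i, d] > 0


def test_entropy_sum_channel(random_small_msa):
    fi, fij = column_frequencies(random_small_msa, pseudocount=0.5)
    stats = information_statistics(fi, fij, random_small_msa)
    Hi = column_entropy(fi)
    np.testing.assert_allclose(stats["shannon_entropy_sum"].values,
                               Hi[:, None] + Hi[None, :], atol=1e-12)
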