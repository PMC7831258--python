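"""Co-evolutionary pair tensors (COV, PRE, PLM) and scalar 2-D statistics.

The three 441-channel tensors satisfy the transpose rule
``T[i, j, a, b] == T[j, i, b, a]``; scalar statistics are symmetric L x L
matrices. The PLM tensor is the coupling matrix of a 21-state Potts model
fitted by weighted, L2-regularized pseudolikelihood maximization.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .alphabet import ALPHABET, GAP_INDEX, HYDROPATHY, N_STATES
from .msa import MSA

Q = N_STATES


@dataclass
class PairChannelBlock:
    """Named L x L x k feature block with its transpose symmetry rule.

    ``values`` has shape (L, L, Q, Q) for COV/PRE/PLM blocks and (L, L)
    for scalar statistics. ``symmetric_under`` is ``"pair-state"`` for the
    former (swap i,j and a,b together) and ``"transpose"`` for the latter.
    """

    name: str
    values: np.ndarray
    symmetric_under: str

    @property
    def n_channels(self) -> int:
        return 1 if self.values.ndim == 2 else Q * Q

    def as_channels(self) -> np.ndarray:
        """View as (L, L, k) with k = 441 or 1."""
        v = self.values
        if v.ndim == 2:
            return v[:, :, None]
        L = v.shape[0]
        return v.reshape(L, L, Q * Q)

    def check(self, atol: float = 1e-9) -> None:
        v = self.values
        if not np.all(np.isfinite(v)):
            raise ValueError(f"non-finite values in block {self.name}")
        if v.ndim == 4:
            np.testing.assert_allclose(v, v.transpose(1, 0, 3, 2), atol=atol)
        else:
            np.testing.assert_allclose(v, v.T, atol=atol)


# ---------------------------------------------------------------------------
# COV / PRE

def covariance_tensor(fi: np.ndarray, fij: np.ndarray) -> PairChannelBlock:
    """C_ij(a,b) = f_ij(a,b) - f_i(a) * f_j(b)."""
    cov = fij - fi[:, None, :, None] * fi[None, :, None, :]
    return PairChannelBlock("COV", cov, "pair-state")


def precision_tensor(cov: PairChannelBlock,
                     shrinkage: float = 0.1) -> PairChannelBlock:
    """Inverse of the shrunk covariance matrix, reshaped to L x L x 441.

    The (21L) x (21L) covariance matrix is shrunk toward its own diagonal,
    ``(1 - lam) * C + lam * diag(C)``, then inverted.
    """
    if not 0 <= shrinkage <= 1:
        raise ValueError("shrinkage must be in [0, 1]")
    v = cov.values
    L = v.shape[0]
    C = v.transpose(0, 2, 1, 3).reshape(L * Q, L * Q)
    shrunk = (1.0 - shrinkage) * C + shrinkage * np.diag(np.diag(C))
    try:
        P = np.linalg.inv(shrunk)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "covariance matrix is singular; use a nonzero shrinkage"
        ) from exc
    P = 0.5 * (P + P.T)
    pre = P.reshape(L, Q, L, Q).transpose(0, 2, 1, 3)
    return PairChannelBlock("PRE", pre, "pair-state")


# ---------------------------------------------------------------------------
# PLM

def _plm_objective(theta, onehot_flat, w, L, lam_h, lam_j, mask_flat):
    """Weighted negative log pseudolikelihood + L2, with analytic gradient.

    Parameters are the fields h (L, Q) and the full asymmetric coupling
    tensor J (L, Q, L, Q) with diagonal site blocks masked to zero.
    """
    n = onehot_flat.shape[0]
    h = theta[: L * Q].reshape(L, Q)
    J = (theta[L * Q:].reshape(L * Q, L * Q)) * mask_flat
    # logits[n, i, a] = h[i, a] + sum_j J[(i,a),(j,b)] x[n, j, b]
    logits = onehot_flat @ J.T  # (n, L*Q)
    logits = logits.reshape(n, L, Q) + h[None]
    lse = logsumexp(logits, axis=2)  # (n, L)
    x_logit = np.einsum("nia,nia->ni",
                        logits, onehot_flat.reshape(n, L, Q))
    nll = float(np.sum(w[:, None] * (lse - x_logit)))
    obj = nll + lam_h * float(np.sum(h * h)) + 0.5 * lam_j * float(np.sum(J * J))

    p = np.exp(logits - lse[:, :, None])  # (n, L, Q) conditional probs
    G = w[:, None, None] * (p - onehot_flat.reshape(n, L, Q))
    gh = G.sum(axis=0) + 2.0 * lam_h * h
    gJ = G.reshape(n, L * Q).T @ onehot_flat  # (L*Q, L*Q)
    gJ = (gJ + lam_j * J) * mask_flat
    return obj, np.concatenate([gh.ravel(), gJ.ravel()])


def plm_tensor(msa: MSA, l2_couplings: float | None = None,
               l2_fields: float = 0.01, optimizer_budget: int = 200,
               return_trace: bool = False) -> PairChannelBlock:
    """Potts couplings by pseudolikelihood maximization (L-BFGS).

    Defaults follow the CCMpred-family convention: coupling penalty
    ``0.2 * (L - 1)``, field penalty ``0.01``. The asymmetric per-site
    estimates are symmetrized on return:
    ``J'_ij(a, b) = (J_ij(a, b) + J_ji(b, a)) / 2``.
    """
    if msa.weights is None:
        raise ValueError("compute_weights must run before plm_tensor")
    rows, w = msa.rows, msa.weights
    n, L = rows.shape
    if L < 2:
        raise ValueError("PLM requires L >= 2")
    lam_j = 0.2 * (L - 1) if l2_couplings is None else l2_couplings
    onehot = np.zeros((n, L, Q))
    onehot[np.arange(n)[:, None], np.arange(L)[None, :], rows] = 1.0
    onehot_flat = onehot.reshape(n, L * Q)

    mask = np.ones((L, L)) - np.eye(L)
    mask_flat = np.repeat(np.repeat(mask, Q, axis=0), Q, axis=1)

    theta0 = np.zeros(L * Q + (L * Q) ** 2)
    trace: list[float] = []

    def fun(theta):
        return _plm_objective(theta, onehot_flat, w, L,
                              l2_fields, lam_j, mask_flat)

    def cb(theta):
        trace.append(fun(theta)[0])

    res = minimize(fun, theta0, jac=True, method="L-BFGS-B",
                   callback=cb if return_trace else None,
                   options={"maxiter": optimizer_budget, "maxcor": 5})
    if not res.success and res.status != 1:  # 1 = iteration cap reached
        warnings.warn(f"PLM optimizer did not converge: {res.message}",
                      RuntimeWarning, stacklevel=2)
    J = res.x[L * Q:].reshape(L, Q, L, Q) * mask[:, None, :, None]
    J = J.transpose(0, 2, 1, 3)  # (L, L, Q, Q)
    J_sym = 0.5 * (J + J.transpose(1, 0, 3, 2))
    block = PairChannelBlock("PLM", J_sym, "pair-state")
    if return_trace:
        return block, trace
    return block


def apc_correct(S: np.ndarray) -> np.ndarray:
    """Average-product correction: S - S_i. * S_.j / S_.. (elementwise).

    Annihilates rank-one structure exactly: for S = u u^T the correction
    returns all zeros.
    """
    denom = S.sum()
    if denom == 0:
        return S.copy()
    return S - np.outer(S.sum(axis=1), S.sum(axis=0)) / denom


def coupling_contact_score(plm: PairChannelBlock,
                           apc: bool = True) -> PairChannelBlock:
    """Frobenius-norm coupling score with optional average-product correction.

    The norm runs over the 20 x 20 non-gap states; with ``apc`` the
    background S_i. * S_.j / S_.. term is subtracted. Diagonal zeroed.
    """
    J = plm.values
    L = J.shape[0]
    ng = [a for a in range(Q) if a != GAP_INDEX]
    S = np.sqrt(np.sum(J[:, :, ng][:, :, :, ng] ** 2, axis=(2, 3)))
    S[np.diag_indices(L)] = 0.0
    if apc:
        S = apc_correct(S)
    S[np.diag_indices(L)] = 0.0
    return PairChannelBlock("contact_score", S, "transpose")


# ---------------------------------------------------------------------------
# Scalar information statistics

def load_contact_potential() -> np.ndarray:
    """Bundled 20x20 quasi-potential U(a,b) in alphabet order."""
    ref = importlib.resources.files("resdist.data") / "contact_potential.tsv"
    rows = []
    header = None
    for line in ref.read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if header is None:
            header = parts[1:]
            continue
        rows.append([float(x) for x in parts[1:]])
    U = np.array(rows)
    order = [header.index(a) for a in ALPHABET[:20]]
    return U[np.ix_(order, order)]


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def information_statistics(fi: np.ndarray, fij: np.ndarray,
                           msa: MSA | None = None
                           ) -> dict[str, PairChannelBlock]:
    """MI, normalized MI, joint entropy, entropy sum, Pearson correlation,
    mean contact potential — each an L x L symmetric scalar block.

    Gap is treated as a 21st state in the entropy/MI sums (0*log 0 = 0).
    Pearson correlation uses the Kyte-Doolittle hydropathy encoding of
    columns (gap = 0), weighted by sequence weights; it requires ``msa``.
    The mean contact potential is sum_ab f_ij(a,b) U(a,b) over the 20
    non-gap states with the bundled table.
    """
    L = fi.shape[0]
    Hi = -np.sum(_xlogx(fi), axis=1)  # (L,)
    Hij = -np.sum(_xlogx(fij), axis=(2, 3))  # (L, L)
    prod = fi[:, None, :, None] * fi[None, :, None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where((fij > 0) & (prod > 0), fij / prod, 1.0)
    mi = np.sum(fij * np.log(ratio), axis=(2, 3))
    mi = np.maximum(0.5 * (mi + mi.T), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        nmi = np.where(Hij > 0, mi / Hij, 0.0)
    hsum = Hi[:, None] + Hi[None, :]

    U = load_contact_potential()
    mcp = np.einsum("ijab,ab->ij", fij[:, :, :20, :20], U)
    mcp = 0.5 * (mcp + mcp.T)

    if msa is not None:
        w = msa.weights if msa.weights is not None else np.ones(msa.n_sequences)
        enc = HYDROPATHY[msa.rows]  # (n, L)
        wn = w / w.sum()
        mu = wn @ enc
        centered = enc - mu
        cov = (centered * wn[:, None]).T @ centered
        sd = np.sqrt(np.clip(np.diag(cov), 0, None))
        denom = np.outer(sd, sd)
        with np.errstate(divide="ignore", invalid="ignore"):
            pearson = np.where(denom > 0, cov / denom, 0.0)
        np.fill_diagonal(pearson, 1.0)
        pearson = np.clip(0.5 * (pearson + pearson.T), -1.0, 1.0)
    else:
        pearson = np.zeros((L, L))

    blocks = {
        "mutual_information": mi,
        "normalized_mi": nmi,
        "joint_entropy": 0.5 * (Hij + Hij.T),
        "shannon_entropy_sum": hsum,
        "pearson_correlation": pearson,
        "mean_contact_potential": mcp,
    }
    return {k: PairChannelBlock(k, v, "transpose") for k, v in blocks.items()}


def column_entropy(fi: np.ndarray) -> np.ndarray:
    """Per-column Shannon entropy H_i over the 21 states."""
    return -np.sum(_xlogx(fi), axis=1)
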