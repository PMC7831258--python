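"""Multiple sequence alignments: readers, sequence weights, column counts.

An :class:`MSA` holds aligned rows over the fixed 21-letter alphabet
(insertions relative to the query removed), per-sequence weights from
identity clustering, and the effective sequence count ``neff``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np

from .alphabet import N_STATES, encode, sanitize

DEFAULT_IDENTITY_THRESHOLD = 0.8


class MSAFormatError(ValueError):
    """Raised on malformed alignment input."""


@dataclass
class MSA:
    """Aligned sequences with optional identity-based weights.

    Rows are stored as an ``(n, L)`` int8 index matrix over the alphabet.
    ``weights`` is None until :func:`compute_weights` has run; ``neff`` is
    the sum of weights.
    """

    identifiers: list[str]
    rows: np.ndarray
    query_index: int = 0
    weights: np.ndarray | None = None
    neff: float | None = None
    sequences: list[str] = field(default_factory=list, repr=False)

    @property
    def n_sequences(self) -> int:
        return self.rows.shape[0]

    @property
    def length(self) -> int:
        return self.rows.shape[1]

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.int8)
        if self.rows.ndim != 2 or self.rows.shape[1] < 1:
            raise MSAFormatError("alignment must be a nonempty 2-D row matrix")
        if self.rows.min() < 0 or self.rows.max() >= N_STATES:
            raise MSAFormatError("row indices outside the 21-letter alphabet")


def _from_strings(identifiers: list[str], seqs: list[str],
                  wildcard_policy: str = "gap") -> MSA:
    if not seqs:
        raise MSAFormatError("empty alignment")
    clean = [sanitize(s, wildcard_policy) for s in seqs]
    lengths = {len(s) for s in clean}
    if len(lengths) != 1:
        raise MSAFormatError(f"ragged alignment: row lengths {sorted(lengths)}")
    rows = np.stack([encode(s) for s in clean])
    return MSA(identifiers=identifiers, rows=rows, sequences=clean)


def _read_fasta_records(text: str) -> tuple[list[str], list[str]]:
    names: list[str] = []
    seqs: list[str] = []
    cur: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if names:
                seqs.append("".join(cur))
            names.append(line[1:].split()[0] if len(line) > 1 else "")
            cur = []
        else:
            cur.append(line)
    if names:
        seqs.append("".join(cur))
    return names, seqs


def read_msa(path: str | os.PathLike, format: str | None = None,
             wildcard_policy: str = "gap") -> MSA:
    """Read an alignment from FASTA, A3M or one-sequence-per-line ``aln``.

    For A3M, lowercase letters are insertion states relative to the query
    and are deleted. ``format=None`` infers from the file extension.
    Tolerates Windows and Unix line endings.
    """
    path = os.fspath(path)
    if format is None:
        ext = os.path.splitext(path)[1].lower().lstrip(".")
        format = {"fa": "fasta", "fasta": "fasta", "a3m": "a3m",
                  "aln": "aln"}.get(ext, "fasta")
    with open(path, "r", newline=None) as fh:
        text = fh.read()
    if not text.strip():
        raise MSAFormatError(f"empty alignment file: {path}")

    if format == "aln":
        seqs = [ln.strip() for ln in text.splitlines() if ln.strip()]
        names = [f"seq{i}" for i in range(len(seqs))]
        return _from_strings(names, seqs, wildcard_policy)
    if format == "fasta":
        names, seqs = _read_fasta_records(text)
        return _from_strings(names, seqs, wildcard_policy)
    if format == "a3m":
        names, raw = _read_fasta_records(text)
        seqs = ["".join(c for c in s if not c.islower()) for s in raw]
        return _from_strings(names, seqs, wildcard_policy)
    raise ValueError(f"unknown MSA format: {format!r}")


def compute_weights(msa: MSA,
                    identity_threshold: float = DEFAULT_IDENTITY_THRESHOLD
                    ) -> MSA:
    """Identity-clustering sequence weights (standard DCA preprocessing).

    weight(s) = 1 / |{t : fractional identity(s, t) >= threshold}|, with s
    counted in its own cluster. Identity is the fraction of columns where
    both sequences carry the same non-gap residue; any position involving a
    gap (including gap-gap) counts as a mismatch. ``neff`` = sum of weights.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    rows = msa.rows
    n, L = rows.shape
    # matches[s, t] = #{i : rows[s,i] == rows[t,i], neither a gap}
    matches = np.zeros((n, n), dtype=np.int32)
    for a in range(N_STATES - 1):  # gap never matches
        m = (rows == a).astype(np.int32)
        matches += m @ m.T
    frac = matches / float(L)
    # a sequence is always in its own cluster, even when gappy enough that
    # the gap-as-mismatch rule puts its self-identity below the threshold
    np.fill_diagonal(frac, 1.0)
    counts = (frac >= identity_threshold).sum(axis=1)
    weights = 1.0 / counts
    return replace(msa, weights=weights, neff=float(weights.sum()))


def column_frequencies(msa: MSA, pseudocount: float = 0.0
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Weighted, pseudocount-regularized column and column-pair frequencies.

    Returns ``(fi, fij)`` with shapes ``(L, 21)`` and ``(L, L, 21, 21)``.
    Each marginal and each pair table sums to 1; ``fij[i, j, a, b] ==
    fij[j, i, b, a]`` and ``fij[i, i, a, a] == fi[i, a]``.

    The pseudocount ``pc`` mixes the empirical tables toward uniform:
    ``fi = (counts + pc/21) / (neff + pc)`` and
    ``fij = (paircounts + pc/441) / (neff + pc)`` off-diagonal; the diagonal
    pair table is set from the marginals for exact diagonal consistency.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    if msa.weights is None:
        raise ValueError("compute_weights must run before column_frequencies")
    rows, w = msa.rows, msa.weights
    n, L = rows.shape
    q = N_STATES
    onehot = np.zeros((n, L, q))
    onehot[np.arange(n)[:, None], np.arange(L)[None, :], rows] = 1.0

    neff = float(w.sum())
    counts_i = np.einsum("s,sia->ia", w, onehot)
    fi = (counts_i + pseudocount / q) / (neff + pseudocount)

    flat = onehot.reshape(n, L * q)
    counts_ij = (flat * w[:, None]).T @ flat  # (L*q, L*q)
    counts_ij = counts_ij.reshape(L, q, L, q).transpose(0, 2, 1, 3)
    fij = (counts_ij + pseudocount / (q * q)) / (neff + pseudocount)
    # diagonal: f_ii(a, b) = delta(a, b) * f_i(a)
    for i in range(L):
        fij[i, i] = np.diag(fi[i])
    return fi, fij


def write_fasta(msa: MSA, path: str | os.PathLike) -> None:
    """Write the alignment as FASTA."""
    from .alphabet import ALPHABET
    with open(path, "w") as fh:
        for name, row in zip(msa.identifiers, msa.rows):
            fh.write(f">{name}\n")
            fh.write("".join(ALPHABET[i] for i in row) + "\n")
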