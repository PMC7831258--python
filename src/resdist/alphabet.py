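"""Shared 21-letter amino-acid alphabet and residue property tables.

All tensors in the package index amino acids by this fixed order:
the 20 standard residues alphabetically by one-letter code, then the gap
symbol ``-`` at index 20.
"""

from __future__ import annotations

import numpy as np

#: 20 standard amino acids (alphabetical one-letter codes) + gap last.
ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY-"
N_STATES: int = len(ALPHABET)  # 21
GAP: str = "-"
GAP_INDEX: int = 20

#: Non-standard codes; mapped to gap by default (configurable in readers).
WILDCARDS: str = "BZXUOJ"

_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

#: Kyte-Doolittle hydropathy, used as the documented numeric column encoding
#: for Pearson correlation and as the basis of the bundled quasi-potential.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

#: Hydropathy vector in alphabet order, gap encoded as 0.0.
HYDROPATHY = np.array([KYTE_DOOLITTLE.get(a, 0.0) for a in ALPHABET])


def index_of(symbol: str) -> int:
    """Alphabet index of a (sanitized) residue symbol."""
    return _INDEX[symbol]


def encode(sequence: str) -> np.ndarray:
    """Encode a sanitized sequence string as an int8 index array."""
    return np.fromiter((_INDEX[c] for c in sequence), dtype=np.int8,
                       count=len(sequence))


def sanitize(sequence: str, wildcard_policy: str = "gap") -> str:
    """Map a raw aligned sequence onto the 21-letter alphabet.

    ``.`` and ``*`` become gaps; wildcard codes (B/Z/X/U/O/J) follow
    ``wildcard_policy``: ``"gap"`` maps them to ``-``.
    """
    seq = sequence.upper().replace(".", GAP).replace("*", GAP)
    if wildcard_policy != "gap":
        raise ValueError(f"unknown wildcard policy: {wildcard_policy!r}")
    out = []
    for c in seq:
        if c in _INDEX:
            out.append(c)
        elif c in WILDCARDS:
            out.append(GAP)
        else:
            raise ValueError(f"unrecognized residue symbol {c!r}")
    return "".join(out)
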