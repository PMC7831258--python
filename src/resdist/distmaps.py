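"""Distance discretization and conversions among maps, distograms, contacts.

The default 25-bin scheme: one open bin below 4.5 Å, 23 half-open bins of
width 0.5 Å covering [4.5, 16), and one open bin for distances >= 16 Å.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONTACT_THRESHOLD = 8.0
INV_DIST_EPS = 0.1  # Å floor for the 1/d relative contact score


@dataclass
class BinScheme:
    """Distance bin edges and per-bin representative values (Å)."""

    edges: np.ndarray = field(
        default_factory=lambda: np.arange(4.5, 16.0 + 1e-9, 0.5))
    first_rep: float = 4.25
    last_rep: float = 16.25

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=float)

    @property
    def n_bins(self) -> int:
        return len(self.edges) + 1  # 25 for the default scheme

    @property
    def representatives(self) -> np.ndarray:
        mids = 0.5 * (self.edges[:-1] + self.edges[1:])
        return np.concatenate([[self.first_rep], mids, [self.last_rep]])

    def discretize(self, d: np.ndarray | float) -> np.ndarray | int:
        """Bin index in [0, 24]; half-open [lower, upper) convention."""
        d = np.asarray(d, dtype=float)
        if np.any(d < 0):
            raise ValueError("distances must be nonnegative")
        idx = np.searchsorted(self.edges, d, side="right")
        return int(idx) if idx.ndim == 0 else idx

    def contact_bins(self, threshold: float = CONTACT_THRESHOLD) -> np.ndarray:
        """Indices of bins whose upper boundary is <= threshold."""
        uppers = np.concatenate([self.edges, [np.inf]])
        return np.nonzero(uppers <= threshold + 1e-12)[0]


DEFAULT_BINS = BinScheme()


def discretize(d, scheme: BinScheme = DEFAULT_BINS):
    return scheme.discretize(d)


def symmetrize(m: np.ndarray) -> np.ndarray:
    """(M + M^T) / 2 over the first two axes; idempotent."""
    m = np.asarray(m, dtype=float)
    if m.ndim < 2 or m.shape[0] != m.shape[1]:
        raise ValueError("map must be square in its first two axes")
    if m.ndim == 2:
        return 0.5 * (m + m.T)
    return 0.5 * (m + m.transpose(1, 0, *range(2, m.ndim)))


def realdist_to_contact(d: np.ndarray, eps: float = INV_DIST_EPS) -> np.ndarray:
    """Relative contact score 1 / max(d, eps); diagonal zeroed.

    Scores are relative: only the (reverse-of-distance) ranking is
    contract-bound, not the scale.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be nonnegative")
    score = 1.0 / np.maximum(d, eps)
    np.fill_diagonal(score, 0.0)
    return score


def distogram_to_contact(p: np.ndarray, threshold: float = CONTACT_THRESHOLD,
                         scheme: BinScheme = DEFAULT_BINS) -> np.ndarray:
    """Contact probability: total mass of bins with upper boundary <= 8 Å."""
    p = np.asarray(p, dtype=float)
    return p[..., scheme.contact_bins(threshold)].sum(axis=-1)


def distogram_to_realdist(p: np.ndarray, scheme: BinScheme = DEFAULT_BINS,
                          include_last_bin: bool = False
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Probability-weighted mean distance and per-pair standard deviation.

    By default the open >= 16 Å bin is excluded and the remaining mass
    renormalized; pairs with (numerically) all mass in the excluded bin are
    flagged unpredictable with NaN in both outputs. ``include_last_bin``
    switches to the alternative convention (all 25 bins, representative
    16.25 Å for the last).
    """
    p = np.asarray(p, dtype=float)
    reps = scheme.representatives
    if include_last_bin:
        mass = p
    else:
        mass = p[..., :-1]
        reps = reps[:-1]
    total = mass.sum(axis=-1)
    ok = total > 1e-12
    safe = np.where(ok, total, 1.0)
    w = mass / safe[..., None]
    mean = w @ reps
    var = np.clip((w * (reps - mean[..., None]) ** 2).sum(-1), 0.0, None)
    std = np.sqrt(var)
    mean[~ok] = np.nan
    std[~ok] = np.nan
    return mean, std


def ensemble_average(maps: list[np.ndarray]) -> np.ndarray:
    """Elementwise mean; averaged distograms are renormalized per pair."""
    if not maps:
        raise ValueError("cannot ensemble an empty list of maps")
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"shape mismatch among maps: {sorted(shapes)}")
    stack = np.stack([np.asarray(m, dtype=float) for m in maps])
    # elementwise sort makes the summation order canonical, so the result
    # is bit-for-bit invariant under permutation of the input list
    out = np.sort(stack, axis=0).mean(axis=0)
    if out.ndim == 3:  # distogram: renormalize (no-op up to float error)
        out = out / out.sum(axis=-1, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# plain-text exports

def write_matrix(m: np.ndarray, path: str) -> None:
    np.savetxt(path, np.asarray(m, dtype=float), fmt="%.6f")


def read_matrix(path: str) -> np.ndarray:
    return np.atleast_2d(np.loadtxt(path))


def write_rr(scores: np.ndarray, path: str, sequence: str | None = None,
             min_sep: int = 1, d_lower: float = 0.0,
             d_upper: float = CONTACT_THRESHOLD) -> None:
    """CASP RR contact list: header then 'i j d1 d2 score', 1-based,
    sorted by descending score."""
    scores = np.asarray(scores, dtype=float)
    L = scores.shape[0]
    recs = [(i + 1, j + 1, scores[i, j])
            for i in range(L) for j in range(i + min_sep, L)]
    recs.sort(key=lambda r: (-r[2], r[0], r[1]))
    with open(path, "w") as fh:
        if sequence:
            fh.write(sequence + "\n")
        for i, j, s in recs:
            fh.write(f"{i} {j} {d_lower:g} {d_upper:g} {s:.6f}\n")


def read_rr(path: str) -> list[tuple[int, int, float, float, float]]:
    """Parse an RR file back into (i, j, d1, d2, score) records."""
    out = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) == 5:
                try:
                    i, j = int(parts[0]), int(parts[1])
                except ValueError:
                    continue
                out.append((i, j, float(parts[2]), float(parts[3]),
                            float(parts[4])))
    return out
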