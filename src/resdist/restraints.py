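"""Distance restraints for distance-geometry folding, and violation scoring.

Restraints are Cβ–Cβ (Cα for glycine) bounds derived from a predicted
real-value distance map: pairs with predicted distance <= 15 Å and sequence
separation >= 3, bounds at the prediction ± 0.1 Å. Five nested subsets are
produced at cutoffs 11, 12, 13, 14, 15 Å. The violation score of a set of
coordinates is the summed bound violation over all restraints.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass

import numpy as np

MAX_RESTRAINT_DIST = 15.0
MIN_SEPARATION = 3
BOUND_DELTA = 0.1
SUBSET_CUTOFFS = (11.0, 12.0, 13.0, 14.0, 15.0)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Restraint:
    """One Cβ–Cβ distance bound; indices are 1-based."""

    i: int
    j: int
    target: float
    lower: float
    upper: float
    atom_pair: str = "CB-CB"


@dataclass
class RestraintSet:
    restraints: list[Restraint]
    cutoff: float = MAX_RESTRAINT_DIST

    def __len__(self) -> int:
        return len(self.restraints)

    def __iter__(self):
        return iter(self.restraints)


@dataclass
class RestraintSubsets:
    cutoffs: tuple[float, ...]
    subsets: dict[float, RestraintSet]


def make_restraints(d: np.ndarray, max_dist: float = MAX_RESTRAINT_DIST,
                    min_sep: int = MIN_SEPARATION,
                    delta: float = BOUND_DELTA) -> RestraintSet:
    """One restraint per upper-triangle pair with sep >= 3 and d <= 15 Å.

    Only the upper triangle of ``d`` is read; NaN predictions (pairs
    flagged unpredictable by the distogram conversion) are skipped.
    """
    d = np.asarray(d, dtype=float)
    L = d.shape[0]
    out: list[Restraint] = []
    iu, ju = np.triu_indices(L, k=min_sep)
    for i, j in zip(iu, ju):
        dij = d[i, j]
        if np.isnan(dij) or dij > max_dist:
            continue
        out.append(Restraint(i=int(i) + 1, j=int(j) + 1, target=float(dij),
                             lower=float(dij) - delta, upper=float(dij) + delta))
    return RestraintSet(out, cutoff=max_dist)


def make_subsets(d: np.ndarray,
                 cutoffs: tuple[float, ...] = SUBSET_CUTOFFS
                 ) -> RestraintSubsets:
    """Nested restraint subsets at the five printed distance cutoffs."""
    subsets = {x: make_restraints(d, max_dist=x) for x in cutoffs}
    return RestraintSubsets(cutoffs=tuple(cutoffs), subsets=subsets)


def violation_score(coordinates: np.ndarray | dict[int, np.ndarray],
                    restraints: RestraintSet) -> float:
    """Sum over restraints of max(0, lower - d) + max(0, d - upper).

    ``coordinates``: (L, 3) array (row r = residue r+1) or a {1-based
    residue: xyz} dict. Restraints on residues without coordinates are
    skipped with a warning count.
    """
    if isinstance(coordinates, dict):
        coords = coordinates
    else:
        arr = np.asarray(coordinates, dtype=float)
        coords = {r + 1: arr[r] for r in range(arr.shape[0])}
    total = 0.0
    skipped = 0
    for r in restraints:
        if r.i not in coords or r.j not in coords:
            skipped += 1
            continue
        d = float(np.linalg.norm(coords[r.i] - coords[r.j]))
        total += max(0.0, r.lower - d) + max(0.0, d - r.upper)
    if skipped:
        warnings.warn(f"{skipped} restraints skipped (missing coordinates)",
                      RuntimeWarning, stacklevel=2)
    return total


# ---------------------------------------------------------------------------
# coordinate input

def read_cb_coordinates(pdb_path: str | os.PathLike) -> dict[int, np.ndarray]:
    """Cβ coordinates (Cα for glycine) from a PDB file.

    First model, first altloc. Returns {1-based residue number: xyz}.
    """
    from Bio.PDB import PDBParser
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", os.fspath(pdb_path))
    model = next(structure.get_models())
    coords: dict[int, np.ndarray] = {}
    for chain in model:
        for res in chain:
            atom_name = "CA" if res.get_resname().strip() == "GLY" else "CB"
            atom = res[atom_name] if atom_name in res else (
                res["CA"] if "CA" in res else None)
            if atom is None:
                continue
            resnum = res.id[1]
            if resnum not in coords:
                coords[resnum] = np.asarray(atom.get_coord(), dtype=float)
    return coords


# ---------------------------------------------------------------------------
# writers

def write_restraints(rset: RestraintSet, path: str | os.PathLike,
                     format: str = "cns_tbl") -> None:
    """Write restraints as a CNS .tbl dialect or a delimited table.

    CNS dialect: ``assign (resid I and name CB) (resid J and name CB)
    TARGET DMINUS DPLUS`` — target with minus/plus deltas (lower = target -
    dminus, upper = target + dplus).
    """
    try:
        with open(path, "w") as fh:
            if format == "cns_tbl":
                fh.write(f"! {len(rset)} distance restraints "
                         f"(cutoff {rset.cutoff:g} A)\n")
                for r in rset:
                    dminus = r.target - r.lower
                    dplus = r.upper - r.target
                    fh.write(
                        f"assign (resid {r.i:4d} and name CB) "
                        f"(resid {r.j:4d} and name CB) "
                        f"{r.target:6.2f} {dminus:4.2f} {dplus:4.2f}\n")
            elif format == "tabular":
                fh.write("i\tj\tatom_pair\ttarget\tlower\tupper\n")
                for r in rset:
                    fh.write(f"{r.i}\t{r.j}\t{r.atom_pair}\t{r.target:.4f}"
                             f"\t{r.lower:.4f}\t{r.upper:.4f}\n")
            else:
                raise ValueError(f"unknown restraint format {format!r}")
    except OSError as exc:
        raise OSError(f"failed writing restraints to {path}: {exc}") from exc
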