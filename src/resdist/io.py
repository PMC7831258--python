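"""On-disk interchange: chunked HDF5 tensor container and toy PDB output."""

from __future__ import annotations

import json
import os

import h5py
import numpy as np

from .features import BranchInput


def write_branch_input(binput: BranchInput, path: str | os.PathLike) -> None:
    """Store a branch tensor with its channel manifest (chunked by channel)."""
    with h5py.File(path, "w") as fh:
        L = binput.tensor.shape[0]
        fh.create_dataset("tensor", data=binput.tensor,
                          chunks=(L, L, 1), compression="gzip")
        fh.attrs["branch"] = binput.branch
        fh.attrs["channel_manifest"] = json.dumps(binput.channel_manifest)


def read_branch_input(path: str | os.PathLike) -> BranchInput:
    with h5py.File(path, "r") as fh:
        return BranchInput(
            branch=str(fh.attrs["branch"]),
            tensor=fh["tensor"][()],
            channel_manifest=json.loads(fh.attrs["channel_manifest"]))


def write_toy_pdb(coordinates: np.ndarray, path: str | os.PathLike,
                  residue_name: str = "ALA") -> None:
    """Write (L, 3) Cβ coordinates as a minimal single-chain PDB file."""
    coords = np.asarray(coordinates, dtype=float)
    with open(path, "w") as fh:
        for r, (x, y, z) in enumerate(coords, start=1):
            fh.write(
                f"ATOM  {r:5d}  CB  {residue_name} A{r:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")
        fh.write("END\n")
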