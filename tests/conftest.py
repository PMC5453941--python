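"""Shared fixtures: small structures built programmatically at test time."""

import numpy as np
import pytest

from poremap.model import Frame, Topology


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_residue_pdb(tmp_path):
    """Minimal two-residue (GLY, LYS) PDB file."""
    lines = [
        "CRYST1  100.000  100.000  100.000  90.00  90.00  90.00 P 1           1",
        "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00           C",
        "ATOM      2  CA  LYS A   2       3.800   0.000   0.000  1.00  0.00           C",
        "ATOM      3  NZ  LYS A   2       5.500   2.000   1.000  1.00  0.00           N",
        "END",
    ]
    path = tmp_path / "two_res.pdb"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def small_protein():
    """A 6-residue mixed-polarity single-bead-per-residue chain."""
    resnames = ["LYS", "GLU", "SER", "LEU", "ALA", "ARG"]
    coords = np.column_stack([
        3.8 * np.arange(6), np.zeros(6), np.zeros(6)])
    top = Topology(
        names=["CA"] * 6,
        residue_indices=np.arange(1, 7),
        residue_names=resnames,
        chain_ids=["A"] * 6,
        group_tags="protein",
    )
    return top, Frame(coords, np.array([100.0, 100.0, 100.0]))
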