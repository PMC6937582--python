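"""Shared fixtures: tiny hand-written PDB texts and built synthetic models."""

from __future__ import annotations

import pytest

from pfrkit import BuilderSpec, build_peptide

THREE_ATOM_PDB = """\
CRYST1   40.000   50.000   60.000  90.00  99.50  90.00 P 1 21 1
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 30.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 32.50           C
ATOM      3  C   ALA A   1      13.062   6.548  -5.061  1.00 29.00           C
END
"""

ALTLOC_PDB = """\
ATOM      1  N   SER A   1       0.000   0.000   0.000  1.00 20.00           N
ATOM      2  CA ASER A   1       1.458   0.000   0.000  0.60 20.00           C
ATOM      3  CA BSER A   1       1.500   0.100   0.000  0.40 21.00           C
ATOM      4  CB ASER A   1       2.000   1.400   0.000  0.50 20.00           C
ATOM      5  CB BSER A   1       2.100   1.500   0.000  0.50 22.00           C
ATOM      6  C   SER A   1       2.000  -1.400   0.000  1.00 20.00           C
END
"""


@pytest.fixture
def three_atom_pdb(tmp_path):
    p = tmp_path / "three.pdb"
    p.write_text(THREE_ATOM_PDB)
    return p


@pytest.fixture
def altloc_pdb(tmp_path):
    p = tmp_path / "altloc.pdb"
    p.write_text(ALTLOC_PDB)
    return p


@pytest.fixture
def helix_model():
    """5-residue poly-Ala built at canonical α-helical dihedrals."""
    return build_peptide(BuilderSpec.uniform("AAAAA", -57.0, -47.0))


@pytest.fixture
def type_ii_turn_model():
    """LSGS tetrapeptide built at ideal type II β-turn central dihedrals."""
    return build_peptide(BuilderSpec.turn("LSGS"))
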