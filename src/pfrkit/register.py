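"""Peptide register assignment: core nonamer vs peptide-flanking residues.

An HLA class II binding groove seats nine peptide residues (P1–P9, with
anchor side chains in pockets P1, P4, P6 and P9); because the groove is
open-ended the peptide usually overhangs both ends, forming
peptide-flanking residues (PFRs).  N-terminal PFRs are numbered P(−1),
P(−2), … walking backwards from P1 (there is no P0), C-terminal PFRs P10,
P11, … after P9.

The core register is an *input* here (from crystallographic anchor occupancy
or an external predictor), not inferred: this module only turns a declared
core start into a residue → P-position mapping and partitions the peptide
into N-PFR / core / C-PFR regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .structure_io import StructureModel

__all__ = ["PeptideRegister", "assign_register", "declare_sequence_gap", "ANCHOR_POSITIONS"]

#: groove anchor pockets for class II
ANCHOR_POSITIONS = frozenset({1, 4, 6, 9})

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}


def _p_position(index: int, core_start: int) -> int:
    """P-position of the 1-based peptide index given the 1-based core start.

    Skips zero: the residue immediately before P1 is P(−1).
    """
    offset = index - core_start  # 0 for P1
    return offset + 1 if offset >= 0 else offset


def region_of_p(p: int) -> str:
    if p < 0:
        return "N-PFR"
    if 1 <= p <= 9:
        return "core"
    return "C-PFR"


@dataclass(frozen=True)
class PeptideRegister:
    """Mapping of modeled peptide residues to P-positions."""

    chain_id: str
    sequence: str                     # one-letter, modeled residues in order
    core_start: int                   # 1-based index into the modeled peptide
    residue_keys: tuple[tuple[str, int, str], ...]  # per modeled residue
    anchors: frozenset[int] = ANCHOR_POSITIONS
    _p_by_key: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if len(self.residue_keys) != len(self.sequence):
            raise ValueError("sequence length and residue count disagree")
        if self.core_start < 1 or len(self.sequence) - self.core_start + 1 < 9:
            raise ValueError(
                f"core_start={self.core_start} leaves fewer than 9 residues "
                f"in a {len(self.sequence)}-mer"
            )
        object.__setattr__(
            self,
            "_p_by_key",
            {
                key: _p_position(i + 1, self.core_start)
                for i, key in enumerate(self.residue_keys)
            },
        )

    # -- lookups ---------------------------------------------------------
    def p_of(self, key: tuple[str, int, str]) -> int:
        """P-position of a modeled residue key (chain, res_seq, icode)."""
        return self._p_by_key[key]

    def region_of(self, key: tuple[str, int, str]) -> str:
        return region_of_p(self.p_of(key))

    @property
    def p_positions(self) -> tuple[int, ...]:
        return tuple(self._p_by_key[k] for k in self.residue_keys)

    def key_of_p(self, p: int) -> tuple[str, int, str]:
        for k, v in self._p_by_key.items():
            if v == p:
                return k
        raise KeyError(f"no modeled residue at P{p}")

    def residues_in(self, region: str) -> list[tuple[str, int, str]]:
        return [k for k in self.residue_keys if self.region_of(k) == region]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "res_seq": k[1],
                "icode": k[2],
                "aa": self.sequence[i],
                "p_position": self._p_by_key[k],
                "region": self.region_of(k),
                "anchor": self._p_by_key[k] in self.anchors,
            }
            for i, k in enumerate(self.residue_keys)
        ]
        return pd.DataFrame(rows)

    # -- constructors ----------------------------------------------------
    @classmethod
    def from_sequence(
        cls, sequence: str, core_start: int, chain_id: str = "C"
    ) -> "PeptideRegister":
        """Register for a plain sequence (residues keyed 1..n on *chain_id*)."""
        keys = tuple((chain_id, i + 1, "") for i in range(len(sequence)))
        return cls(chain_id, sequence, core_start, keys)


def assign_register(
    model: StructureModel, peptide_chain: str, core_start: int
) -> PeptideRegister:
    """Assign P-positions to the modeled peptide chain.

    ``core_start`` is the 1-based index of P1 along the *modeled* peptide
    residues (file order).  Residues before it become N-PFRs (P(−1)
    backwards), the next nine are the core, anything beyond P9 is a C-PFR.
    """
    residues = model.chain(peptide_chain)
    seq = "".join(_THREE_TO_ONE.get(r.res_name, "X") for r in residues)
    keys = tuple(r.key for r in residues)
    return PeptideRegister(peptide_chain, seq, core_start, keys)


def declare_sequence_gap(
    register: PeptideRegister, declared_sequence: str
) -> dict[int, str]:
    """Report declared-but-unmodeled residues with their P-positions.

    The modeled sequence must occur in ``declared_sequence`` as a contiguous
    substring; flanking residues of the declared sequence absent from the
    coordinates are returned as ``{p_position: one_letter}`` — e.g. an
    unmodeled N-terminal residue one position before the first modeled
    N-PFR.  Returns an empty dict when declared == modeled.
    """
    modeled = register.sequence
    start = declared_sequence.find(modeled)
    if start < 0:
        raise ValueError(
            "modeled sequence is not a contiguous subsequence of the declared sequence"
        )
    gaps: dict[int, str] = {}
    first_p = register.p_positions[0]
    for j in range(start):  # declared residues before the modeled stretch
        back = start - j  # how many positions before the first modeled residue
        p = first_p - back
        if first_p > 0 and p <= 0:  # crossing P1 → P(−1): no zero
            p -= 1
        gaps[p] = declared_sequence[j]
    last_p = register.p_positions[-1]
    for j in range(start + len(modeled), len(declared_sequence)):
        ahead = j - (start + len(modeled)) + 1
        p = last_p + ahead
        if last_p < 0 and p >= 0:
            p += 1
        gaps[p] = declared_sequence[j]
    return gaps
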