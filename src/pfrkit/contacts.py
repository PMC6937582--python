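"""Peptide-to-receptor atomic contact enumeration and summaries.

A *contact* is a peptide-atom/receptor-atom pair within a distance cutoff
(4.0 Å by default, the convention for van der Waals contacts in pMHC
structure reports).  Pairs whose atoms form a chemically plausible
donor–acceptor pair within the hydrogen-bond cutoff (3.4 Å) are labelled
``hbond``; every other pair within the vdW cutoff is labelled ``vdw``.  A
pair is never counted in both classes, so per-residue totals are simply
vdW + H-bond.

The hydrogen-bond criterion is distance-only by default (that is what
contact-table programs such as NCONT report); an angle term can be layered
on by the caller via a custom donor/acceptor table.  Waters are always
excluded from both selections; hydrogens are excluded by default (crystal
models carry no informative hydrogens) and included for MD-style counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .register import PeptideRegister, region_of_p
from .structure_io import AtomRecord, StructureModel

__all__ = [
    "ContactPair",
    "ContactTable",
    "DONOR_ATOMS",
    "ACCEPTOR_ATOMS",
    "find_contacts",
    "summarize_contacts",
    "residue_contact_detail",
    "is_donor",
    "is_acceptor",
]

# Donor/acceptor typing for the distance-only H-bond criterion.  Side-chain
# entries are keyed (res_name, atom_name); backbone N donates, backbone
# O/OXT accepts, for every residue type.  Hydroxyls (Ser/Thr/Tyr) and His
# ring nitrogens appear in both tables since they can do either.
DONOR_ATOMS: frozenset[tuple[str, str]] = frozenset(
    {
        ("LYS", "NZ"),
        ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2"),
        ("HIS", "ND1"), ("HIS", "NE2"),
        ("TRP", "NE1"),
        ("ASN", "ND2"),
        ("GLN", "NE2"),
        ("SER", "OG"),
        ("THR", "OG1"),
        ("TYR", "OH"),
    }
)

ACCEPTOR_ATOMS: frozenset[tuple[str, str]] = frozenset(
    {
        ("ASP", "OD1"), ("ASP", "OD2"),
        ("GLU", "OE1"), ("GLU", "OE2"),
        ("ASN", "OD1"),
        ("GLN", "OE1"),
        ("HIS", "ND1"), ("HIS", "NE2"),
        ("SER", "OG"),
        ("THR", "OG1"),
        ("TYR", "OH"),
        ("MET", "SD"),
    }
)


def is_donor(atom: AtomRecord, table: frozenset = DONOR_ATOMS) -> bool:
    if atom.name == "N":  # backbone amide
        return True
    return (atom.res_name, atom.name) in table


def is_acceptor(atom: AtomRecord, table: frozenset = ACCEPTOR_ATOMS) -> bool:
    if atom.name in ("O", "OXT"):  # backbone carbonyl / C-terminal carboxylate
        return True
    return (atom.res_name, atom.name) in table


@dataclass(frozen=True)
class ContactPair:
    peptide_atom: AtomRecord
    receptor_atom: AtomRecord
    distance: float
    kind: Literal["vdw", "hbond"]


def _hbond_compatible(a: AtomRecord, b: AtomRecord) -> bool:
    return (is_donor(a) and is_acceptor(b)) or (is_donor(b) and is_acceptor(a))


def find_contacts(
    model: StructureModel,
    peptide_chain: str,
    receptor_chains: Iterable[str],
    vdw_cutoff: float = 4.0,
    hbond_cutoff: float = 3.4,
    hydrogen_policy: Literal["exclude", "include"] = "exclude",
) -> list[ContactPair]:
    """Every peptide/receptor atom pair within ``vdw_cutoff``, classified.

    Pairs that satisfy donor/acceptor chemistry within ``hbond_cutoff`` are
    ``hbond``; all remaining pairs within ``vdw_cutoff`` are ``vdw``.
    Waters are excluded on both sides; hydrogens per ``hydrogen_policy``.
    """
    if vdw_cutoff <= 0 or hbond_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    include_h = hydrogen_policy == "include"
    pep_idx = model.select(
        chain_ids=[peptide_chain], include_hydrogens=include_h, include_waters=False
    )
    rec_idx = model.select(
        chain_ids=list(receptor_chains), include_hydrogens=include_h, include_waters=False
    )
    if not pep_idx:
        raise ValueError(f"empty peptide selection (chain {peptide_chain!r})")
    if not rec_idx:
        raise ValueError(f"empty receptor selection (chains {list(receptor_chains)!r})")

    coords = model.coords()
    pep_xyz, rec_xyz = coords[pep_idx], coords[rec_idx]
    tree = cKDTree(rec_xyz)
    pairs: list[ContactPair] = []
    for i, neighbours in enumerate(tree.query_ball_point(pep_xyz, r=vdw_cutoff)):
        pa = model.atoms[pep_idx[i]]
        for j in sorted(neighbours):
            ra = model.atoms[rec_idx[j]]
            d = float(np.linalg.norm(pep_xyz[i] - rec_xyz[j]))
            kind = (
                "hbond"
                if d <= hbond_cutoff and _hbond_compatible(pa, ra)
                else "vdw"
            )
            pairs.append(ContactPair(pa, ra, d, kind))
    return pairs


@dataclass(frozen=True)
class ContactTable:
    """Per-residue contact counts with regional and grand totals."""

    rows: pd.DataFrame         # residue rows ordered by P-position
    region_totals: pd.DataFrame  # N-PFR / core / C-PFR / all

    @property
    def grand_total(self) -> tuple[int, int, int]:
        r = self.region_totals.loc["all"]
        return int(r["vdw"]), int(r["hbonds"]), int(r["total"])

    def row_at(self, p: int) -> pd.Series:
        hit = self.rows[self.rows["p_position"] == p]
        if hit.empty:
            raise KeyError(f"no residue at P{p}")
        return hit.iloc[0]


def summarize_contacts(
    pairs: Sequence[ContactPair], register: PeptideRegister
) -> ContactTable:
    """Tabulate contact pairs per registered peptide residue.

    Rows are ordered by P-position and include zero-contact residues; the
    percentage column is each residue's share of the grand total (summing to
    100 % over residues with at least one contact).  A pair whose peptide
    atom falls outside the register raises ``KeyError`` naming the residue.
    """
    counts: dict[tuple[str, int, str], dict[str, int]] = {
        k: {"vdw": 0, "hbonds": 0} for k in register.residue_keys
    }
    for p in pairs:
        key = p.peptide_atom.residue_key()
        if key not in counts:
            raise KeyError(
                f"contact atom in unregistered residue "
                f"{p.peptide_atom.res_name}-{key[0]}{key[1]}{key[2]}"
            )
        counts[key]["hbonds" if p.kind == "hbond" else "vdw"] += 1

    rows = []
    for i, key in enumerate(register.residue_keys):
        pp = register.p_of(key)
        c = counts[key]
        rows.append(
            {
                "res_seq": key[1],
                "aa": register.sequence[i],
                "p_position": pp,
                "region": region_of_p(pp),
                "vdw": c["vdw"],
                "hbonds": c["hbonds"],
                "total": c["vdw"] + c["hbonds"],
            }
        )
    df = pd.DataFrame(rows).sort_values("p_position").reset_index(drop=True)
    grand = int(df["total"].sum())
    df["pct"] = 0.0 if grand == 0 else 100.0 * df["total"] / grand

    regions = []
    for name in ("N-PFR", "core", "C-PFR"):
        sub = df[df["region"] == name]
        regions.append(
            {
                "region": name,
                "vdw": int(sub["vdw"].sum()),
                "hbonds": int(sub["hbonds"].sum()),
                "total": int(sub["total"].sum()),
            }
        )
    regions.append(
        {
            "region": "all",
            "vdw": int(df["vdw"].sum()),
            "hbonds": int(df["hbonds"].sum()),
            "total": grand,
        }
    )
    reg_df = pd.DataFrame(regions).set_index("region")
    return ContactTable(rows=df, region_totals=reg_df)


def residue_contact_detail(
    pairs: Sequence[ContactPair],
    residue: tuple[str, int] | tuple[str, int, str],
) -> pd.DataFrame:
    """Per-atom contact listing for one peptide residue.

    Peptide atoms are classified backbone (N, CA, C, O, OXT) vs side chain;
    partner receptor residues are listed with distances and contact kind.
    Returns an empty frame (with the same columns) for a residue without
    contacts.
    """
    chain, res_seq = residue[0], residue[1]
    icode = residue[2] if len(residue) > 2 else ""
    rows = []
    for p in pairs:
        a = p.peptide_atom
        if (a.chain_id, a.res_seq, a.icode) != (chain, res_seq, icode):
            continue
        r = p.receptor_atom
        rows.append(
            {
                "peptide_atom": a.name,
                "atom_class": "backbone" if a.is_backbone else "side-chain",
                "partner_chain": r.chain_id,
                "partner_res_seq": r.res_seq,
                "partner_res": r.res_name,
                "partner_atom": r.name,
                "distance": p.distance,
                "kind": p.kind,
            }
        )
    cols = [
        "peptide_atom", "atom_class", "partner_chain", "partner_res_seq",
        "partner_res", "partner_atom", "distance", "kind",
    ]
    return pd.DataFrame(rows, columns=cols)
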