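"""Coordinate file reading, altloc handling and B-factor profiling.

This module turns PDB/mmCIF files into a light, validated in-memory model
(:class:`StructureModel`, a flat list of :class:`AtomRecord`) that the rest of
the package operates on.  Parsing itself is delegated to :mod:`gemmi`; the
model here adds the policies the analyses need:

* an explicit altloc/occupancy policy (crystal structures of pMHC-II
  complexes routinely carry alternate conformers on flexible flanking
  residues),
* per-residue isotropic B-factor profiles with the flexibility categories
  used for peptide-flanking-residue (PFR) analysis: mean B < 40 Å² is
  "stable", > 80 Å² is "high-flex", anything between is "intermediate".

Hydrogens, waters and non-polymer HETATM records are *retained* at parse
time; each downstream analysis selects what it needs (the crystal model has
no informative hydrogens, MD frames do).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "HeaderMeta",
    "Residue",
    "StructureModel",
    "BFactorProfile",
    "StructureParseError",
    "AltlocError",
    "WATER_NAMES",
    "BACKBONE_NAMES",
    "read_structure",
    "write_pdb",
    "apply_altloc_policy",
    "bfactor_profile",
]

#: residue names treated as solvent and excluded from contact analyses
WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

#: protein backbone heavy-atom names (OXT counts as backbone terminus)
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})

# B-factor flexibility thresholds (Å²)
B_STABLE_MAX = 40.0
B_HIGHFLEX_MIN = 80.0


class StructureParseError(RuntimeError):
    """Raised when a coordinate file cannot be parsed."""


class AltlocError(ValueError):
    """Raised by the *strict* altloc policy when alternate conformers exist."""


@dataclass(frozen=True)
class AtomRecord:
    """A single atom as authored in the coordinate file (no renumbering)."""

    serial: int
    name: str
    element: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    icode: str
    x: float
    y: float
    z: float
    occupancy: float
    b_iso: float

    def __post_init__(self) -> None:
        if not all(math.isfinite(v) for v in (self.x, self.y, self.z)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(
                f"occupancy {self.occupancy} outside [0,1] for atom "
                f"{self.chain_id}/{self.res_seq}/{self.name}"
            )
        if self.b_iso < 0:
            raise ValueError(f"negative B-factor for atom {self.name}")
        if not self.element:
            raise ValueError(f"empty element for atom {self.name}")

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")

    @property
    def is_water(self) -> bool:
        return self.res_name in WATER_NAMES

    @property
    def is_backbone(self) -> bool:
        return self.name in BACKBONE_NAMES

    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.icode)


@dataclass(frozen=True)
class HeaderMeta:
    """Crystallographic header metadata (unit cell, space group, resolution)."""

    space_group: str = ""
    cell_a: float = 1.0
    cell_b: float = 1.0
    cell_c: float = 1.0
    cell_alpha: float = 90.0
    cell_beta: float = 90.0
    cell_gamma: float = 90.0
    resolution: float | None = None

    def __post_init__(self) -> None:
        if min(self.cell_a, self.cell_b, self.cell_c) <= 0:
            raise ValueError("unit cell lengths must be positive")
        for ang in (self.cell_alpha, self.cell_beta, self.cell_gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("unit cell angles must lie in (0, 180) degrees")


@dataclass(frozen=True)
class Residue:
    """A group of atoms sharing (chain, res_seq, icode)."""

    chain_id: str
    res_seq: int
    icode: str
    res_name: str
    atoms: tuple[AtomRecord, ...]

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.res_seq, self.icode)

    def atom(self, name: str, alt_loc: str | None = None) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name and (alt_loc is None or a.alt_loc == alt_loc):
                return a
        return None

    @property
    def label(self) -> str:
        return f"{self.res_name}-{self.chain_id}{self.res_seq}{self.icode}".rstrip()


@dataclass
class StructureModel:
    """An ordered list of atoms belonging to one MODEL block."""

    atoms: list[AtomRecord]
    model_id: int = 1
    header: HeaderMeta = field(default_factory=HeaderMeta)

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for a in self.atoms:
            k = (a.chain_id, a.res_seq, a.icode, a.name, a.alt_loc)
            if k in seen:
                raise ValueError(f"duplicate atom {k} in model {self.model_id}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.atoms)

    def coords(self) -> np.ndarray:
        """(n_atoms, 3) Cartesian coordinates in atom order."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def with_coords(self, xyz: np.ndarray) -> "StructureModel":
        """Copy of the model with coordinates replaced (same atom order)."""
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        atoms = [
            replace(a, x=float(p[0]), y=float(p[1]), z=float(p[2]))
            for a, p in zip(self.atoms, xyz)
        ]
        return StructureModel(atoms, model_id=self.model_id, header=self.header)

    def chain_ids(self) -> list[str]:
        out: list[str] = []
        for a in self.atoms:
            if a.chain_id not in out:
                out.append(a.chain_id)
        return out

    def residues(self, chain_id: str | None = None) -> list[Residue]:
        """Residues in file order, optionally restricted to one chain."""
        groups: dict[tuple, list[AtomRecord]] = {}
        order: list[tuple] = []
        for a in self.atoms:
            if chain_id is not None and a.chain_id != chain_id:
                continue
            k = a.residue_key()
            if k not in groups:
                groups[k] = []
                order.append(k)
            groups[k].append(a)
        return [
            Residue(k[0], k[1], k[2], groups[k][0].res_name, tuple(groups[k]))
            for k in order
        ]

    def chain(self, chain_id: str) -> list[Residue]:
        res = self.residues(chain_id)
        if not res:
            raise KeyError(f"chain {chain_id!r} not found in model {self.model_id}")
        return res

    def select(
        self,
        chain_ids: Iterable[str] | None = None,
        include_hydrogens: bool = True,
        include_waters: bool = True,
        names: Iterable[str] | None = None,
    ) -> list[int]:
        """Indices (into ``atoms``) matching the selection."""
        chain_set = set(chain_ids) if chain_ids is not None else None
        name_set = set(names) if names is not None else None
        out = []
        for i, a in enumerate(self.atoms):
            if chain_set is not None and a.chain_id not in chain_set:
                continue
            if not include_hydrogens and a.is_hydrogen:
                continue
            if not include_waters and a.is_water:
                continue
            if name_set is not None and a.name not in name_set:
                continue
            out.append(i)
        return out


def _element_from_name(name: str, res_name: str) -> str:
    """PDB fallback rule: infer the element when the element column is blank."""
    stripped = name.strip()
    if not stripped:
        return ""
    if stripped[0].isdigit():  # e.g. 1HB2
        return "H"
    if res_name in WATER_NAMES:
        return "O" if stripped[0] == "O" else stripped[0]
    first = stripped[0]
    # two-letter elements in standard residues are rare; handle the common ones
    if first in ("H", "C", "N", "O", "S", "P"):
        return first
    el = gemmi.Element(stripped[:2])
    return el.name if el.name != "X" else first


def _convert_model(model: gemmi.Model, header: HeaderMeta, model_id: int) -> StructureModel:
    atoms: list[AtomRecord] = []
    for chain in model:
        for res in chain:
            for atom in res:
                alt = atom.altloc if atom.altloc not in ("\x00", " ") else ""
                element = atom.element.name
                if element in ("", "X"):
                    element = _element_from_name(atom.name, res.name)
                atoms.append(
                    AtomRecord(
                        serial=atom.serial,
                        name=atom.name,
                        element=element,
                        alt_loc=alt,
                        res_name=res.name,
                        chain_id=chain.name,
                        res_seq=res.seqid.num,
                        icode=(res.seqid.icode or "").strip(),
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                        occupancy=min(max(atom.occ, 0.0), 1.0),
                        b_iso=max(atom.b_iso, 0.0),
                    )
                )
    return StructureModel(atoms, model_id=model_id, header=header)


_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def read_structure(
    path: str | Path,
    format: Literal["pdb", "mmcif", "auto"] = "auto",
) -> list[StructureModel]:
    """Read a coordinate file into one :class:`StructureModel` per MODEL block.

    Parameters
    ----------
    path:
        PDB (fixed-column) or mmCIF file.
    format:
        File dialect; ``auto`` detects from the extension/content.

    Returns
    -------
    list of StructureModel
        Ordered as in the file.  A file with zero atoms yields a single empty
        model and a warning rather than an exception.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected pdb/mmcif/auto")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        st = None
        if format == "auto":
            # content sniffing fails on header-only files; try the dialects
            for fallback in (gemmi.CoorFormat.Pdb, gemmi.CoorFormat.Mmcif):
                try:
                    st = gemmi.read_structure(str(path), format=fallback)
                    break
                except (RuntimeError, ValueError):
                    continue
        if st is None:
            raise StructureParseError(f"cannot parse {path}: {exc}") from exc

    cell = st.cell
    header = HeaderMeta(
        space_group=st.spacegroup_hm or "",
        cell_a=cell.a if cell.a > 0 else 1.0,
        cell_b=cell.b if cell.b > 0 else 1.0,
        cell_c=cell.c if cell.c > 0 else 1.0,
        cell_alpha=cell.alpha if 0 < cell.alpha < 180 else 90.0,
        cell_beta=cell.beta if 0 < cell.beta < 180 else 90.0,
        cell_gamma=cell.gamma if 0 < cell.gamma < 180 else 90.0,
        resolution=st.resolution if st.resolution > 0 else None,
    )
    models = [
        _convert_model(m, header, getattr(m, "num", i + 1))
        for i, m in enumerate(st)
    ]
    if not models or all(len(m) == 0 for m in models):
        warnings.warn(f"{path} contains no atoms", stacklevel=2)
        return [StructureModel([], model_id=1, header=header)]
    return models


def _pdb_atom_line(a: AtomRecord) -> str:
    name = a.name
    # atom-name column alignment: element symbols of one letter start in col 14
    if len(name) < 4 and len(a.element) == 1:
        name = " " + name
    return (
        f"ATOM  {a.serial % 100000:5d} {name:<4.4s}{a.alt_loc or ' ':1.1s}"
        f"{a.res_name:>3.3s} {a.chain_id[:1]:1.1s}{a.res_seq % 10000:4d}"
        f"{a.icode or ' ':1.1s}   "
        f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{a.b_iso:6.2f}"
        f"          {a.element:>2.2s}"
    )


def write_pdb(models: StructureModel | Sequence[StructureModel], path: str | Path) -> None:
    """Write one or more models as fixed-column PDB (multi-model if several)."""
    if isinstance(models, StructureModel):
        models = [models]
    lines: list[str] = []
    first = models[0]
    h = first.header
    if h.space_group or (h.cell_a, h.cell_b, h.cell_c) != (1.0, 1.0, 1.0):
        lines.append(
            f"CRYST1{h.cell_a:9.3f}{h.cell_b:9.3f}{h.cell_c:9.3f}"
            f"{h.cell_alpha:7.2f}{h.cell_beta:7.2f}{h.cell_gamma:7.2f} "
            f"{h.space_group:<11.11s}"
        )
    multi = len(models) > 1
    for m in models:
        if multi:
            lines.append(f"MODEL     {m.model_id:4d}")
        prev_chain = None
        for a in m.atoms:
            if prev_chain is not None and a.chain_id != prev_chain:
                lines.append("TER")
            lines.append(_pdb_atom_line(a))
            prev_chain = a.chain_id
        if m.atoms:
            lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def apply_altloc_policy(
    model: StructureModel,
    policy: Literal["highest_occupancy", "first", "strict"] = "highest_occupancy",
) -> StructureModel:
    """Reduce alternate conformers to at most one atom per (chain, res, name).

    ``highest_occupancy`` keeps the max-occupancy conformer (ties broken by
    altloc alphabetical order); ``first`` keeps the first in file order;
    ``strict`` raises :class:`AltlocError` listing the affected residues.
    Idempotent: a model without altlocs is returned unchanged.
    """
    if policy not in ("highest_occupancy", "first", "strict"):
        raise ValueError(f"unknown altloc policy {policy!r}")
    if not any(a.alt_loc for a in model.atoms):
        return model
    if policy == "strict":
        affected = sorted(
            {f"{a.chain_id}/{a.res_seq}{a.icode}/{a.res_name}" for a in model.atoms if a.alt_loc}
        )
        raise AltlocError("alternate conformers present in: " + ", ".join(affected))

    groups: dict[tuple, list[AtomRecord]] = {}
    order: list[tuple] = []
    for a in model.atoms:
        k = (a.chain_id, a.res_seq, a.icode, a.name)
        if k not in groups:
            groups[k] = []
            order.append(k)
        groups[k].append(a)

    kept: list[AtomRecord] = []
    for k in order:
        cands = groups[k]
        if len(cands) == 1:
            chosen = cands[0]
        elif policy == "first":
            chosen = cands[0]
        else:  # highest_occupancy; altloc alphabetical tie-break
            chosen = sorted(cands, key=lambda a: (-a.occupancy, a.alt_loc or "~"))[0]
        if chosen.alt_loc:
            chosen = replace(chosen, alt_loc="")
        kept.append(chosen)
    return StructureModel(kept, model_id=model.model_id, header=model.header)


@dataclass(frozen=True)
class BFactorProfile:
    """Per-residue mean isotropic B with a flexibility category.

    Categories follow the PFR-analysis convention: mean B < 40 Å² marks a
    stably bound (well-ordered) residue, mean B > 80 Å² marks high
    flexibility, anything between is intermediate.
    """

    chain_id: str
    selection: str
    entries: tuple[tuple[tuple[str, int, str], str, float, str], ...]
    # each entry: (residue key, res_name, mean_b, category)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "chain": k[0],
                "res_seq": k[1],
                "icode": k[2],
                "res_name": name,
                "mean_b": mean_b,
                "category": cat,
            }
            for k, name, mean_b, cat in self.entries
        ]
        return pd.DataFrame(rows)

    def category_of(self, res_seq: int, icode: str = "") -> str:
        for k, _, _, cat in self.entries:
            if k[1] == res_seq and k[2] == icode:
                return cat
        raise KeyError(res_seq)


def _b_category(mean_b: float) -> str:
    if mean_b < B_STABLE_MAX:
        return "stable"
    if mean_b > B_HIGHFLEX_MIN:
        return "high-flex"
    return "intermediate"


def bfactor_profile(
    model: StructureModel,
    chain: str,
    selection: Literal["all", "backbone"] = "all",
) -> BFactorProfile:
    """Mean B-factor per residue of *chain*, categorised by flexibility.

    ``selection`` chooses the atoms averaged: all heavy atoms, or backbone
    (N, CA, C, O) only; hydrogens are always excluded from the mean.  The
    selection is recorded on the profile since the two conventions can
    disagree for long side chains.
    """
    if selection not in ("all", "backbone"):
        raise ValueError(f"unknown selection {selection!r}")
    residues = model.chain(chain)  # raises KeyError if missing
    entries = []
    for res in residues:
        atoms = [a for a in res.atoms if not a.is_hydrogen]
        if selection == "backbone":
            atoms = [a for a in atoms if a.is_backbone]
        if not atoms:
            continue
        mean_b = float(np.mean([a.b_iso for a in atoms]))
        entries.append((res.key, res.res_name, mean_b, _b_category(mean_b)))
    return BFactorProfile(chain_id=chain, selection=selection, entries=tuple(entries))
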