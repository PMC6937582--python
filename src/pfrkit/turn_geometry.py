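"""Backbone dihedrals, β-turn window classification and loop superposition.

The C-terminal flank of a class II-bound peptide can fold back on itself as
a four-residue reverse turn (residues i…i+3).  Two named (ϕ,ψ) windows are
built in:

* ``type II β-turn`` — ideal central dihedrals (ϕ,ψ)_{i+1} = (−60°, +120°),
  (ϕ,ψ)_{i+2} = (+80°, 0°), with Cα(i)–Cα(i+3) under ~7 Å;
* ``glycine-extended`` — the opened conformation a glycine at i+2 can adopt,
  (ϕ,ψ)_{i+2} = (−60°, ±140°) (two ψ centers), i+1 staying turn-like.

Membership is judged on the circle (wrap-aware) with a ±40° tolerance by
default.  An *ST loop* is a turn capped by a serine/threonine at i+3 whose
side-chain hydroxyl hydrogen-bonds the turn backbone.

Superposition uses the standard least-squares rigid (Kabsch) fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .structure_io import AtomRecord, Residue, StructureModel

__all__ = [
    "DihedralRecord",
    "TurnWindowSpec",
    "TurnAssignment",
    "SuperpositionResult",
    "TYPE_II_BETA_TURN",
    "GLYCINE_EXTENDED",
    "DEFAULT_WINDOW_SPECS",
    "dihedral",
    "backbone_dihedrals",
    "classify_window",
    "hairpin_evidence",
    "superpose_segments",
    "kabsch",
]


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC convention (−180, 180]."""
    b0 = np.asarray(p0) - np.asarray(p1)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = float(np.dot(v, w))
    y = float(np.dot(np.cross(b1, v), w))
    ang = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def circular_delta(a: float, b: float) -> float:
    """Minimal absolute difference of two angles on the circle, degrees."""
    d = (a - b) % 360.0
    return min(d, 360.0 - d)


@dataclass(frozen=True)
class DihedralRecord:
    """Backbone torsions of one residue; angles absent at chain termini are None."""

    residue: tuple[str, int, str]
    res_name: str
    phi: float | None
    psi: float | None
    omega: float | None  # reported only, never used for classification


def _centers(value: float | Sequence[float]) -> tuple[float, ...]:
    if isinstance(value, (int, float)):
        return (float(value),)
    return tuple(float(v) for v in value)


@dataclass(frozen=True)
class TurnWindowSpec:
    """A named (ϕ,ψ) target window for the two central residues of a turn.

    Each target component may be a single center or a ± pair of centers
    (e.g. ψ = ±140°); membership means being within ``tolerance`` degrees
    (wrap-aware) of *any* center of every component.
    """

    name: str
    phi1: tuple[float, ...]
    psi1: tuple[float, ...]
    phi2: tuple[float, ...]
    psi2: tuple[float, ...]
    tolerance: float = 40.0

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")

    @classmethod
    def make(
        cls,
        name: str,
        target_i1: tuple[float | Sequence[float], float | Sequence[float]],
        target_i2: tuple[float | Sequence[float], float | Sequence[float]],
        tolerance: float = 40.0,
    ) -> "TurnWindowSpec":
        return cls(
            name,
            _centers(target_i1[0]), _centers(target_i1[1]),
            _centers(target_i2[0]), _centers(target_i2[1]),
            tolerance,
        )

    def _in(self, angle: float, centers: tuple[float, ...]) -> bool:
        return any(circular_delta(angle, c) <= self.tolerance for c in centers)

    def matches(self, phi1: float, psi1: float, phi2: float, psi2: float) -> bool:
        return (
            self._in(phi1, self.phi1)
            and self._in(psi1, self.psi1)
            and self._in(phi2, self.phi2)
            and self._in(psi2, self.psi2)
        )

    def matches_i2(self, phi2: float, psi2: float) -> bool:
        """Membership judged on the i+2 residue only (marginal mode)."""
        return self._in(phi2, self.phi2) and self._in(psi2, self.psi2)


TYPE_II_BETA_TURN = TurnWindowSpec.make("type II β-turn", (-60.0, 120.0), (80.0, 0.0))
GLYCINE_EXTENDED = TurnWindowSpec.make(
    "glycine-extended", (-60.0, 120.0), (-60.0, (140.0, -140.0))
)
DEFAULT_WINDOW_SPECS: tuple[TurnWindowSpec, ...] = (TYPE_II_BETA_TURN, GLYCINE_EXTENDED)


def backbone_dihedrals(model: StructureModel, chain: str) -> list[DihedralRecord]:
    """ϕ/ψ/ω per residue of *chain* (None at termini or where atoms are missing)."""
    residues = model.chain(chain)
    if len(residues) < 2:
        raise ValueError("need at least 2 residues for backbone dihedrals")

    def bb(res: Residue, name: str) -> np.ndarray | None:
        a = res.atom(name)
        return a.pos if a is not None else None

    out: list[DihedralRecord] = []
    for i, res in enumerate(residues):
        n, ca, c = bb(res, "N"), bb(res, "CA"), bb(res, "C")
        phi = psi = omega = None
        if n is None or ca is None or c is None:
            warnings.warn(f"incomplete backbone in {res.label}; dihedrals absent", stacklevel=2)
            out.append(DihedralRecord(res.key, res.res_name, None, None, None))
            continue
        if i > 0:
            prev = residues[i - 1]
            c_prev, ca_prev = bb(prev, "C"), bb(prev, "CA")
            if c_prev is not None:
                phi = dihedral(c_prev, n, ca, c)
                if ca_prev is not None:
                    omega = dihedral(ca_prev, c_prev, n, ca)
        if i < len(residues) - 1:
            n_next = bb(residues[i + 1], "N")
            if n_next is not None:
                psi = dihedral(n, ca, c, n_next)
        out.append(DihedralRecord(res.key, res.res_name, phi, psi, omega))
    return out


def classify_window(
    dihedrals_i1: DihedralRecord | tuple[float, float],
    dihedrals_i2: DihedralRecord | tuple[float, float],
    specs: Iterable[TurnWindowSpec] = DEFAULT_WINDOW_SPECS,
) -> str:
    """Name of the first spec matching the (i+1, i+2) dihedrals, else "other".

    Accepts either :class:`DihedralRecord` or bare ``(phi, psi)`` tuples;
    undefined dihedrals raise ``ValueError``.
    """

    def unpack(d) -> tuple[float, float]:
        if isinstance(d, DihedralRecord):
            if d.phi is None or d.psi is None:
                raise ValueError(f"undefined dihedral for residue {d.residue}")
            return d.phi, d.psi
        phi, psi = d
        if phi is None or psi is None:
            raise ValueError("undefined dihedral")
        return float(phi), float(psi)

    phi1, psi1 = unpack(dihedrals_i1)
    phi2, psi2 = unpack(dihedrals_i2)
    for spec in specs:
        if spec.matches(phi1, psi1, phi2, psi2):
            return spec.name
    return "other"


@dataclass(frozen=True)
class TurnAssignment:
    """Evidence for a reverse turn over the window i…i+3."""

    window: tuple[tuple[str, int, str], ...]   # residue keys i..i+3
    state: str                                 # window name or "other"
    ca_distance_i_i3: float                    # Å
    stabilizing_hbonds: tuple[tuple[str, str, float], ...]
    polar_contacts: tuple[tuple[str, str, float], ...]
    st_loop: bool


def hairpin_evidence(
    model: StructureModel,
    chain: str,
    i: int,
    hbond_cutoff: float = 3.4,
    polar_cutoff: float = 3.6,
    ca_cutoff: float = 7.0,
    specs: Iterable[TurnWindowSpec] = DEFAULT_WINDOW_SPECS,
) -> TurnAssignment:
    """Geometric evidence for a β-hairpin / ST loop over residues i…i+3.

    ``i`` is the author residue number (res_seq) of the first window
    residue.  Reports the Cα(i)–Cα(i+3) distance, the i-carbonyl →
    (i+3)-side-chain-hydroxyl hydrogen bond (≤ ``hbond_cutoff``), the
    i-carbonyl → (i+3)-amide polar interaction (≤ ``polar_cutoff``), the
    dihedral window classification of (i+1, i+2), and whether the window is
    an ST loop (Ser/Thr at i+3 whose hydroxyl H-bonds the window backbone).
    """
    residues = model.chain(chain)
    by_seq = {r.res_seq: r for r in residues}
    try:
        window = [by_seq[i + k] for k in range(4)]
    except KeyError as exc:
        raise ValueError(f"residues {i}..{i+3} not all modeled in chain {chain}") from exc

    ca_i, ca_i3 = window[0].atom("CA"), window[3].atom("CA")
    o_i = window[0].atom("O")
    if ca_i is None or ca_i3 is None or o_i is None:
        raise ValueError("incomplete window: missing CA or carbonyl O")
    ca_distance = float(np.linalg.norm(ca_i.pos - ca_i3.pos))

    hydroxyl_name = {"SER": "OG", "THR": "OG1"}.get(window[3].res_name)
    hbonds: list[tuple[str, str, float]] = []
    st_loop = False
    if hydroxyl_name:
        oh = window[3].atom(hydroxyl_name)
        if oh is not None:
            d = float(np.linalg.norm(o_i.pos - oh.pos))
            if d <= hbond_cutoff:
                hbonds.append(
                    (f"{window[3].label}/{hydroxyl_name}", f"{window[0].label}/O", d)
                )
            # ST loop: the hydroxyl H-bonds a backbone N/O of the window,
            # excluding its own residue (covalent-neighbour geometry)
            for res in window[:3]:
                for name in ("O", "N"):
                    bb_atom = res.atom(name)
                    if bb_atom is None:
                        continue
                    if np.linalg.norm(bb_atom.pos - oh.pos) <= hbond_cutoff:
                        st_loop = True

    polar: list[tuple[str, str, float]] = []
    n_i3 = window[3].atom("N")
    if n_i3 is not None:
        d = float(np.linalg.norm(o_i.pos - n_i3.pos))
        if d <= polar_cutoff:
            polar.append((f"{window[3].label}/N", f"{window[0].label}/O", d))

    dihedrals = backbone_dihedrals(model, chain)
    by_key = {d.residue: d for d in dihedrals}
    try:
        state = classify_window(by_key[window[1].key], by_key[window[2].key], specs)
    except ValueError:
        state = "other"

    return TurnAssignment(
        window=tuple(r.key for r in window),
        state=state,
        ca_distance_i_i3=ca_distance,
        stabilizing_hbonds=tuple(hbonds),
        polar_contacts=tuple(polar),
        st_loop=bool(st_loop),
    )


# ---------------------------------------------------------------------------
# rigid superposition


def kabsch(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid fit of *mobile* onto *reference*.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation ≈ reference``; the RMSD is over the
    fitted points (weighted if weights are given).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must both be (n, 3)")
    w = np.ones(len(P)) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    cp = w @ P
    cq = w @ Q
    P0, Q0 = P - cp, Q - cq
    H = (P0 * w[:, None]).T @ Q0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    fitted = P @ R.T + t
    rmsd = float(np.sqrt(np.sum(w * np.sum((fitted - Q) ** 2, axis=1))))
    return R, t, rmsd


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    pairing: tuple[str, ...]
    n_atoms: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def superpose_segments(
    mobile: Sequence[Residue],
    reference: Sequence[Residue],
    pairing: Sequence[str] = ("N", "CA", "C", "O"),
) -> SuperpositionResult:
    """Rigidly superpose residue segments paired in order, atoms by name.

    ``mobile`` and ``reference`` are equal-length residue lists (e.g. the
    four loop residues from two structures); from each residue pair the
    atoms named in ``pairing`` are matched.  At least 3 atom pairs are
    required; a name missing from either residue raises ``KeyError``.
    """
    if len(mobile) != len(reference):
        raise ValueError("segments must pair the same number of residues")
    P, Q = [], []
    for rm, rr in zip(mobile, reference):
        for name in pairing:
            am, ar = rm.atom(name), rr.atom(name)
            if am is None:
                raise KeyError(f"atom {name!r} missing in {rm.label}")
            if ar is None:
                raise KeyError(f"atom {name!r} missing in {rr.label}")
            P.append(am.pos)
            Q.append(ar.pos)
    if len(P) < 3:
        raise ValueError("need at least 3 atom pairs for a rigid superposition")
    R, t, rmsd = kabsch(np.array(P), np.array(Q))
    return SuperpositionResult(R, t, rmsd, tuple(pairing), len(P))
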