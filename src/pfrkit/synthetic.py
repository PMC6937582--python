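"""Synthetic fixtures with exact ground truth for every analysis stage.

Generators here emulate the *inputs* of the pipeline, never its physics:

* :func:`build_peptide` — an internal-coordinate (NeRF) backbone builder
  placing N/CA/C/O (+ CB stub, + Ser OG / Thr OG1) at standard bond
  lengths/angles with caller-specified (ϕ, ψ, ω), so turn-geometry code can
  be tested against constructions whose dihedrals are known exactly;
* :func:`build_contact_scene` — a toy peptide/receptor scene with planted
  atom pairs at controlled distances and decoys safely outside the cutoff,
  with a ledger listing every planted pair and its intended class;
* :func:`make_jitter_traj` — per-residue isotropic Gaussian positional
  noise of known amplitude (closed-form RMSF: σ√3);
* :func:`make_switch_traj` / :func:`make_multistate_traj` — trajectories
  whose (i+1, i+2) dihedrals hop between named states with known
  per-frame assignments, so window-occupancy recovery can be checked
  exactly against the draw ledger.

All generators are deterministic under a fixed seed (one named
``numpy.random.default_rng`` per spec, seed recorded in the ledger).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .structure_io import AtomRecord, StructureModel
from .traj import TrajectoryEnsemble

__all__ = [
    "BuilderSpec",
    "JitterSpec",
    "SwitchSpec",
    "PlantedPair",
    "build_peptide",
    "build_contact_scene",
    "make_jitter_traj",
    "make_switch_traj",
    "make_multistate_traj",
    "IDEAL_TYPE_II",
    "FULLY_EXTENDED",
]

# standard backbone geometry (lengths in Å, angles in degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_CA_CB = 1.521
BOND_CB_OG = 1.417
ANGLE_C_N_CA = 121.7
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_CA_C_O = 120.5
ANGLE_N_CA_CB = 110.4
ANGLE_CA_CB_OG = 110.8

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

#: ideal type II β-turn central dihedrals: (ϕ,ψ)_{i+1}, (ϕ,ψ)_{i+2}
IDEAL_TYPE_II = ((-60.0, 120.0), (80.0, 0.0))
#: fully extended backbone
FULLY_EXTENDED = ((-180.0, 180.0), (-180.0, 180.0))


def _place(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, torsion_deg: float,
) -> np.ndarray:
    """NeRF: position d with |cd|=bond, ∠(b,c,d)=angle, τ(a,b,c,d)=torsion."""
    angle = np.radians(angle_deg)
    torsion = np.radians(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(angle),
            bond * np.sin(angle) * np.cos(torsion),
            bond * np.sin(angle) * np.sin(torsion),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass(frozen=True)
class BuilderSpec:
    """A peptide to build from per-residue (ϕ, ψ, ω) internal coordinates.

    ``dihedrals`` holds one (phi, psi, omega) triple per residue; phi of the
    first residue and psi/omega entries past the chain end are ignored.
    Omega defaults to 180° (trans) when given as None.
    """

    sequence: str
    dihedrals: tuple[tuple[float | None, float | None, float | None], ...]
    chain_id: str = "P"
    # Ser/Thr hydroxyl torsion N-CA-CB-OG; gauche+ points the hydroxyl back
    # toward the i-th carbonyl in a turn (the ST-loop capping rotamer)
    chi1: float = 65.0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        for aa in self.sequence:
            if aa not in _ONE_TO_THREE:
                raise ValueError(f"nonstandard residue {aa!r}")
        if len(self.dihedrals) != len(self.sequence):
            raise ValueError("one (phi, psi, omega) triple per residue required")

    @classmethod
    def uniform(cls, sequence: str, phi: float, psi: float, omega: float = 180.0,
                chain_id: str = "P") -> "BuilderSpec":
        return cls(sequence, tuple((phi, psi, omega) for _ in sequence), chain_id)

    @classmethod
    def turn(cls, sequence: str = "LSGS",
             central=IDEAL_TYPE_II, flank=(-120.0, 130.0),
             chain_id: str = "P") -> "BuilderSpec":
        """A 4-mer turn window: flank residues extended, i+1/i+2 at *central*."""
        if len(sequence) != 4:
            raise ValueError("turn spec needs a 4-residue sequence")
        (phi1, psi1), (phi2, psi2) = central
        d = (
            (None, flank[1], 180.0),
            (phi1, psi1, 180.0),
            (phi2, psi2, 180.0),
            (flank[0], flank[1], 180.0),
        )
        return cls(sequence, d, chain_id)


def build_peptide(spec: BuilderSpec) -> StructureModel:
    """Build backbone coordinates from internal coordinates (NeRF chaining).

    Atoms placed per residue: N, CA, C, O, plus a CB stub (except Gly) and
    the Ser OG / Thr OG1 hydroxyl.  Re-measuring ϕ/ψ/ω on the built chain
    reproduces the requested values within 0.5°.
    """
    n_res = len(spec.sequence)
    dihedrals = [
        (
            phi if phi is not None else -120.0,
            psi if psi is not None else 130.0,
            omega if omega is not None else 180.0,
        )
        for (phi, psi, omega) in spec.dihedrals
    ]

    # first residue: N at origin, CA on x, C in the xy-plane
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([BOND_N_CA, 0.0, 0.0])]
    ang = np.radians(180.0 - ANGLE_N_CA_C)
    C = [CA[0] + BOND_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, n_res):
        psi_prev = dihedrals[i - 1][1]
        omega_prev = dihedrals[i - 1][2]
        phi_i = dihedrals[i][0]
        N.append(_place(N[i - 1], CA[i - 1], C[i - 1], BOND_C_N, ANGLE_CA_C_N, psi_prev))
        CA.append(_place(CA[i - 1], C[i - 1], N[i], BOND_N_CA, ANGLE_C_N_CA, omega_prev))
        C.append(_place(C[i - 1], N[i], CA[i], BOND_CA_C, ANGLE_N_CA_C, phi_i))

    atoms: list[AtomRecord] = []
    serial = 0

    def add(name: str, element: str, res_i: int, pos: np.ndarray) -> None:
        nonlocal serial
        serial += 1
        atoms.append(
            AtomRecord(
                serial=serial, name=name, element=element, alt_loc="",
                res_name=_ONE_TO_THREE[spec.sequence[res_i]],
                chain_id=spec.chain_id, res_seq=res_i + 1, icode="",
                x=float(pos[0]), y=float(pos[1]), z=float(pos[2]),
                occupancy=1.0, b_iso=20.0,
            )
        )

    for i in range(n_res):
        add("N", "N", i, N[i])
        add("CA", "C", i, CA[i])
        add("C", "C", i, C[i])
        # carbonyl O anti to the next amide (torsion psi+180 about N-CA-C)
        psi_i = dihedrals[i][1]
        O = _place(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O, psi_i + 180.0)
        add("O", "O", i, O)
        aa = spec.sequence[i]
        if aa != "G":
            # CB from the improper N-C-CA frame; ~ +122.6° gives L-chirality
            CB = _place(N[i], C[i], CA[i], BOND_CA_CB, ANGLE_N_CA_CB, 122.6)
            add("CB", "C", i, CB)
            if aa in ("S", "T"):
                OG = _place(N[i], CA[i], CB, BOND_CB_OG, ANGLE_CA_CB_OG, spec.chi1)
                add("OG" if aa == "S" else "OG1", "O", i, OG)
    return StructureModel(atoms, model_id=1)


# ---------------------------------------------------------------------------
# contact scenes


@dataclass(frozen=True)
class PlantedPair:
    """Ledger entry: one intended peptide/receptor contact."""

    peptide_residue: tuple[str, int, str]
    peptide_atom: str
    receptor_residue: tuple[str, int, str]
    receptor_atom: str
    distance: float
    kind: str  # intended class: "hbond" or "vdw"


def build_contact_scene(
    n_planted: int,
    distances: Sequence[float],
    decoys: int = 0,
    seed: int = 0,
    hbond_cutoff: float = 3.4,
    decoy_min_distance: float = 4.5,
) -> tuple[StructureModel, list[PlantedPair]]:
    """A toy peptide ("P") / receptor ("R") scene with planted contacts.

    Exactly ``n_planted`` peptide/receptor atom pairs sit at the requested
    distances (cycled if fewer distances than pairs are given); pairs at or
    under ``hbond_cutoff`` are planted with hydrogen-bond chemistry
    (Ser OG ↔ backbone O), longer pairs as carbon–carbon (vdW-only).
    ``decoys`` extra receptor atoms are placed at least
    ``decoy_min_distance`` from every peptide atom.  Pair sites are spaced
    20 Å apart so no accidental cross-pair contact can occur.  The ledger
    lists every planted pair with its intended class.
    """
    if any(d <= 0 for d in distances):
        raise ValueError("planted distances must be positive")
    if n_planted > 0 and not distances:
        raise ValueError("no distances given for planted pairs")
    rng = np.random.default_rng(seed)
    atoms: list[AtomRecord] = []
    ledger: list[PlantedPair] = []
    serial = 0

    def add(name, element, res_name, chain, res_seq, pos, b=20.0) -> AtomRecord:
        nonlocal serial
        serial += 1
        a = AtomRecord(
            serial=serial, name=name, element=element, alt_loc="",
            res_name=res_name, chain_id=chain, res_seq=res_seq, icode="",
            x=float(pos[0]), y=float(pos[1]), z=float(pos[2]),
            occupancy=1.0, b_iso=b,
        )
        atoms.append(a)
        return a

    spacing = 20.0
    for k in range(n_planted):
        d = float(distances[k % len(distances)])
        base = np.array([spacing * k, 0.0, 0.0])
        hbond = d <= hbond_cutoff
        if hbond:
            pep = add("OG", "O", "SER", "P", k + 1, base)
            add("CB", "C", "SER", "P", k + 1, base + np.array([0.0, 0.0, 8.0]))
            rec = add("O", "O", "GLY", "R", k + 1, base + np.array([d, 0.0, 0.0]))
        else:
            pep = add("CB", "C", "ALA", "P", k + 1, base)
            add("CA", "C", "ALA", "P", k + 1, base + np.array([0.0, 0.0, 8.0]))
            rec = add("CB", "C", "ALA", "R", k + 1, base + np.array([d, 0.0, 0.0]))
        ledger.append(
            PlantedPair(
                peptide_residue=("P", k + 1, ""), peptide_atom=pep.name,
                receptor_residue=("R", k + 1, ""), receptor_atom=rec.name,
                distance=d, kind="hbond" if hbond else "vdw",
            )
        )
    if n_planted == 0:
        # still provide a peptide atom so downstream selections are non-empty
        add("CA", "C", "ALA", "P", 1, np.array([0.0, 0.0, 0.0]))

    for j in range(decoys):
        jitter = rng.uniform(-1.0, 1.0, size=3)
        pos = np.array([spacing * (j % max(n_planted, 1)),
                        decoy_min_distance + 10.0 + 3.0 * (j // max(n_planted, 1)),
                        0.0]) + jitter
        add("CB", "C", "ALA", "R", 1000 + j, pos, b=30.0)
    return StructureModel(atoms, model_id=1), ledger


# ---------------------------------------------------------------------------
# trajectories


@dataclass(frozen=True)
class JitterSpec:
    """Gaussian positional noise around a base model.

    ``sigma`` is the per-coordinate (isotropic) standard deviation in Å,
    either one value for every atom or a per-residue mapping
    ``res_seq → σ`` applied to all atoms of that residue.
    """

    base: StructureModel
    sigma: float | Mapping[int, float]
    n_frames: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        sigmas = (
            [self.sigma] if isinstance(self.sigma, (int, float))
            else list(self.sigma.values())
        )
        if any(s < 0 for s in sigmas):
            raise ValueError("sigma must be non-negative")


def make_jitter_traj(spec: JitterSpec) -> tuple[TrajectoryEnsemble, dict]:
    """Frames = base coordinates + N(0, σ²) per coordinate; σ ledger returned."""
    base_xyz = spec.base.coords()
    if isinstance(spec.sigma, (int, float)):
        per_atom = np.full(len(spec.base.atoms), float(spec.sigma))
    else:
        per_atom = np.array(
            [float(spec.sigma.get(a.res_seq, 0.0)) for a in spec.base.atoms]
        )
    rng = np.random.default_rng(spec.seed)
    noise = rng.normal(0.0, 1.0, size=(spec.n_frames, len(per_atom), 3))
    frames = base_xyz[None, :, :] + noise * per_atom[None, :, None]
    ledger = {
        "seed": spec.seed,
        "n_frames": spec.n_frames,
        "sigma_per_atom": per_atom.tolist(),
        "sigma_per_residue": {
            a.res_seq: float(s) for a, s in zip(spec.base.atoms, per_atom)
        },
    }
    return TrajectoryEnsemble(spec.base, frames), ledger


def make_multistate_traj(
    base: BuilderSpec,
    window: tuple[int, int],
    states: Mapping[str, tuple[tuple[float, float], tuple[float, float]]],
    probs: Mapping[str, float],
    n_frames: int,
    seed: int = 0,
    jitter_sigma: float = 0.0,
) -> tuple[TrajectoryEnsemble, dict]:
    """Frames hopping between named dihedral states of the (i+1, i+2) window.

    ``window`` gives the 1-based residue indices of (i+1, i+2) in the base
    sequence; each state maps to ((ϕ,ψ)_{i+1}, (ϕ,ψ)_{i+2}) targets used to
    rebuild the chain for frames drawn into that state.  ``probs`` are the
    state probabilities (must sum to 1).  The ledger records the per-frame
    state names and their exact empirical fractions — downstream
    window-occupancy classification of noise-free frames matches it exactly.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    names = list(states)
    p = np.array([probs[n] for n in names], dtype=float)
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("state probabilities must be non-negative and sum to 1")
    if jitter_sigma < 0:
        raise ValueError("jitter_sigma must be non-negative")
    i1, i2 = window
    templates: dict[str, np.ndarray] = {}
    topology: StructureModel | None = None
    for name in names:
        (phi1, psi1), (phi2, psi2) = states[name]
        d = list(base.dihedrals)
        d[i1 - 1] = (phi1, psi1, d[i1 - 1][2])
        d[i2 - 1] = (phi2, psi2, d[i2 - 1][2])
        model = build_peptide(BuilderSpec(base.sequence, tuple(d), base.chain_id, base.chi1))
        templates[name] = model.coords()
        if topology is None:
            topology = model

    rng = np.random.default_rng(seed)
    draws = rng.choice(len(names), size=n_frames, p=p)
    frames = np.stack([templates[names[k]] for k in draws])
    if jitter_sigma > 0:
        frames = frames + rng.normal(0.0, jitter_sigma, size=frames.shape)
    state_seq = tuple(names[k] for k in draws)
    ledger = {
        "seed": seed,
        "n_frames": n_frames,
        "states": state_seq,
        "fractions": {n: state_seq.count(n) / n_frames for n in names},
    }
    assert topology is not None
    return TrajectoryEnsemble(topology, frames), ledger


@dataclass(frozen=True)
class SwitchSpec:
    """Two-state dihedral switching with known state-A probability."""

    base: BuilderSpec
    window: tuple[int, int]
    state_a: tuple[tuple[float, float], tuple[float, float]]
    state_b: tuple[tuple[float, float], tuple[float, float]]
    p_a: float
    n_frames: int
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_a <= 1.0:
            raise ValueError("p_a must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")


def make_switch_traj(spec: SwitchSpec) -> tuple[TrajectoryEnsemble, dict]:
    """Bernoulli(p_a) switching between states "A" and "B"; per-frame ledger."""
    return make_multistate_traj(
        spec.base,
        spec.window,
        {"A": spec.state_a, "B": spec.state_b},
        {"A": spec.p_a, "B": 1.0 - spec.p_a},
        spec.n_frames,
        seed=spec.seed,
    )
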