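"""Trajectory statistics: RMSF, contact fractions, dihedral occupancy, clustering.

A :class:`TrajectoryEnsemble` is an ordered stack of coordinate frames over a
shared topology (a :class:`~pfrkit.structure_io.StructureModel`); the minimum
on-disk dialect is multi-model PDB.  The statistics implemented here are the
standard post-processing of peptide/MHC molecular-dynamics runs:

* per-residue Cα RMSF about the time-averaged position, after a
  mass-weighted rigid fit of the receptor Cα atoms onto the first frame;
* per-residue share of the total peptide-to-receptor contact count
  (all atoms including hydrogens within 3.0 Å, the MD convention);
* occupancy of named (ϕ,ψ) turn windows over time (e.g. the fraction of
  frames in which the C-terminal hairpin is maintained);
* hierarchical agglomerative conformational clustering with a minimum
  inter-cluster distance stopping rule (CPPTRAJ-style ε, default 2.5 Å),
  medoid representatives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist, squareform

from .structure_io import StructureModel, read_structure, write_pdb
from .turn_geometry import DEFAULT_WINDOW_SPECS, TurnWindowSpec, dihedral

__all__ = [
    "TrajectoryEnsemble",
    "RMSFProfile",
    "OccupancyStats",
    "ClusterResult",
    "ATOMIC_MASSES",
    "fit_frames",
    "rmsf",
    "contact_fraction",
    "dihedral_occupancy",
    "cluster_frames",
]

ATOMIC_MASSES = {
    "H": 1.008, "D": 2.014, "C": 12.011, "N": 14.007, "O": 15.999,
    "S": 32.06, "P": 30.974, "SE": 78.971, "FE": 55.845, "ZN": 65.38,
    "MG": 24.305, "CA": 40.078, "NA": 22.990, "CL": 35.45, "K": 39.098,
}


def _masses(model: StructureModel, indices: Sequence[int]) -> np.ndarray:
    return np.array(
        [ATOMIC_MASSES.get(model.atoms[i].element.upper(), 12.0) for i in indices]
    )


@dataclass
class TrajectoryEnsemble:
    """Ordered coordinate frames congruent with a shared topology."""

    topology: StructureModel
    frames: np.ndarray               # (n_frames, n_atoms, 3)
    frame_interval: float | None = None  # metadata only (e.g. ns between frames)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must be (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("a trajectory needs at least one frame")
        if self.frames.shape[1] != len(self.topology.atoms):
            raise ValueError("frame atom count does not match topology")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    def frame_model(self, t: int) -> StructureModel:
        return self.topology.with_coords(self.frames[t])

    def strided(self, stride: int) -> "TrajectoryEnsemble":
        if stride < 1:
            raise ValueError("stride must be >= 1")
        return TrajectoryEnsemble(self.topology, self.frames[::stride], self.frame_interval)

    @classmethod
    def from_models(
        cls, models: Sequence[StructureModel], frame_interval: float | None = None
    ) -> "TrajectoryEnsemble":
        if not models:
            raise ValueError("no models given")
        ref = [(a.chain_id, a.res_seq, a.icode, a.name) for a in models[0].atoms]
        for m in models[1:]:
            sig = [(a.chain_id, a.res_seq, a.icode, a.name) for a in m.atoms]
            if sig != ref:
                raise ValueError(
                    f"model {m.model_id} is not congruent with the first model"
                )
        frames = np.stack([m.coords() for m in models])
        return cls(models[0], frames, frame_interval)

    @classmethod
    def from_pdb(cls, path, frame_interval: float | None = None) -> "TrajectoryEnsemble":
        """Read a multi-model PDB as a trajectory."""
        return cls.from_models(read_structure(path, format="pdb"), frame_interval)

    def to_pdb(self, path) -> None:
        models = []
        for t in range(self.n_frames):
            m = self.topology.with_coords(self.frames[t])
            m.model_id = t + 1
            models.append(m)
        write_pdb(models, path)


def fit_frames(
    traj: TrajectoryEnsemble,
    fit_indices: Sequence[int],
    mass_weighted: bool = True,
) -> TrajectoryEnsemble:
    """Rigidly superpose every frame onto frame 0 using the fit selection.

    The rotation/translation minimises the (mass-weighted, by default) RMSD
    of the fit-selection atoms to their frame-0 positions and is applied to
    *all* atoms of the frame.
    """
    from .turn_geometry import kabsch

    fit_indices = list(fit_indices)
    if not fit_indices:
        raise ValueError("empty fit selection")
    weights = _masses(traj.topology, fit_indices) if mass_weighted else None
    ref = traj.frames[0][fit_indices]
    out = np.empty_like(traj.frames)
    out[0] = traj.frames[0]
    for t in range(1, traj.n_frames):
        R, trans, _ = kabsch(traj.frames[t][fit_indices], ref, weights)
        out[t] = traj.frames[t] @ R.T + trans
    return TrajectoryEnsemble(traj.topology, out, traj.frame_interval)


@dataclass(frozen=True)
class RMSFProfile:
    """Per-residue Cα root-mean-square fluctuation about the time average."""

    entries: tuple[tuple[tuple[str, int, str], str, float], ...]
    n_frames: int
    fit_selection: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"chain": k[0], "res_seq": k[1], "res_name": name, "rmsf": v}
                for k, name, v in self.entries
            ]
        )

    def values(self) -> np.ndarray:
        return np.array([v for _, _, v in self.entries])


def rmsf(
    traj: TrajectoryEnsemble,
    chain: str,
    atom_name: str = "CA",
    fit_selection: str = "as-given",
) -> RMSFProfile:
    """RMSF_r = sqrt(mean_t ||x_r(t) − <x_r>||²) for each *atom_name* of *chain*.

    The trajectory is used as given — fit first (:func:`fit_frames`) if
    global rigid motion should be removed.  ``fit_selection`` is a free-text
    record of that choice carried into the profile.
    """
    if traj.n_frames < 2:
        raise ValueError("insufficient frames: RMSF needs at least 2")
    idx, meta = [], []
    for i, a in enumerate(traj.topology.atoms):
        if a.chain_id == chain and a.name == atom_name:
            idx.append(i)
            meta.append(((a.chain_id, a.res_seq, a.icode), a.res_name))
    if not idx:
        raise ValueError(f"no {atom_name!r} atoms in chain {chain!r}")
    X = traj.frames[:, idx, :]               # (T, R, 3)
    mean = X.mean(axis=0)
    fluct = np.sqrt(np.mean(np.sum((X - mean) ** 2, axis=2), axis=0))
    entries = tuple((meta[r][0], meta[r][1], float(fluct[r])) for r in range(len(idx)))
    return RMSFProfile(entries=entries, n_frames=traj.n_frames, fit_selection=fit_selection)


def contact_fraction(
    traj: TrajectoryEnsemble,
    peptide_chain: str,
    receptor_chains: Iterable[str],
    cutoff: float = 3.0,
    hydrogen_policy: Literal["include", "exclude"] = "include",
) -> pd.DataFrame:
    """Each peptide residue's percentage of the summed contact count.

    Per frame, every peptide-atom/receptor-atom pair within ``cutoff``
    counts one contact for the peptide residue; percentages are shares of
    the total over all frames and residues (summing to 100 % whenever any
    contact exists).  The MD convention is all atoms including modeled
    hydrogens within 3.0 Å.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    top = traj.topology
    include_h = hydrogen_policy == "include"
    pep_idx = top.select([peptide_chain], include_hydrogens=include_h, include_waters=False)
    rec_idx = top.select(list(receptor_chains), include_hydrogens=include_h, include_waters=False)
    if not pep_idx:
        raise ValueError(f"empty peptide selection (chain {peptide_chain!r})")
    if not rec_idx:
        raise ValueError("empty receptor selection")

    res_keys: list[tuple[str, int, str]] = []
    atom_res: list[int] = []
    for i in pep_idx:
        k = top.atoms[i].residue_key()
        if k not in res_keys:
            res_keys.append(k)
        atom_res.append(res_keys.index(k))
    atom_res_arr = np.array(atom_res)

    counts = np.zeros(len(res_keys), dtype=np.int64)
    for t in range(traj.n_frames):
        xyz = traj.frames[t]
        tree = cKDTree(xyz[rec_idx])
        hits = tree.query_ball_point(xyz[pep_idx], r=cutoff)
        n_hits = np.array([len(h) for h in hits])
        np.add.at(counts, atom_res_arr, n_hits)

    total = counts.sum()
    pct = np.zeros(len(res_keys)) if total == 0 else 100.0 * counts / total
    rows = []
    for r, k in enumerate(res_keys):
        name = next(top.atoms[i].res_name for i in pep_idx if top.atoms[i].residue_key() == k)
        rows.append(
            {
                "res_seq": k[1],
                "res_name": name,
                "contacts": int(counts[r]),
                "pct": float(pct[r]),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OccupancyStats:
    """Fraction of frames per named dihedral window state."""

    fractions: dict[str, float]
    per_frame: tuple[str, ...]
    joint: bool

    def __post_init__(self) -> None:
        for v in self.fractions.values():
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError("fractions must lie in [0, 1]")


def _window_dihedrals(
    traj: TrajectoryEnsemble, chain: str, res_seq: int
) -> tuple[np.ndarray, np.ndarray]:
    """(phi, psi) per frame for one residue, vectorised over frames."""
    top = traj.topology
    residues = top.chain(chain)
    by_seq = {r.res_seq: r for r in residues}
    order = sorted(by_seq)
    pos = order.index(res_seq)
    if pos == 0 or pos == len(order) - 1:
        raise ValueError(f"residue {res_seq} is a terminus: dihedrals undefined")

    def atom_index(seq: int, name: str) -> int:
        res = by_seq[seq]
        for i, a in enumerate(top.atoms):
            if a.residue_key() == res.key and a.name == name:
                return i
        raise ValueError(f"frame topology lacks atom {name} of residue {seq}")

    c_prev = atom_index(order[pos - 1], "C")
    n = atom_index(res_seq, "N")
    ca = atom_index(res_seq, "CA")
    c = atom_index(res_seq, "C")
    n_next = atom_index(order[pos + 1], "N")
    phis = np.empty(traj.n_frames)
    psis = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        f = traj.frames[t]
        phis[t] = dihedral(f[c_prev], f[n], f[ca], f[c])
        psis[t] = dihedral(f[n], f[ca], f[c], f[n_next])
    return phis, psis


def dihedral_occupancy(
    traj: TrajectoryEnsemble,
    chain: str,
    res_i1: int,
    res_i2: int,
    specs: Sequence[TurnWindowSpec] = DEFAULT_WINDOW_SPECS,
    joint: bool = True,
) -> OccupancyStats:
    """Per-frame window classification of the (i+1, i+2) residues, aggregated.

    ``joint=True`` requires both residues inside a spec's respective targets
    simultaneously; ``joint=False`` classifies on the i+2 residue alone
    (the residue whose state change opens the turn).  States are exclusive
    and exhaustive: the first matching spec wins, unmatched frames are
    "other", so the reported fractions sum to 1.
    """
    phi1, psi1 = _window_dihedrals(traj, chain, res_i1)
    phi2, psi2 = _window_dihedrals(traj, chain, res_i2)
    states: list[str] = []
    for t in range(traj.n_frames):
        state = "other"
        for spec in specs:
            ok = (
                spec.matches(phi1[t], psi1[t], phi2[t], psi2[t])
                if joint
                else spec.matches_i2(phi2[t], psi2[t])
            )
            if ok:
                state = spec.name
                break
        states.append(state)
    names = [s.name for s in specs] + ["other"]
    fr = {name: states.count(name) / len(states) for name in names}
    return OccupancyStats(fractions=fr, per_frame=tuple(states), joint=joint)


@dataclass(frozen=True)
class ClusterResult:
    """Partition of trajectory frames into conformational clusters."""

    labels: np.ndarray                  # cluster id per frame (0-based, by size)
    clusters: tuple[dict, ...]          # id, members, representative (medoid)
    threshold: float
    linkage: str

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def cluster_frames(
    traj: TrajectoryEnsemble,
    selection: Sequence[int],
    threshold: float = 2.5,
    linkage: Literal["average", "complete", "single"] = "average",
    max_frames: int = 5000,
) -> ClusterResult:
    """Hierarchical agglomerative clustering of frames on selection RMSD.

    The pairwise metric is the coordinate RMSD over the selected atoms
    (frames are assumed already fitted to a common reference, as produced
    by :func:`fit_frames`).  Agglomeration stops when the minimum
    inter-cluster distance (under the chosen linkage) exceeds
    ``threshold`` — the ε stopping rule of CPPTRAJ's hieragglo.  Clusters
    are ordered by population; each representative is the medoid.

    The exact pairwise matrix is quadratic in frames; beyond ``max_frames``
    pre-stride the trajectory explicitly (``traj.strided(k)``).
    """
    selection = list(selection)
    if not selection:
        raise ValueError("empty selection")
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if traj.n_frames > max_frames:
        raise ValueError(
            f"{traj.n_frames} frames exceed the exact-matrix guard ({max_frames}); "
            "apply a stride first"
        )
    X = traj.frames[:, selection, :].reshape(traj.n_frames, -1)
    if traj.n_frames == 1:
        return ClusterResult(
            labels=np.zeros(1, dtype=int),
            clusters=({"id": 0, "members": (0,), "representative": 0},),
            threshold=threshold,
            linkage=linkage,
        )
    condensed = pdist(X) / np.sqrt(len(selection))   # Euclidean → RMSD
    Z = scipy_linkage(condensed, method=linkage)
    raw = fcluster(Z, t=threshold, criterion="distance")

    D = squareform(condensed)
    groups: dict[int, list[int]] = {}
    for t, lab in enumerate(raw):
        groups.setdefault(int(lab), []).append(t)
    ordered = sorted(groups.values(), key=lambda m: (-len(m), m[0]))
    labels = np.empty(traj.n_frames, dtype=int)
    clusters = []
    for cid, members in enumerate(ordered):
        labels[members] = cid
        sub = D[np.ix_(members, members)]
        medoid = members[int(np.argmin(sub.sum(axis=1)))]
        clusters.append({"id": cid, "members": tuple(members), "representative": medoid})
    return ClusterResult(
        labels=labels, clusters=tuple(clusters), threshold=threshold, linkage=linkage
    )
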