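"""End-to-end report bundles: crystal-structure and trajectory analyses.

``run_crystal_analysis`` chains register assignment, B-factor profiling,
contact enumeration/summary, hairpin evidence and (optionally) native-loop
superposition on a static structure; ``run_traj_analysis`` chains RMSF,
contact fractions, dihedral-window occupancy and conformational clustering
on a multi-model ensemble.  Every artifact is TSV (tables) or JSON (nested
results); the configuration is serialized verbatim into each bundle's
MANIFEST so a run can be reproduced byte-identically (the MANIFEST's
timestamp is the only varying field).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import contacts as contacts_mod
from . import traj as traj_mod
from .register import assign_register, declare_sequence_gap
from .structure_io import apply_altloc_policy, bfactor_profile, read_structure
from .turn_geometry import hairpin_evidence, superpose_segments

logger = logging.getLogger("pfrkit")

__all__ = ["RunConfig", "run_crystal_analysis", "run_traj_analysis"]


@dataclass
class RunConfig:
    """Flat parameter set shared by the pipeline stages."""

    structure: str = ""
    trajectory: str = ""
    peptide_chain: str = "C"
    receptor_chains: tuple[str, ...] = ("A", "B")
    core_start: int = 1
    declared_sequence: str = ""
    vdw_cutoff: float = 4.0
    hbond_cutoff: float = 3.4
    polar_cutoff: float = 3.6
    ca_cutoff: float = 7.0
    md_contact_cutoff: float = 3.0
    tolerance_deg: float = 40.0
    cluster_threshold: float = 2.5
    cluster_linkage: str = "average"
    altloc_policy: str = "highest_occupancy"
    hydrogen_policy: str = "exclude"
    hairpin_start: int | None = None   # res_seq of window residue i
    native_structure: str = ""         # optional reference for loop superposition
    native_chain: str = ""
    native_range: tuple[int, int] | None = None
    mobile_range: tuple[int, int] | None = None
    pairing: tuple[str, ...] = ("N", "CA", "C", "O")
    stride: int = 1
    seed: int = 0
    outdir: str = "pfrkit_out"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("receptor_chains", "pairing"):
            if key in raw and isinstance(raw[key], str):
                raw[key] = tuple(s.strip() for s in raw[key].split(","))
            elif key in raw:
                raw[key] = tuple(raw[key])
        for key in ("native_range", "mobile_range"):
            if raw.get(key):
                raw[key] = tuple(int(v) for v in raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _write_manifest(outdir: Path, config: RunConfig, artifacts: list[str], status: str) -> None:
    manifest = {
        "status": status,
        "artifacts": artifacts,
        "config": config.to_dict(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "MANIFEST.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def run_crystal_analysis(config: RunConfig) -> Path:
    """Static-structure bundle: register, B-factors, contacts, turn geometry.

    Writes register.tsv, bfactor.tsv, contact_table.tsv, contact_pairs.json,
    turn.json (if a hairpin window is configured), superposition.json (if a
    native reference is configured) and MANIFEST.json into ``config.outdir``.
    Raises on stage errors after writing a failure MANIFEST.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    try:
        models = read_structure(config.structure)
        model = apply_altloc_policy(models[0], config.altloc_policy)
        logger.info(
            "loaded %s (%d models; analyzing model %d with %d atoms)",
            config.structure, len(models), model.model_id, len(model),
        )

        reg = assign_register(model, config.peptide_chain, config.core_start)
        reg_df = reg.to_frame()
        reg_df.to_csv(outdir / "register.tsv", sep="\t", index=False)
        artifacts.append("register.tsv")
        if config.declared_sequence:
            gaps = declare_sequence_gap(reg, config.declared_sequence)
            (outdir / "gaps.json").write_text(
                json.dumps({str(k): v for k, v in gaps.items()}, indent=2) + "\n"
            )
            artifacts.append("gaps.json")

        prof = bfactor_profile(model, config.peptide_chain)
        prof.to_frame().to_csv(outdir / "bfactor.tsv", sep="\t", index=False)
        artifacts.append("bfactor.tsv")

        pairs = contacts_mod.find_contacts(
            model,
            config.peptide_chain,
            config.receptor_chains,
            vdw_cutoff=config.vdw_cutoff,
            hbond_cutoff=config.hbond_cutoff,
            hydrogen_policy=config.hydrogen_policy,
        )
        table = contacts_mod.summarize_contacts(pairs, reg)
        # Table-style TSV: per-residue rows then region totals, headers vdW/H-bonds/Total
        rows = table.rows.rename(
            columns={"vdw": "vdW", "hbonds": "H-bonds", "total": "Total"}
        )
        rows.to_csv(outdir / "contact_table.tsv", sep="\t", index=False)
        table.region_totals.rename(
            columns={"vdw": "vdW", "hbonds": "H-bonds", "total": "Total"}
        ).to_csv(outdir / "contact_regions.tsv", sep="\t")
        pair_dump = [
            {
                "peptide": f"{p.peptide_atom.res_name}-{p.peptide_atom.res_seq}/{p.peptide_atom.name}",
                "receptor": f"{p.receptor_atom.res_name}-{p.receptor_atom.chain_id}{p.receptor_atom.res_seq}/{p.receptor_atom.name}",
                "distance": round(p.distance, 3),
                "kind": p.kind,
            }
            for p in pairs
        ]
        (outdir / "contact_pairs.json").write_text(json.dumps(pair_dump, indent=2) + "\n")
        artifacts += ["contact_table.tsv", "contact_regions.tsv", "contact_pairs.json"]

        if config.hairpin_start is not None:
            ta = hairpin_evidence(
                model,
                config.peptide_chain,
                config.hairpin_start,
                hbond_cutoff=config.hbond_cutoff,
                polar_cutoff=config.polar_cutoff,
                ca_cutoff=config.ca_cutoff,
            )
            (outdir / "turn.json").write_text(
                json.dumps(
                    {
                        "window": [list(k) for k in ta.window],
                        "state": ta.state,
                        "ca_distance_i_i3": round(ta.ca_distance_i_i3, 3),
                        "within_ca_cutoff": ta.ca_distance_i_i3 <= config.ca_cutoff,
                        "stabilizing_hbonds": [list(h) for h in ta.stabilizing_hbonds],
                        "polar_contacts": [list(h) for h in ta.polar_contacts],
                        "st_loop": ta.st_loop,
                    },
                    indent=2,
                    default=str,
                )
                + "\n"
            )
            artifacts.append("turn.json")

        if config.native_structure and config.native_range and config.mobile_range:
            native = apply_altloc_policy(
                read_structure(config.native_structure)[0], config.altloc_policy
            )
            nat_res = [
                r
                for r in native.chain(config.native_chain)
                if config.native_range[0] <= r.res_seq <= config.native_range[1]
            ]
            mob_res = [
                r
                for r in model.chain(config.peptide_chain)
                if config.mobile_range[0] <= r.res_seq <= config.mobile_range[1]
            ]
            sup = superpose_segments(mob_res, nat_res, config.pairing)
            (outdir / "superposition.json").write_text(
                json.dumps(
                    {
                        "rmsd": round(sup.rmsd, 4),
                        "pairing": list(sup.pairing),
                        "n_atoms": sup.n_atoms,
                    },
                    indent=2,
                )
                + "\n"
            )
            artifacts.append("superposition.json")
    except Exception:
        _write_manifest(outdir, config, artifacts, status="failed")
        raise
    _write_manifest(outdir, config, artifacts, status="ok")
    return outdir


def run_traj_analysis(config: RunConfig) -> Path:
    """Trajectory bundle: RMSF, contact fractions, occupancy, clustering."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[str] = []
    try:
        ens = traj_mod.TrajectoryEnsemble.from_pdb(config.trajectory)
        if config.stride > 1:
            ens = ens.strided(config.stride)
        logger.info("trajectory: %d frames, %d atoms", ens.n_frames, len(ens.topology))

        fit_idx = ens.topology.select(
            list(config.receptor_chains), include_waters=False, names=["CA"]
        )
        fitted = traj_mod.fit_frames(ens, fit_idx) if fit_idx else ens
        fit_desc = (
            f"mass-weighted CA fit on chains {','.join(config.receptor_chains)}"
            if fit_idx
            else "no fit (no receptor CA atoms)"
        )

        profile = traj_mod.rmsf(fitted, config.peptide_chain, fit_selection=fit_desc)
        profile.to_frame().to_csv(outdir / "rmsf.tsv", sep="\t", index=False)
        artifacts.append("rmsf.tsv")

        try:
            cf = traj_mod.contact_fraction(
                fitted,
                config.peptide_chain,
                config.receptor_chains,
                cutoff=config.md_contact_cutoff,
                hydrogen_policy="include",
            )
            cf.to_csv(outdir / "contact_fraction.tsv", sep="\t", index=False)
            artifacts.append("contact_fraction.tsv")
        except ValueError as exc:
            logger.info("contact fractions skipped: %s", exc)

        if config.hairpin_start is not None:
            occ = traj_mod.dihedral_occupancy(
                fitted,
                config.peptide_chain,
                config.hairpin_start + 1,
                config.hairpin_start + 2,
            )
            (outdir / "occupancy.json").write_text(
                json.dumps(
                    {"fractions": occ.fractions, "joint": occ.joint,
                     "n_frames": len(occ.per_frame)},
                    indent=2,
                )
                + "\n"
            )
            artifacts.append("occupancy.json")

        sel = ens.topology.select([config.peptide_chain], include_waters=False)
        cl = traj_mod.cluster_frames(
            fitted, sel, threshold=config.cluster_threshold,
            linkage=config.cluster_linkage,
        )
        (outdir / "clusters.json").write_text(
            json.dumps(
                {
                    "n_clusters": cl.n_clusters,
                    "threshold": cl.threshold,
                    "linkage": cl.linkage,
                    "clusters": [
                        {
                            "id": c["id"],
                            "population": len(c["members"]),
                            "representative": c["representative"],
                        }
                        for c in cl.clusters
                    ],
                },
                indent=2,
            )
            + "\n"
        )
        artifacts.append("clusters.json")
    except Exception:
        _write_manifest(outdir, config, artifacts, status="failed")
        raise
    _write_manifest(outdir, config, artifacts, status="ok")
    return outdir
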