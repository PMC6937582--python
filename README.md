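# pfrkit

Structural and trajectory analysis of **peptide-flanking residues (PFRs)**
in HLA class II epitopes.

## The problem

HLA class II molecules present peptides in an open-ended groove: nine
residues (the *core nonamer*, P1–P9, with anchor side chains in pockets P1,
P4, P6 and P9) sit inside the groove, and the overhanging residues — the
PFRs, numbered P(−1), P(−2), … before P1 and P10, P11, … after P9 — extend
beyond it. PFRs can contribute real anchoring contacts to the HLA, and the
C-terminal flank can fold back on itself as a four-residue reverse turn
(a type II β-turn capped by a serine/threonine hydroxyl — an *ST loop*),
echoing the secondary structure the same residues adopt in the native
antigen. Dissecting these features requires a chain of small, well-defined
geometric analyses on crystal structures and MD ensembles; `pfrkit`
implements that chain as a tested library plus a thin CLI, for structural
immunologists working on pMHC-II systems.

## What it computes

| Stage | Statistic |
|---|---|
| `pfrkit.structure_io` | PDB/mmCIF parsing, altloc policy, per-residue mean B with flexibility categories (stable < 40 Å² < intermediate < 80 Å² < high-flex) |
| `pfrkit.register` | residue → P-position mapping from a declared core start; N-PFR / core / C-PFR partition; unmodeled-residue gap reports |
| `pfrkit.contacts` | peptide↔receptor atom pairs within 4.0 Å, partitioned into H-bonds (donor/acceptor chemistry within 3.4 Å) and van der Waals contacts; per-residue and per-region tables, per-atom detail |
| `pfrkit.turn_geometry` | backbone ϕ/ψ/ω; wrap-aware (ϕ,ψ)-window classification (type II β-turn: (−60°, +120°)/(+80°, 0°); glycine-extended: ψ = ±140° at i+2; ±40° tolerance); hairpin/ST-loop evidence; Kabsch superposition RMSD |
| `pfrkit.traj` | per-residue Cα RMSF after a mass-weighted receptor-Cα fit; per-residue share of trajectory contacts (< 3.0 Å, hydrogens included); dihedral-window occupancy over time; hierarchical agglomerative clustering with a minimum inter-cluster distance ε = 2.5 Å |
| `pfrkit.synthetic` | internal-coordinate peptide builder, planted contact scenes, jitter and dihedral-switch trajectories — fixtures with exact ground truth |

Key formulas: RMSF_r = √⟨‖x_r(t) − ⟨x_r⟩‖²⟩_t; window membership is the
minimal circular difference to each (ϕ,ψ) target center ≤ tolerance;
superposition is the least-squares rigid (Kabsch) fit, RMSD over the paired
atoms after fitting.

## Worked example

Build an ideal type II β-turn tetrapeptide and interrogate its geometry:

```
$ pfrkit synth turn -o turn.pdb
$ pfrkit turn turn.pdb --chain P --window 1
{
  "state": "type II β-turn",
  "ca_distance_i_i3": 4.869,
  "stabilizing_hbonds": [["SER-P4/OG", "LEU-P1/O", 2.696]],
  "polar_contacts": [["SER-P4/N", "LEU-P1/O", 2.820]],
  "st_loop": true
}
```

The Cα(i)–Cα(i+3) distance of 4.87 Å is well inside the 7 Å hairpin bound,
and the serine hydroxyl caps the turn by hydrogen-bonding the i-th carbonyl
at 2.70 Å — the ST-loop signature.

Plant a two-state dihedral switch with 28 % turn occupancy and recover it:

```
$ pfrkit synth switch --p-a 0.28 --frames 2000 --seed 11 -o sw.pdb --ledger sw.json
$ pfrkit occupancy sw.pdb --chain P --i1 2 --i2 3
{
  "fractions": {"type II β-turn": 0.2885, "glycine-extended": 0.7115, "other": 0.0},
  "joint": true,
  "n_frames": 2000
}
```

The measured occupancy (0.2885) equals the generator's Bernoulli draw
fraction exactly (ledger `fractions.A = 0.2885`) and sits within sampling
noise of the planted 0.28.

For full report bundles, `pfrkit crystal --config run.yaml` and
`pfrkit traj --config run.yaml` chain all stages and write TSV/JSON
artifacts plus a MANIFEST echoing every parameter.

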