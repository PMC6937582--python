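# Methods

## Scope and model

`pfrkit` analyses the geometry of class II pMHC complexes around the
peptide register: which residues sit in the groove (P1–P9), which overhang
(the PFRs), how the overhangs touch the receptor, and whether the
C-terminal flank folds into a reverse turn. The register itself is an
*input* — either user-declared or taken from an external binding predictor
— because inferring it reliably requires a pocket-specificity model that is
a separate problem; the package only validates that a declared core leaves
nine residues and numbers everything else relative to it (P-positions skip
zero: …, P(−2), P(−1), P1, …).

## Coordinate handling

Parsing is delegated to gemmi; the in-memory model keeps author numbering
(no renumbering), retains hydrogens, waters and heteroatoms, and defers all
selection to the individual analyses — the crystal model carries no
informative hydrogens while MD frames do, so the reader must not make that
choice. Elements are taken from the element column and inferred from the
atom name only when that column is blank (leading digit ⇒ hydrogen,
otherwise the leading letter). Alternate conformers are reduced by an
explicit policy: `highest_occupancy` (ties broken by altloc letter),
`first`, or `strict` (error listing affected residues). The policy is
idempotent and applied before any distance computation so contact counts
cannot double-count conformers.

B-factor profiles average the isotropic B of either all heavy atoms or the
backbone only; the choice is recorded on the profile because deposited
structures do not state which convention a flexibility figure used. The
category thresholds — stable below 40 Å², high-flex above 80 Å² — are the
conventions used when reading pMHC-II peptide density quality.

## Contacts

A contact is any peptide-atom/receptor-atom pair within the van der Waals
cutoff (default 4.0 Å, KD-tree enumeration, verified against an O(n·m)
double loop in the tests). Pairs within the hydrogen-bond cutoff (3.4 Å)
whose atoms satisfy donor/acceptor chemistry are labelled `hbond`, all
others `vdw`; a pair is never in both classes, so totals decompose as
vdW + H-bond. The chemistry is a distance-only table (backbone N donates,
backbone O/OXT accepts; standard side-chain donors/acceptors, with Ser/Thr/
Tyr hydroxyls and His ring nitrogens in both tables). No angle term is
applied by default since contact-table programs used for published pMHC
counts (e.g. NCONT) report distance-only criteria; the exact split between
the two classes is therefore sensitive to the typing table, while grand
totals depend only on the 4.0 Å cutoff. Receptor selection defaults to all
HLA chains because N-terminal PFRs can reach the α2 domain; waters are
always excluded, symmetry mates are never generated.

## Turn geometry

Backbone torsions use the standard IUPAC sign convention (cross-checked in
the tests against an independent implementation); terminal angles are
absent, not zero. Window classification compares (ϕ,ψ) of the two central
residues of a four-residue window to named targets with a ±40° tolerance,
measured as the minimal circular difference; targets written "±140°" are
treated as two centers and membership means being within tolerance of
either. Two windows are built in: the type II β-turn
((−60°, +120°) / (+80°, 0°)) and the glycine-extended state
((−60°, 120°) at i+1, (−60°, ±140°) at i+2) that a glycine at i+2 can
reach when the turn opens. The first matching spec wins; ω is reported but
never classified.

Hairpin evidence for a window i…i+3 combines the Cα(i)–Cα(i+3) distance
(hairpin bound 7 Å), the i-carbonyl → (i+3)-hydroxyl hydrogen bond
(≤ 3.4 Å), the i-carbonyl → (i+3)-amide polar interaction (≤ 3.6 Å) and
the window classification. The ST-loop flag requires a Ser/Thr at i+3
whose side-chain hydroxyl lies within hydrogen-bond distance of a backbone
N/O of residues i…i+2; the hydroxyl's own residue is excluded because an
intra-residue O–OG separation is covalent-neighbour geometry, not a bond.

Superposition is the weighted Kabsch fit (SVD with determinant correction;
verified against an independent implementation to 6 decimals). The default
pairing for loop comparisons is backbone N, CA, C, O of the paired
residues; because published loop RMSDs rarely state their atom set, the
pairing is a parameter and is echoed in every result.

## Trajectory statistics

Multi-model PDB is the native trajectory dialect; any reader producing
congruent frame coordinates can feed the same `TrajectoryEnsemble`.
Frames are fitted to frame 0 by a mass-weighted rigid fit of a caller
selection (conventionally the receptor Cα atoms); mass weighting applies
to the fit only — RMSF itself is the unweighted fluctuation of each Cα
about its time average. Contact fractions follow the MD convention: all
atoms including hydrogens, 3.0 Å cutoff, each residue reported as its share
of the total count over all frames (shares sum to 100 % whenever any
contact exists).

Dihedral-window occupancy classifies every frame with the same specs as the
static analysis. `joint=True` demands both central residues in-window
simultaneously (the criterion used for "hairpin maintained" statements);
`joint=False` classifies on the i+2 residue alone, which isolates the
glycine inversion that opens the turn. Both modes are exposed because
published occupancy figures do not always state which was used; states are
exclusive and exhaustive, so fractions sum to 1.

Clustering computes the exact pairwise RMSD matrix over a selection
(coordinate RMSD of pre-fitted frames) and applies hierarchical
agglomeration (average linkage by default; complete and single available),
stopping when the minimum inter-cluster distance exceeds ε = 2.5 Å — the
stopping rule of CPPTRAJ's hieragglo. Representatives are medoids. The
exact matrix is quadratic in frames, so beyond 5,000 frames the operation
requires an explicit stride rather than silently subsampling.

## Synthetic data

The generators define the conditions under which the statistics are
validated:

* **Backbone builder** — NeRF internal-coordinate chaining at standard
  geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å; angles 111.2° /
  116.2° / 121.7°; ω = 180°), placing N/CA/C/O plus a CB stub (improper
  +122.6°, L-chirality checked against CCD ideal residues) and the Ser/Thr
  hydroxyl at χ₁ = +65° — the gauche+ rotamer that caps a turn, chosen so
  an ideal built turn exhibits the ST-loop hydrogen bond (2.70 Å) near the
  2.8 Å seen in real ST loops. Build→measure round-trips hold to 0.5°.
* **Contact scenes** — planted pairs at exact distances 20 Å apart with
  decoys kept ≥ 4.5 Å out; pairs at ≤ 3.4 Å are planted with
  hydrogen-bond chemistry (Ser OG ↔ backbone O), longer ones as
  carbon–carbon. The ledger is the oracle.
* **Jitter trajectories** — i.i.d. Gaussian noise per coordinate with
  per-residue σ; the closed form RMSF = σ√3 validates the RMSF path, and a
  σ ramp (0.3 Å core → 2.0 Å termini) reproduces the parabolic profile
  shape expected of a groove-anchored peptide. 5,000 frames put sampling
  error well under the 2 % check tolerance.
* **Switch trajectories** — frames drawn i.i.d. between named dihedral
  states (e.g. turn vs glycine-extended) with declared probabilities
  (0.28 for the two-state hairpin fixture, 10,000 frames); because frames
  are rebuilt exactly at the state targets, downstream classification
  equals the draw ledger *exactly*, and the ledger concentrates within
  ±0.01 of the planted probability at that length.

What these fixtures do **not** emulate: force-field energetics, correlated
motion, solvent, or realistic side-chain packing. Passing the recovery
tests demonstrates the estimators are correct and unbiased under known
ground truth — not that any particular biological system behaves this way.

## Numerical choices and degenerate inputs

Angles are computed in degrees in (−180, 180], with −180 normalised to
+180. Zero-atom files parse to an empty model with a warning. A single
frame is a valid trajectory for clustering (one cluster) but not for RMSF
(error). Contact cutoffs must be positive; empty chain selections raise
rather than return empty tables. Cluster ordering is by population with
first-frame tie-break; altloc occupancy ties break alphabetically. All
random draws come from one `numpy.random.default_rng` per generator spec
with the seed recorded in the ledger, so every fixture is bit-reproducible.

## Known limitations

* The donor/acceptor table is distance-only; structures with unusual
  protonation or metal coordination will misclassify some pairs (the vdW +
  H-bond total is unaffected).
* Crystal-symmetry contacts are not generated; analyses are intra-ASU.
* The register must be supplied; there is no binding-motif scoring.
* The trajectory reader accepts multi-model PDB only; binary MD formats
  need an external conversion step.
* Checks pinned to deposited entries (6HBY, 4CNM) require those files to
  be present locally or fetchable.
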