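"""Trajectory statistics recover the generating parameters of synthetic data."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pfrkit import (
    BuilderSpec,
    JitterSpec,
    SwitchSpec,
    TrajectoryEnsemble,
    build_peptide,
    cluster_frames,
    contact_fraction,
    dihedral_occupancy,
    fit_frames,
    make_jitter_traj,
    make_multistate_traj,
    make_switch_traj,
    rmsf,
)
from pfrkit.structure_io import AtomRecord, StructureModel
from pfrkit.synthetic import FULLY_EXTENDED, IDEAL_TYPE_II

GLY_EXT = ((-60.0, 120.0), (-60.0, 140.0))


@pytest.fixture(scope="module")
def decapeptide():
    return build_peptide(BuilderSpec.uniform("ALSGSAALSA", -120.0, 130.0))


class TestFitFrames:
    def test_rigid_copies_collapse_onto_frame0(self, decapeptide):
        X = decapeptide.coords()
        rng = np.random.default_rng(0)
        frames = [X]
        for _ in range(5):
            R = Rotation.random(random_state=rng).as_matrix()
            frames.append(X @ R.T + rng.uniform(-20, 20, 3))
        traj = TrajectoryEnsemble(decapeptide, np.stack(frames))
        fitted = fit_frames(traj, range(len(decapeptide)))
        for t in range(6):
            assert np.abs(fitted.frames[t] - X).max() < 1e-6

    def test_single_frame_unchanged(self, decapeptide):
        traj = TrajectoryEnsemble(decapeptide, decapeptide.coords()[None])
        fitted = fit_frames(traj, range(5))
        np.testing.assert_array_equal(fitted.frames, traj.frames)

    def test_empty_selection_raises(self, decapeptide):
        traj = TrajectoryEnsemble(decapeptide, decapeptide.coords()[None])
        with pytest.raises(ValueError, match="empty"):
            fit_frames(traj, [])

    def test_fit_absorbs_little_noise(self, decapeptide):
        """Fitting jittered frames leaves per-atom deviations near the injected σ."""
        sigma = 0.5
        traj, _ = make_jitter_traj(JitterSpec(decapeptide, sigma, 200, seed=5))
        fitted = fit_frames(traj, range(len(decapeptide)))
        dev = np.sqrt(
            np.mean(np.sum((fitted.frames - decapeptide.coords()) ** 2, axis=2))
        )
        expected = sigma * np.sqrt(3)
        assert abs(dev - expected) / expected < 0.05


class TestRMSF:
    def test_constant_trajectory_zero(self, decapeptide):
        traj = TrajectoryEnsemble(decapeptide, np.repeat(decapeptide.coords()[None], 3, axis=0))
        assert rmsf(traj, "P").values() == pytest.approx(0.0, abs=1e-12)

    def test_single_frame_raises(self, decapeptide):
        traj = TrajectoryEnsemble(decapeptide, decapeptide.coords()[None])
        with pytest.raises(ValueError, match="insufficient frames"):
            rmsf(traj, "P")

    def test_isotropic_jitter_closed_form(self, decapeptide):
        """Per-coordinate σ=1 Å ⇒ RMSF √3 Å (3 d.o.f.), within 2 % per residue."""
        traj, _ = make_jitter_traj(JitterSpec(decapeptide, 1.0, 5000, seed=2024))
        values = rmsf(traj, "P").values()
        np.testing.assert_allclose(values, np.sqrt(3.0), rtol=0.02)

    def test_sigma_ramp_gives_parabolic_profile(self, decapeptide):
        n_res = len(decapeptide.residues("P"))
        center = (n_res + 1) / 2
        sigma = {
            i + 1: 0.3 + (2.0 - 0.3) * ((i + 1 - center) / (n_res - center)) ** 2
            for i in range(n_res)
        }
        traj, _ = make_jitter_traj(JitterSpec(decapeptide, sigma, 2000, seed=7))
        values = rmsf(traj, "P").values()
        assert values[0] > values[n_res // 2]
        assert values[-1] > values[n_res // 2]

    def test_invariant_under_global_rigid_transform_before_fit(self, decapeptide):
        traj, _ = make_jitter_traj(JitterSpec(decapeptide, 0.4, 300, seed=3))
        base = rmsf(fit_frames(traj, range(len(decapeptide))), "P").values()
        R = Rotation.random(random_state=np.random.default_rng(4)).as_matrix()
        moved = TrajectoryEnsemble(traj.topology, traj.frames @ R.T + 13.0)
        again = rmsf(fit_frames(moved, range(len(decapeptide))), "P").values()
        np.testing.assert_allclose(again, base, atol=1e-9)


def _two_chain_model(contact_pattern):
    """Peptide chain P with one CA per residue; receptor atom per residue at
    2.5 Å (in contact) or 50 Å (never) according to the pattern."""
    atoms = []
    serial = 0
    for i, close in enumerate(contact_pattern):
        serial += 1
        atoms.append(AtomRecord(
            serial=serial, name="CA", element="C", alt_loc="", res_name="ALA",
            chain_id="P", res_seq=i + 1, icode="", x=10.0 * i, y=0.0, z=0.0,
            occupancy=1.0, b_iso=20.0,
        ))
        serial += 1
        atoms.append(AtomRecord(
            serial=serial, name="CB", element="C", alt_loc="", res_name="ALA",
            chain_id="R", res_seq=i + 1, icode="",
            x=10.0 * i + (2.5 if close else 50.0), y=0.0, z=0.0,
            occupancy=1.0, b_iso=20.0,
        ))
    return StructureModel(atoms)


class TestContactFraction:
    def test_single_contacting_residue_is_100pct(self):
        model = _two_chain_model([True, False, False])
        traj = TrajectoryEnsemble(model, np.repeat(model.coords()[None], 4, axis=0))
        df = contact_fraction(traj, "P", ["R"])
        assert df["pct"].tolist() == pytest.approx([100.0, 0.0, 0.0])

    def test_two_equal_residues_split_evenly(self):
        model = _two_chain_model([True, True, False])
        traj = TrajectoryEnsemble(model, np.repeat(model.coords()[None], 3, axis=0))
        df = contact_fraction(traj, "P", ["R"])
        assert df["pct"].tolist() == pytest.approx([50.0, 50.0, 0.0])

    def test_percentages_sum_to_100_when_any_contact(self):
        model = _two_chain_model([True, False, True, True])
        traj = TrajectoryEnsemble(model, np.repeat(model.coords()[None], 5, axis=0))
        df = contact_fraction(traj, "P", ["R"])
        assert df["pct"].sum() == pytest.approx(100.0)

    def test_planted_per_frame_counts(self):
        """Percentages match a plant ledger where contacts vary frame by frame."""
        model = _two_chain_model([True, True])
        base = model.coords()
        far = base.copy()
        far[3, 0] += 100.0  # receptor partner of residue 2 leaves in frame 2
        traj = TrajectoryEnsemble(model, np.stack([base, base, far, far]))
        df = contact_fraction(traj, "P", ["R"])
        # residue 1: 4 contacts, residue 2: 2 contacts → 66.7 / 33.3
        assert df["contacts"].tolist() == [4, 2]
        assert df["pct"].tolist() == pytest.approx([400 / 6, 200 / 6])


class TestDihedralOccupancy:
    def test_all_ideal_frames_full_occupancy(self):
        traj, _ = make_switch_traj(SwitchSpec(
            base=BuilderSpec.turn("LSGS"), window=(2, 3),
            state_a=IDEAL_TYPE_II, state_b=GLY_EXT, p_a=1.0, n_frames=50, seed=0,
        ))
        occ = dihedral_occupancy(traj, "P", 2, 3)
        assert occ.fractions["type II β-turn"] == pytest.approx(1.0)

    def test_occupancy_equals_ledger_exactly(self):
        traj, ledger = make_switch_traj(SwitchSpec(
            base=BuilderSpec.turn("LSGS"), window=(2, 3),
            state_a=IDEAL_TYPE_II, state_b=GLY_EXT, p_a=0.28, n_frames=2000, seed=42,
        ))
        occ = dihedral_occupancy(traj, "P", 2, 3)
        assert occ.fractions["type II β-turn"] == ledger["fractions"]["A"]
        assert occ.fractions["glycine-extended"] == ledger["fractions"]["B"]

    def test_fractions_sum_to_one(self):
        traj, _ = make_multistate_traj(
            BuilderSpec.turn("LSGS"), (2, 3),
            states={"A": IDEAL_TYPE_II, "B": GLY_EXT, "C": FULLY_EXTENDED},
            probs={"A": 0.5, "B": 0.3, "C": 0.2}, n_frames=500, seed=1,
        )
        occ = dihedral_occupancy(traj, "P", 2, 3)
        assert sum(occ.fractions.values()) == pytest.approx(1.0)

    def test_marginal_mode_classifies_on_i2_only(self):
        # state B keeps i+1 turn-like but opens i+2: joint and marginal agree here
        traj, ledger = make_switch_traj(SwitchSpec(
            base=BuilderSpec.turn("LSGS"), window=(2, 3),
            state_a=IDEAL_TYPE_II, state_b=GLY_EXT, p_a=0.6, n_frames=300, seed=9,
        ))
        joint = dihedral_occupancy(traj, "P", 2, 3, joint=True)
        marg = dihedral_occupancy(traj, "P", 2, 3, joint=False)
        assert joint.fractions == marg.fractions

    def test_terminus_window_raises(self):
        traj, _ = make_switch_traj(SwitchSpec(
            base=BuilderSpec.turn("LSGS"), window=(2, 3),
            state_a=IDEAL_TYPE_II, state_b=GLY_EXT, p_a=1.0, n_frames=2, seed=0,
        ))
        with pytest.raises(ValueError, match="terminus"):
            dihedral_occupancy(traj, "P", 1, 2)


class TestClustering:
    def _conformer_traj(self, n_frames=60, seed=11):
        states = {
            "turn": IDEAL_TYPE_II,
            "open": GLY_EXT,
            "extended": FULLY_EXTENDED,
        }
        probs = {"turn": 0.5, "open": 0.3, "extended": 0.2}
        return make_multistate_traj(
            BuilderSpec.uniform("ALSGSAAL", -120.0, 130.0), (4, 5),
            states=states, probs=probs, n_frames=n_frames, seed=seed,
            jitter_sigma=0.05,
        )

    def test_identical_frames_one_cluster(self, decapeptide):
        traj = TrajectoryEnsemble(decapeptide, np.repeat(decapeptide.coords()[None], 8, axis=0))
        cl = cluster_frames(traj, range(len(decapeptide)))
        assert cl.n_clusters == 1

    def test_threshold_above_max_rmsd_one_cluster(self):
        traj, _ = self._conformer_traj()
        cl = cluster_frames(traj, range(len(traj.topology)), threshold=500.0)
        assert cl.n_clusters == 1

    def test_three_conformers_recovered(self):
        traj, ledger = self._conformer_traj()
        cl = cluster_frames(traj, range(len(traj.topology)), threshold=2.5)
        assert cl.n_clusters == 3
        # memberships agree with the generating states
        by_state = {}
        for t, s in enumerate(ledger["states"]):
            by_state.setdefault(s, set()).add(t)
        found = {frozenset(c["members"]) for c in cl.clusters}
        assert found == {frozenset(v) for v in by_state.values()}

    def test_representative_is_member(self):
        traj, _ = self._conformer_traj()
        cl = cluster_frames(traj, range(len(traj.topology)))
        for c in cl.clusters:
            assert c["representative"] in c["members"]

    def test_cluster_count_nonincreasing_in_threshold(self):
        traj, _ = self._conformer_traj(n_frames=40)
        sel = range(len(traj.topology))
        counts = [
            cluster_frames(traj, sel, threshold=t).n_clusters
            for t in (0.5, 1.0, 2.0, 2.5, 4.0, 8.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_frame_guard(self, decapeptide):
        traj = TrajectoryEnsemble(decapeptide, np.repeat(decapeptide.coords()[None], 12, axis=0))
        with pytest.raises(ValueError, match="stride"):
            cluster_frames(traj, range(5), max_frames=10)
        assert cluster_frames(traj.strided(2), range(5), max_frames=10).n_clusters == 1
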