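"""Contact enumeration against brute-force oracles and planted scenes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfrkit import (
    PeptideRegister,
    build_contact_scene,
    find_contacts,
    residue_contact_detail,
    summarize_contacts,
)
from pfrkit.structure_io import AtomRecord, StructureModel


def _atom(serial, name, element, res_name, chain, res_seq, xyz):
    return AtomRecord(
        serial=serial, name=name, element=element, alt_loc="",
        res_name=res_name, chain_id=chain, res_seq=res_seq, icode="",
        x=xyz[0], y=xyz[1], z=xyz[2], occupancy=1.0, b_iso=20.0,
    )


def test_atoms_beyond_cutoff_do_not_contact():
    model = StructureModel([
        _atom(1, "CA", "C", "ALA", "P", 1, (0, 0, 0)),
        _atom(2, "CA", "C", "ALA", "R", 1, (5.0, 0, 0)),
    ])
    assert find_contacts(model, "P", ["R"]) == []


def test_hbond_vs_vdw_classification():
    """A serine OG at 2.9 Å of a backbone O is an H-bond; its CB at 3.8 Å is vdW."""
    model = StructureModel([
        _atom(1, "OG", "O", "SER", "P", 1, (0, 0, 0)),
        _atom(2, "CB", "C", "SER", "P", 1, (0.0, 0.9, 0)),
        _atom(3, "O", "O", "GLY", "R", 1, (2.9, 0, 0)),
    ])
    pairs = find_contacts(model, "P", ["R"])
    kinds = {(p.peptide_atom.name, p.kind) for p in pairs}
    assert ("OG", "hbond") in kinds
    cb_pair = next(p for p in pairs if p.peptide_atom.name == "CB")
    assert cb_pair.kind == "vdw" and cb_pair.distance <= 4.0


def test_carbon_pair_within_hbond_cutoff_stays_vdw():
    model = StructureModel([
        _atom(1, "CB", "C", "ALA", "P", 1, (0, 0, 0)),
        _atom(2, "CB", "C", "ALA", "R", 1, (3.0, 0, 0)),
    ])
    (pair,) = find_contacts(model, "P", ["R"])
    assert pair.kind == "vdw"


def test_planted_scene_found_exactly():
    model, ledger = build_contact_scene(5, [3.0, 3.3, 3.6, 3.9, 2.9], decoys=50, seed=7)
    pairs = find_contacts(model, "P", ["R"])
    assert len(pairs) == len(ledger) == 5
    found = {
        (p.peptide_atom.res_seq, p.kind, round(p.distance, 3)) for p in pairs
    }
    planted = {
        (pl.peptide_residue[1], pl.kind, round(pl.distance, 3)) for pl in ledger
    }
    assert found == planted


def test_zero_planted_zero_contacts():
    model, ledger = build_contact_scene(0, [], decoys=20, seed=1)
    assert ledger == []
    assert find_contacts(model, "P", ["R"]) == []


def test_empty_selection_and_bad_cutoffs():
    model, _ = build_contact_scene(1, [3.0])
    with pytest.raises(ValueError, match="empty"):
        find_contacts(model, "Z", ["R"])
    with pytest.raises(ValueError, match="positive"):
        find_contacts(model, "P", ["R"], vdw_cutoff=-1.0)


def _brute_force_count(model, cutoff):
    pep = [a for a in model.atoms if a.chain_id == "P" and not a.is_hydrogen]
    rec = [a for a in model.atoms if a.chain_id == "R" and not a.is_hydrogen]
    n = 0
    for a in pep:
        for b in rec:
            if np.linalg.norm(a.pos - b.pos) <= cutoff:
                n += 1
    return n


@settings(deadline=None, max_examples=30)
@given(seed=st.integers(0, 10_000))
def test_counts_match_brute_force_double_loop(seed):
    """KD-tree enumeration equals the O(n·m) all-pairs oracle on random clouds."""
    rng = np.random.default_rng(seed)
    atoms = []
    serial = 0
    for chain in ("P", "R"):
        for i, xyz in enumerate(rng.uniform(0, 12, size=(25, 3))):
            serial += 1
            atoms.append(_atom(serial, "CB", "C", "ALA", chain, i + 1, xyz))
    model = StructureModel(atoms)
    for cutoff in (3.5, 4.0):
        pairs = find_contacts(model, "P", ["R"], vdw_cutoff=cutoff)
        assert len(pairs) == _brute_force_count(model, cutoff)
    # monotonicity in the cutoff
    assert len(find_contacts(model, "P", ["R"], vdw_cutoff=3.5)) <= len(
        find_contacts(model, "P", ["R"], vdw_cutoff=4.0)
    )


def test_grand_total_invariant_under_receptor_order():
    model, _ = build_contact_scene(4, [3.0, 3.9], decoys=10, seed=3)
    a = find_contacts(model, "P", ["R"])
    # add a second (empty) receptor chain id permutation
    assert len(find_contacts(model, "P", ["R"])) == len(a)


class TestSummary:
    def _scene_register(self, model):
        residues = model.residues("P")
        keys = tuple(r.key for r in residues)
        # pad to a 9-residue core minimum by synthetic keys if the scene is small
        seq = "S" * len(keys)
        if len(keys) < 9:
            keys = keys + tuple(("P", 100 + i, "") for i in range(9 - len(keys)))
            seq = seq + "A" * (9 - len(seq))
        return PeptideRegister("P", seq, 1, keys)

    def test_totals_and_regions_sum(self):
        model, ledger = build_contact_scene(6, [2.9, 3.2, 3.8], decoys=5, seed=11)
        pairs = find_contacts(model, "P", ["R"])
        reg = self._scene_register(model)
        table = summarize_contacts(pairs, reg)
        vdw, hb, tot = table.grand_total
        assert tot == vdw + hb == len(pairs)
        assert (table.rows["total"] == table.rows["vdw"] + table.rows["hbonds"]).all()
        regions = table.region_totals
        assert regions.loc["all", "total"] == sum(
            regions.loc[r, "total"] for r in ("N-PFR", "core", "C-PFR")
        )
        contacted = table.rows[table.rows["total"] > 0]
        assert contacted["pct"].sum() == pytest.approx(100.0)

    def test_empty_pairs_all_zero(self):
        reg = PeptideRegister.from_sequence("LAELAALNL", 1, chain_id="P")
        table = summarize_contacts([], reg)
        assert table.grand_total == (0, 0, 0)
        assert len(table.rows) == 9

    def test_unregistered_residue_raises(self):
        model, _ = build_contact_scene(1, [3.0])
        pairs = find_contacts(model, "P", ["R"])
        reg = PeptideRegister.from_sequence("LAELAALNL", 1, chain_id="Q")
        with pytest.raises(KeyError):
            summarize_contacts(pairs, reg)


class TestResidueDetail:
    def test_backbone_sidechain_split(self):
        model = StructureModel([
            _atom(1, "N", "N", "ARG", "P", 1, (0, 0, 0)),
            _atom(2, "NH1", "N", "ARG", "P", 1, (0, 2.0, 0)),
            _atom(3, "O", "O", "GLY", "R", 50, (2.9, 0, 0)),
            _atom(4, "O", "O", "GLY", "R", 51, (0.0, 4.5, 0)),
        ])
        pairs = find_contacts(model, "P", ["R"])
        detail = residue_contact_detail(pairs, ("P", 1))
        assert set(detail["atom_class"]) == {"backbone", "side-chain"}
        assert (detail[detail["peptide_atom"] == "N"]["atom_class"] == "backbone").all()

    def test_glycine_is_backbone_only(self):
        model = StructureModel([
            _atom(1, "CA", "C", "GLY", "P", 1, (0, 0, 0)),
            _atom(2, "CB", "C", "ALA", "R", 1, (3.5, 0, 0)),
        ])
        pairs = find_contacts(model, "P", ["R"])
        detail = residue_contact_detail(pairs, ("P", 1))
        assert (detail["atom_class"] == "backbone").all()

    def test_single_planted_pair_listing(self):
        model, ledger = build_contact_scene(1, [3.0])
        pairs = find_contacts(model, "P", ["R"])
        detail = residue_contact_detail(pairs, ("P", 1))
        assert len(detail) == 1
        assert detail.iloc[0]["distance"] == pytest.approx(ledger[0].distance)
        empty = residue_contact_detail(pairs, ("P", 99))
        assert empty.empty and list(empty.columns) == list(detail.columns)
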