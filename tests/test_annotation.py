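"""Annotation workflow: ligand detection, occupancy, pocket assignment,
projection, gap closing, capping groups, filters, homology transfer."""

import numpy as np
import pytest

from subsites.annotation import (
    CatalyticAnnotation,
    PeptideLigand,
    PocketAssignment,
    assign_pockets_from_reference,
    catalytic_site_occupancy,
    close_annotation_gaps,
    detect_peptide_ligands,
    filter_assignment,
    infer_catalytic_by_homology,
    project_annotation,
    strip_capping_groups,
)
from subsites.errors import AnnotationError, NotAnnotatable
from subsites.fixtures import FixtureSpec, make_toy_complex
from subsites.geometry import rotation_about_axis
from subsites.observables import shrake_rupley_asa
from subsites.structure import Atom, Chain, Residue, Structure


def _res(name, seq, atoms, chain=None):
    return Residue(name, seq, "", [Atom(n, e, c) for n, e, c in atoms])


def _asa(structure):
    return shrake_rupley_asa(structure, n_sphere_points=240)


class TestDetectLigands:
    def test_toy_peptide_found(self, toy):
        structure, _, _ = toy
        ligands = detect_peptide_ligands(structure)
        assert len(ligands) == 1
        assert ligands[0].chain_id == "P"
        assert ligands[0].length == 8

    def test_short_chain_excluded(self):
        structure, _, _ = make_toy_complex(FixtureSpec(peptide_length=2))
        assert detect_peptide_ligands(structure) == []

    def test_all_unk_chain_excluded(self):
        residues = [
            _res("UNK", i, [("CA", "C", np.array([3.8 * i, 0.0, 0.0]))])
            for i in range(1, 13)
        ]
        structure = Structure([Chain("X", residues)])
        assert detect_peptide_ligands(structure, peptide_like_names={"ALA", "UNK"}) == []


class TestOccupancy:
    def test_bound_peptide_occupies_site(self, toy):
        structure, catalytic, _ = toy
        ligand = detect_peptide_ligands(structure)[0]
        assert catalytic_site_occupancy(structure, catalytic, ligand, _asa)

    def test_distant_peptide_does_not(self, toy):
        structure, catalytic, _ = toy
        moved = structure.copy()
        for res in moved.chain("P").residues:
            for a in res.atoms:
                a.coords = a.coords + np.array([50.0, 0.0, 0.0])
        ligand = detect_peptide_ligands(moved)[0]
        assert not catalytic_site_occupancy(moved, catalytic, ligand, _asa)

    def test_empty_annotation_rejected(self, toy):
        structure, _, _ = toy
        ligand = detect_peptide_ligands(structure)[0]
        with pytest.raises(AnnotationError):
            catalytic_site_occupancy(structure, CatalyticAnnotation([]), ligand, _asa)

    def test_monotone_in_separation(self, toy):
        """Moving the ligand away never turns occupancy false -> true."""
        structure, catalytic, _ = toy
        flags = []
        for shift in (0.0, 10.0, 25.0, 50.0):
            moved = structure.copy()
            for res in moved.chain("P").residues:
                for a in res.atoms:
                    a.coords = a.coords + np.array([0.0, 0.0, shift])
            ligand = detect_peptide_ligands(moved)[0]
            flags.append(
                catalytic_site_occupancy(moved, catalytic, ligand, _asa)
            )
        assert flags[0] is True
        # once contact is lost it never comes back
        for a, b in zip(flags, flags[1:]):
            assert a or not b


class TestAssignPockets:
    def _mini_complex(self, protease_dist):
        pep = _res("ALA", 1, [("CA", "C", np.zeros(3))])
        prot = _res("GLY", 10, [("CA", "C", np.array([protease_dist, 0.0, 0.0]))])
        return Structure([Chain("P", [pep]), Chain("E", [prot])])

    def test_atom_inside_cutoff_joins_pocket(self):
        s = self._mini_complex(4.4)
        asg = assign_pockets_from_reference(s, [(("P", 1, ""), "S1")])
        assert ("E", 10, "") in asg.pocket_residues["S1"]

    def test_atom_beyond_cutoff_excluded(self):
        s = self._mini_complex(4.6)
        asg = assign_pockets_from_reference(s, [(("P", 1, ""), "S1")])
        assert "S1" not in asg.pocket_residues

    def test_residue_can_join_several_pockets(self):
        pep1 = _res("ALA", 1, [("CA", "C", np.array([0.0, 0.0, 0.0]))])
        pep2 = _res("ALA", 2, [("CA", "C", np.array([3.8, 0.0, 0.0]))])
        prot = _res("GLY", 10, [("CA", "C", np.array([1.9, 3.0, 0.0]))])
        s = Structure([Chain("P", [pep1, pep2]), Chain("E", [prot])])
        asg = assign_pockets_from_reference(
            s, [(("P", 1, ""), "S2"), (("P", 2, ""), "S1")]
        )
        assert ("E", 10, "") in asg.pocket_residues["S2"]
        assert ("E", 10, "") in asg.pocket_residues["S1"]

    def test_missing_reference_residue_rejected(self, toy):
        structure, _, _ = toy
        with pytest.raises(AnnotationError):
            assign_pockets_from_reference(structure, [(("P", 99, ""), "S1")])

    def test_invariant_under_rigid_transform(self, toy, rng):
        structure, _, gt = toy
        positions = [(k, lab) for k, lab in gt.peptide_map]
        base = assign_pockets_from_reference(structure, positions)
        R = rotation_about_axis(rng.random(3) - 0.5, 77.0)
        t = np.array([5.0, -30.0, 12.0])
        moved = structure.transform(R, t)
        asg = assign_pockets_from_reference(moved, positions)
        assert asg.pocket_residues == base.pocket_residues
        assert asg.peptide_map == base.peptide_map


class TestProjection:
    def test_identity_projection(self, toy):
        structure, _, gt = toy
        projected = project_annotation(structure, gt, structure)
        assert [lab for _, lab in projected.peptide_map] == [
            lab for _, lab in gt.peptide_map
        ]

    def test_one_position_shift(self, toy):
        structure, _, gt = toy
        target = structure.copy()
        chain = target.chain("P")
        step = (
            chain.residues[1].atom("CA").coords - chain.residues[0].atom("CA").coords
        )
        for res in chain.residues:
            for a in res.atoms:
                a.coords = a.coords + step
        projected = project_annotation(structure, gt, target)
        labels = [lab for _, lab in projected.peptide_map]
        # residue i now occupies the site of reference residue i+1
        assert labels[0] == "S3"
        assert labels[3] == "S1'"
        assert labels[6] == "S4'"

    def test_tie_goes_to_n_terminal_reference(self):
        # two reference residues share identical coordinates: any target
        # residue counts the same atoms for both, so the tie-break decides
        ca = [("CA", "C", np.array([0.0, 0.0, 0.0]))]
        ref_pep = [_res("ALA", 1, ca), _res("ALA", 2, ca)]
        prot = [
            _res("ALA", 10, [("CA", "C", np.array([0.0, 6.0, 0.0]))]),
            _res("ALA", 11, [("CA", "C", np.array([4.0, 6.0, 0.0]))]),
            _res("ALA", 12, [("CA", "C", np.array([0.0, 6.0, 4.0]))]),
        ]
        ref = Structure([Chain("P", ref_pep), Chain("E", [r.copy() for r in prot])])
        tgt_pep = [_res("ALA", 1, ca)]
        target = Structure([Chain("P", tgt_pep), Chain("E", [r.copy() for r in prot])])
        gt = PocketAssignment(
            "P", [(("P", 1, ""), "S2"), (("P", 2, ""), "S1")], {}
        )
        projected = project_annotation(ref, gt, target, target_peptide_chain="P")
        assert projected.peptide_map[0][1] == "S2"


class TestGapClosing:
    def _assignment(self, labels):
        pm = [(("P", i + 1, ""), lab) for i, lab in enumerate(labels)]
        return PocketAssignment("P", pm, {})

    def test_shorter_run_moves_to_longer(self):
        out = close_annotation_gaps(self._assignment(["S4", "S2", "S1"]))
        assert [lab for _, lab in out.peptide_map] == ["S3", "S2", "S1"]

    def test_gap_free_unchanged(self, toy):
        _, _, gt = toy
        out = close_annotation_gaps(gt)
        assert out.peptide_map == gt.peptide_map

    def test_equal_runs_keep_n_terminal(self):
        out = close_annotation_gaps(self._assignment(["S4", "S1"]))
        assert [lab for _, lab in out.peptide_map] == ["S4", "S3"]

    def test_labels_consecutive_after_closing(self):
        from subsites.constants import POCKET_ORDER

        out = close_annotation_gaps(self._assignment(["S4", "S2", "S1", "S1'"]))
        labels = [lab for _, lab in out.peptide_map if lab]
        idx = [POCKET_ORDER.index(lab) for lab in labels]
        assert idx == list(range(idx[0], idx[0] + len(idx)))


class TestCapsAndFilter:
    def _ligand(self, names):
        residues = [
            _res(n, i + 1, [("CA", "C", np.array([3.8 * i, 0.0, 0.0]))])
            for i, n in enumerate(names)
        ]
        return PeptideLigand("P", residues)

    def test_ace_cap_removed(self):
        lig = strip_capping_groups(self._ligand(["ACE", "ALA", "GLY", "VAL", "LEU", "SER"]))
        assert lig.length == 5
        assert all(r.res_name != "ACE" for r in lig.residues)

    def test_uncapped_unchanged(self):
        lig = self._ligand(["ALA", "GLY", "VAL"])
        assert strip_capping_groups(lig).length == 3

    def test_stripping_is_idempotent(self):
        lig = self._ligand(["ACE", "ALA", "GLY", "VAL"])
        once = strip_capping_groups(lig)
        twice = strip_capping_groups(once)
        assert [r.res_name for r in once.residues] == [
            r.res_name for r in twice.residues
        ]

    @pytest.mark.parametrize(
        "n_assigned,keep", [(2, False), (3, True), (8, True)]
    )
    def test_minimum_pocket_residues(self, n_assigned, keep):
        from subsites.constants import POCKET_ORDER

        labels = list(POCKET_ORDER[:n_assigned]) + [None] * (8 - n_assigned)
        pm = [(("P", i + 1, ""), lab) for i, lab in enumerate(labels)]
        decision = filter_assignment(PocketAssignment("P", pm, {}))
        assert decision.keep is keep
        assert decision.reason


class TestHomologyTransfer:
    LIB_SEQ = "ACDEFGHIKLMNPQRSTVWY"

    def test_identical_sequence_transfers_verbatim(self):
        lib = [(self.LIB_SEQ, CatalyticAnnotation([("A", 3, "nucleophile")]))]
        out = infer_catalytic_by_homology(self.LIB_SEQ, lib, query_chain_id="Q")
        assert out.entries == [("Q", 3, "nucleophile")]

    def test_low_identity_not_annotatable(self):
        lib = [(self.LIB_SEQ, CatalyticAnnotation([("A", 3, "nucleophile")]))]
        with pytest.raises(NotAnnotatable):
            infer_catalytic_by_homology("WWWWWWWWWW", lib)

    def test_position_in_query_gap_dropped(self):
        # query lacks the MNP segment: catalytic position 12 (N) has no
        # query counterpart and is dropped; position 3 (D) transfers
        query = "ACDEFGHIKLQRSTVWY"
        lib = [
            (
                self.LIB_SEQ,
                CatalyticAnnotation([("A", 3, "acid"), ("A", 12, "base")]),
            )
        ]
        with pytest.warns(UserWarning, match="gap"):
            out = infer_catalytic_by_homology(query, lib, query_chain_id="Q")
        assert out.entries == [("Q", 3, "acid")]

    def test_first_passing_entry_wins(self):
        lib = [
            ("WWWWWWWWWW", CatalyticAnnotation([("A", 1, "wrong")])),
            (self.LIB_SEQ, CatalyticAnnotation([("A", 5, "first")])),
            (self.LIB_SEQ, CatalyticAnnotation([("A", 6, "second")])),
        ]
        out = infer_catalytic_by_homology(self.LIB_SEQ, lib)
        assert [e[2] for e in out.entries] == ["first"]
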