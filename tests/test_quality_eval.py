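import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from slimscan.formats_io import InputError
from slimscan.quality_eval import (
    CapriClass,
    ReferenceComplex,
    choose_reference,
    classify_capri,
    dockq_score,
    evaluate_model,
    native_contacts,
    superpose,
)
from slimscan.synthetic_fixtures import (
    FixtureSpec,
    make_toy_complex,
    transform_ligand,
    _rotation_matrix,
)


class TestSuperpose:
    def test_identity(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        R, t, rmsd = superpose(pts, pts)
        assert rmsd < 1e-9
        assert np.allclose(R, np.eye(3), atol=1e-9)

    def test_recovers_constructed_transform(self):
        rng = np.random.default_rng(1)
        target = rng.normal(size=(20, 3)) * 5
        Rz = _rotation_matrix(np.array([0.0, 0.0, 1.0]), 90.0)
        mobile = (Rz @ target.T).T + np.array([1.0, 2.0, 3.0])
        R, t, rmsd = superpose(mobile, target)
        assert rmsd < 1e-6
        assert np.allclose(R @ Rz, np.eye(3), atol=1e-6)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_noise_floor_scales_with_sigma(self):
        rng = np.random.default_rng(2)
        target = rng.normal(size=(50, 3)) * 10
        mobile = target + rng.normal(scale=0.1, size=target.shape)
        _, _, rmsd = superpose(mobile, target)
        assert 0.05 < rmsd < 0.2

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_sets_flagged(self):
        line = np.outer(np.arange(5.0), np.array([1.0, 0.0, 0.0]))
        with pytest.raises(ValueError, match="degenerate"):
            superpose(line, line)


class TestNativeContacts:
    def test_matches_brute_force_double_loop(self, toy_reference):
        fast = native_contacts(toy_reference)
        st_ = toy_reference.structure
        slow = set()
        for rres in st_.chains["A"]:
            for lres in st_.chains["B"]:
                for a in rres.atoms.values():
                    for b in lres.atoms.values():
                        if np.linalg.norm(a - b) <= 5.0:
                            slow.add((rres.number, lres.number))
        assert fast == slow
        assert len(fast) >= 5

    @pytest.mark.parametrize("d, included", [(4.9, True), (5.1, False)])
    def test_cutoff_boundary(self, d, included):
        from slimscan.formats_io import ResidueRecord, StructureRecord

        def res(num, x):
            # a single side-chain pseudo-atom is enough for contact counting
            return ResidueRecord(num, "ALA", {"CB": np.array([x, 0.0, 0.0])})

        st_ = StructureRecord(
            chains={
                "A": [res(1, 0.0), res(2, 30.0)],
                "B": [res(1, -d)],
            },
            roles={"A": "receptor", "B": "ligand"},
        )
        pairs = native_contacts(ReferenceComplex(structure=st_))
        assert ((1, 1) in pairs) == included

    def test_far_ligand_has_empty_contact_set(self, toy_reference):
        far = transform_ligand(toy_reference.structure, translation=50.0)
        assert native_contacts(ReferenceComplex(structure=far)) == set()


class TestClassifyCapri:
    @pytest.mark.parametrize(
        "fnat, lrmsd, irmsd, expected",
        [
            # the three printed clause examples
            (0.85, 0.9, 0.6, CapriClass.High),
            (0.9, 1.5, 0.7, CapriClass.Medium),
            (0.6, 2.5, 1.2, CapriClass.Acceptable),
            (0.1, 10.0, 8.0, CapriClass.Incorrect),
            # boundary behaviour: shared endpoints go to the higher class
            (0.8, 1.0, 2.0, CapriClass.High),
            (0.8, 1.5, 0.5, CapriClass.High),
            (0.5, 2.0, 3.0, CapriClass.Medium),
            (0.5, 3.0, 1.0, CapriClass.Medium),
            (0.2, 4.0, 5.0, CapriClass.Acceptable),
            (0.19, 0.1, 0.1, CapriClass.Incorrect),
            (0.5, 2.1, 1.1, CapriClass.Acceptable),
            (1.0, 0.0, 0.0, CapriClass.High),
        ],
    )
    def test_truth_table(self, fnat, lrmsd, irmsd, expected):
        assert classify_capri(fnat, lrmsd, irmsd) is expected

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(
        fnat=st.floats(0, 1),
        lrmsd=st.floats(0, 20),
        irmsd=st.floats(0, 10),
    )
    def test_monotone_dominance(self, fnat, lrmsd, irmsd):
        """Improving any one metric never lowers the class."""
        base = classify_capri(fnat, lrmsd, irmsd)
        assert base <= CapriClass.High
        assert classify_capri(min(1.0, fnat + 0.05), lrmsd, irmsd) >= base
        assert classify_capri(fnat, max(0.0, lrmsd - 0.5), irmsd) >= base
        assert classify_capri(fnat, lrmsd, max(0.0, irmsd - 0.25)) >= base


class TestEvaluateModel:
    def test_identical_model_is_perfect(self, toy_reference):
        m = evaluate_model(toy_reference.structure, toy_reference)
        assert m.fnat == 1.0
        assert m.irmsd == pytest.approx(0.0, abs=1e-9)
        assert m.lrmsd == pytest.approx(0.0, abs=1e-9)
        assert m.dockq == pytest.approx(1.0, abs=1e-12)
        assert m.capri_class is CapriClass.High
        assert m.frir == 1.0 and m.frnnat == 0.0

    def test_far_translation_is_incorrect(self, toy_reference):
        far = transform_ligand(toy_reference.structure, translation=50.0)
        m = evaluate_model(far, toy_reference)
        assert m.fnat == 0.0
        assert m.capri_class is CapriClass.Incorrect

    def test_dockq_closed_form_midpoint(self):
        assert dockq_score(0.5, 1.5, 8.5) == pytest.approx(0.5)
        assert dockq_score(0.0, 0.0, 0.0) == pytest.approx(2 / 3)

    def test_metrics_invariant_under_global_rigid_motion(self, toy_reference):
        import copy

        moved = copy.deepcopy(toy_reference.structure)
        R = _rotation_matrix(np.array([1.0, 2.0, 0.5]), 37.0)
        t = np.array([5.0, -3.0, 12.0])
        for chain in moved.chains.values():
            for res in chain:
                for k in res.atoms:
                    res.atoms[k] = R @ res.atoms[k] + t
        m = evaluate_model(moved, toy_reference)
        assert m.fnat == 1.0
        assert m.lrmsd == pytest.approx(0.0, abs=1e-6)
        assert m.dockq == pytest.approx(1.0, abs=1e-6)

    def test_dockq_bounded_and_degrades(self, toy_reference):
        prev = 1.1
        for t in (0.0, 2.0, 6.0, 20.0):
            m = evaluate_model(
                transform_ligand(toy_reference.structure, translation=t),
                toy_reference,
            )
            assert 0.0 <= m.dockq <= 1.0
            assert m.dockq < prev
            prev = m.dockq


class TestChooseReference:
    def test_single_candidate(self, toy_reference):
        ref, metrics = choose_reference(toy_reference.structure, [toy_reference])
        assert ref is toy_reference
        assert metrics.dockq == pytest.approx(1.0, abs=1e-12)

    def test_symmetry_alternate_with_best_dockq_wins(self, toy_reference):
        # alternate B: the same complex with the ligand slid along the groove
        alt_structure = transform_ligand(toy_reference.structure, translation=3.8)
        alt = ReferenceComplex(structure=alt_structure)
        model = transform_ligand(toy_reference.structure, translation=3.8)
        ref, metrics = choose_reference(model, [toy_reference, alt])
        assert ref is alt
        assert metrics.dockq == pytest.approx(1.0, abs=1e-9)

    def test_exact_beats_poor_homolog(self, toy_reference):
        poor = ReferenceComplex(
            structure=transform_ligand(toy_reference.structure, translation=25.0)
        )
        ref, _ = choose_reference(toy_reference.structure, [poor, toy_reference])
        assert ref is toy_reference

    def test_no_candidates_rejected(self, toy_reference):
        with pytest.raises(ValueError):
            choose_reference(toy_reference.structure, [])
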