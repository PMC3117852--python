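import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from anchorloop import (HarmonicConstraint, ScoreWeights, apply_torsions,
                        build_standard_fold_tree, chainbreak_term, LoopSpec,
                        make_displacement_constraints, make_ideal_chain,
                        measure_torsion, minimize_torsions, score_structure)
from anchorloop.errors import ScoringError, ValidationError
from anchorloop.geometry import (BOND_C_N, IDEAL_C_CA_NEXT, IDEAL_CA_N_NEXT)
from anchorloop.structure import Atom, Residue, Structure


def _far_apart_glycines(d=100.0):
    """Two complete one-residue chains separated by ``d`` Angstrom."""
    res_a = make_ideal_chain("A", ["GLY"], [(-120.0, 130.0, 180.0)])[0]
    res_b = make_ideal_chain("B", ["GLY"], [(-120.0, 130.0, 180.0)])[0]
    for a in res_b.atoms:
        a.position = a.position + np.array([d, 0.0, 0.0])
    s = Structure()
    s.add_residue(res_a)
    s.add_residue(res_b)
    return s


class TestScoreStructure:
    def test_atoms_beyond_cutoff_score_zero_sterics(self, fullatom_weights,
                                                    centroid_weights):
        s = _far_apart_glycines(100.0)
        for weights, repr_ in ((fullatom_weights, "fullatom"),
                               (centroid_weights, "centroid")):
            rep = score_structure(s, weights, repr_)
            assert rep.term_totals["steric_rep"] == 0.0
            assert rep.term_totals["steric_atr"] == 0.0

    def test_ideal_chain_has_zero_chainbreak(self, toy, toy_tree,
                                             fullatom_weights):
        s, _ = toy
        rep = score_structure(s, fullatom_weights, "fullatom",
                              cutpoints=toy_tree.cutpoints)
        assert rep.term_totals["chainbreak"] < 1e-12

    def test_total_equals_per_residue_recomputation(self, toy, toy_tree,
                                                    fullatom_weights):
        """Summation oracle: the weighted per-residue breakdown rebuilds
        the total."""
        s, _ = toy
        rep = score_structure(s, fullatom_weights, "fullatom",
                              cutpoints=toy_tree.cutpoints)
        total = sum(fullatom_weights.get(t) * v
                    for terms in rep.per_residue.values()
                    for t, v in terms.items())
        assert abs(total - rep.total_score) < 1e-9
        assert abs(rep.recompute_total() - rep.total_score) < 1e-9

    def test_rigid_motion_invariance(self, toy, toy_tree, fullatom_weights):
        from scipy.spatial.transform import Rotation
        s, _ = toy
        ref = score_structure(s, fullatom_weights, "fullatom",
                              cutpoints=toy_tree.cutpoints)
        moved = s.copy()
        R = Rotation.from_euler("xyz", [11, 23, -37], degrees=True).as_matrix()
        for _, a in moved.atoms():
            a.position = R @ a.position + np.array([4.0, -2.0, 9.0])
        got = score_structure(moved, fullatom_weights, "fullatom",
                              cutpoints=toy_tree.cutpoints)
        assert abs(got.total_score - ref.total_score) < 1e-6

    def test_missing_interaction_center_errors(self, centroid_weights):
        res = Residue("A", 1, "", "LEU",
                      [Atom("N", "N", [0, 0, 0]),
                       Atom("CA", "C", [1.46, 0, 0]),
                       Atom("C", "C", [2.0, 1.4, 0])])
        s = Structure()
        s.add_residue(res)
        with pytest.raises(ScoringError):
            score_structure(s, centroid_weights, "centroid")

    def test_unknown_weight_term_rejected(self):
        with pytest.raises(ValidationError):
            ScoreWeights("bad", {"no_such_term": 1.0})

    def test_dunbrack_alias_maps_to_rotamer_pref(self, tmp_path):
        path = tmp_path / "w.txt"
        path.write_text("dunbrack 0.7\nchainbreak 2.0\n")
        w = ScoreWeights.from_file(path)
        assert w.get("rotamer_pref") == 0.7


class TestChainbreakTerm:
    def test_ideal_geometry_zero(self, toy, toy_tree):
        s, _ = toy
        assert chainbreak_term(s, toy_tree.cutpoints[0]) < 1e-12

    def test_stretched_bond_matches_formula_oracle(self, toy, toy_tree):
        """Pull the downstream residue 1 A along the C->N bond direction
        and check the hand-computed three-distance formula."""
        s, _ = toy
        c_key, d_key = toy_tree.cutpoints[0]
        work = s.copy()
        rc, rd = work.residue(c_key), work.residue(d_key)
        u = rd.atom("N").position - rc.atom("C").position
        u = u / np.linalg.norm(u)
        for a in rd.atoms:
            a.position = a.position + u
        # independent recomputation from raw coordinates
        Cc, CAc = rc.atom("C").position, rc.atom("CA").position
        Nd, CAd = rd.atom("N").position, rd.atom("CA").position
        expected = ((np.linalg.norm(Cc - Nd) - BOND_C_N) ** 2
                    + (np.linalg.norm(CAc - Nd) - IDEAL_CA_N_NEXT) ** 2
                    + (np.linalg.norm(Cc - CAd) - IDEAL_C_CA_NEXT) ** 2)
        got = chainbreak_term(work, (c_key, d_key))
        assert abs(got - expected) < 1e-12
        assert got > 0.9  # the stretched C-N alone contributes ~1

    def test_weight_two_applied_in_totals(self, toy, toy_tree,
                                          fullatom_weights):
        s, _ = toy
        c_key, d_key = toy_tree.cutpoints[0]
        work = s.copy()
        for a in work.residue(d_key).atoms:
            a.position = a.position + np.array([0.3, 0.0, 0.0])
        term = chainbreak_term(work, (c_key, d_key))
        with_cut = score_structure(work, fullatom_weights, "fullatom",
                                   cutpoints=[(c_key, d_key)])
        assert fullatom_weights.get("chainbreak") == 2.0
        assert abs(with_cut.term_totals["chainbreak"] - term) < 1e-12
        contribution = fullatom_weights.get("chainbreak") * term
        assert contribution == pytest.approx(2.0 * term)


class TestHarmonicConstraints:
    def test_displacement_constraints_default_four(self, toy):
        s, spec = toy
        anchor = (spec.anchor.chain_id, *spec.anchor.start)
        csts = make_displacement_constraints(s, anchor)
        assert len(csts) == 4
        for c in csts:
            assert c.weight == 0.5
            assert c.value(s) < 1e-12

    def test_penalty_half_unit_at_one_angstrom(self, toy):
        s, spec = toy
        anchor = (spec.anchor.chain_id, *spec.anchor.start)
        cst = make_displacement_constraints(s, anchor)[0]
        stretched = HarmonicConstraint(cst.atom_a, cst.atom_b,
                                       cst.d0 - 1.0, cst.weight)
        assert stretched.value(s) == pytest.approx(0.5, abs=1e-9)

    @settings(deadline=None, max_examples=30)
    @given(x=st.floats(-3.0, 3.0))
    def test_quadratic_calibration(self, toy, x):
        s, spec = toy
        anchor = (spec.anchor.chain_id, *spec.anchor.start)
        cst = make_displacement_constraints(s, anchor)[0]
        shifted = HarmonicConstraint(cst.atom_a, cst.atom_b, cst.d0 + x,
                                     cst.weight)
        assert shifted.value(s) == pytest.approx(0.5 * x * x, abs=1e-9)

    def test_too_few_partners_rejected(self):
        s = _far_apart_glycines(5.0)
        with pytest.raises(ValidationError):
            make_displacement_constraints(s, ("A", 1, ""), k_partners=4)


class TestMinimizeTorsions:
    def _one_torsion_problem(self, target_psi):
        """A single mobile psi with a pure-constraint quadratic basin whose
        minimum lies at a known torsion value."""
        residues = make_ideal_chain("B", ["ALA"] * 6,
                                    [(-120.0, 130.0, 180.0)] * 6)
        s = Structure()
        for r in residues:
            s.add_residue(r)
        tree = build_standard_fold_tree(
            s, [LoopSpec.of("B", 2, 5, None, None, 4)])
        key = ("B", 3, "")
        at_min = apply_torsions(s, tree, {(key, "psi"): target_psi})
        probe = ("B", 4, "")
        d0 = float(np.linalg.norm(
            at_min.residue(probe).atom("CA").position
            - s.residue(("B", 1, "")).atom("N").position))
        cst = HarmonicConstraint((probe, "CA"), (("B", 1, ""), "N"), d0, 0.5)
        weights = ScoreWeights("constraint_only", {"constraint": 1.0})
        return s, tree, key, cst, weights

    def test_converges_to_quadratic_minimum(self):
        target = -47.0
        s, tree, key, cst, weights = self._one_torsion_problem(target)
        start = apply_torsions(s, tree, {(key, "psi"): target + 20.0})
        out = minimize_torsions(start, tree, [(key, "psi")], weights,
                                constraints=[cst], cutpoints=[],
                                max_iter=200, gradient_step=1e-5,
                                tolerance=1e-10)
        got = measure_torsion(out, tree, key, "psi")
        # the basin is quadratic in the probe distance; 1e-3 degrees
        assert abs(got - target) < 1e-3

    def test_stationary_point_unchanged(self):
        target = -47.0
        s, tree, key, cst, weights = self._one_torsion_problem(target)
        at_min = apply_torsions(s, tree, {(key, "psi"): target})
        out = minimize_torsions(at_min, tree, [(key, "psi")], weights,
                                constraints=[cst], cutpoints=[],
                                max_iter=50, gradient_step=1e-5)
        assert np.max(np.abs(at_min.coords() - out.coords())) < 1e-6

    def test_descent_contract_on_perturbed_loop(self, toy, toy_tree,
                                                fullatom_weights):
        from anchorloop import perturb_loop
        s, _ = toy
        perturbed = perturb_loop(s, toy_tree, mode="small_move",
                                 magnitude=20.0,
                                 rng=np.random.default_rng(2))
        movable = [(k, n) for k in toy_tree.loops[0].mobile_keys
                   for n in ("phi", "psi")]
        before = score_structure(perturbed, fullatom_weights, "fullatom",
                                 toy_tree.cutpoints).total_score
        out = minimize_torsions(perturbed, toy_tree, movable,
                                fullatom_weights,
                                cutpoints=toy_tree.cutpoints, max_iter=10)
        after = score_structure(out, fullatom_weights, "fullatom",
                                toy_tree.cutpoints).total_score
        assert after <= before + 1e-9
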