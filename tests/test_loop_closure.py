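import numpy as np
import pytest

from anchorloop import (FragmentStore, LoopSpec, apply_torsions,
                        build_fragment_store, ccd_close, kic_close,
                        make_ideal_chain, measure_torsion, perturb_loop)
from anchorloop.errors import (ClosureError, ConfigurationError,
                               KICNoSolution, ValidationError)
from anchorloop.geometry import (BOND_C_N, IDEAL_C_CA_NEXT, IDEAL_CA_N_NEXT)
from anchorloop.kinematics import AnchoredFoldTree
from anchorloop.loop_closure import chainbreak_deviation, default_pivots
from anchorloop.loops import ResolvedLoop
from anchorloop.ramachandran import default_model
from anchorloop.structure import Structure
from conftest import atom_coords


def real_break_deviations(structure, cutpoint):
    """Forward-kinematics oracle: the three real cross-cutpoint distances
    against their ideal-geometry values."""
    c, d = cutpoint
    rc, rd = structure.residue(c), structure.residue(d)
    Cc, CAc = rc.atom("C").position, rc.atom("CA").position
    Nd, CAd = rd.atom("N").position, rd.atom("CA").position
    return (
        abs(np.linalg.norm(Cc - Nd) - BOND_C_N),
        abs(np.linalg.norm(CAc - Nd) - IDEAL_CA_N_NEXT),
        abs(np.linalg.norm(Cc - CAd) - IDEAL_C_CA_NEXT),
    )


def open_loop(structure, tree, delta=30.0, which=1, name="phi"):
    loop = tree.loops[0]
    mk = loop.mobile_keys[which]
    cur = measure_torsion(structure, tree, mk, name)
    return apply_torsions(structure, tree, {(mk, name): cur + delta})


def anchor_torsions(structure, tree):
    return {(k, n): measure_torsion(structure, tree, k, n)
            for k in tree.anchor_keys for n in ("phi", "psi", "omega")}


class TestPerturbers:
    @pytest.mark.parametrize("mode", ["randomize", "small_move", "fragment"])
    def test_anchor_torsions_untouched(self, toy, toy_tree, mode):
        s, _ = toy
        store = build_fragment_store("from_ramachandran", None,
                                     n_fragments=20,
                                     rng=np.random.default_rng(0))
        before = anchor_torsions(s, toy_tree)
        out = perturb_loop(s, toy_tree, mode=mode, magnitude=8.0,
                           rng=np.random.default_rng(2), fragments=store)
        after = anchor_torsions(out, toy_tree)
        for key in before:
            assert abs(before[key] - after[key]) < 1e-12
        assert np.max(np.abs(atom_coords(s, toy_tree.anchor_keys)
                             - atom_coords(out, toy_tree.anchor_keys))) < 1e-9

    def test_small_move_zero_magnitude_is_identity(self, toy, toy_tree):
        s, _ = toy
        out = perturb_loop(s, toy_tree, mode="small_move", magnitude=0.0,
                           rng=np.random.default_rng(1))
        assert np.array_equal(s.coords(), out.coords())

    def test_randomize_deterministic_for_seed(self, toy, toy_tree):
        s, _ = toy
        a = perturb_loop(s, toy_tree, mode="randomize",
                         rng=np.random.default_rng(9))
        b = perturb_loop(s, toy_tree, mode="randomize",
                         rng=np.random.default_rng(9))
        assert np.array_equal(a.coords(), b.coords())

    def test_small_move_lands_in_basins(self, toy, toy_tree):
        s, _ = toy
        rama = default_model()
        out = perturb_loop(s, toy_tree, mode="small_move", magnitude=30.0,
                           rng=np.random.default_rng(5))
        cut, cut_next = toy_tree.cutpoints[0]
        for k in toy_tree.loops[0].mobile_keys:
            if k in (cut, cut_next):
                continue  # chain-measured torsions straddle the break
            phi = measure_torsion(out, toy_tree, k, "phi")
            psi = measure_torsion(out, toy_tree, k, "psi")
            aa = out.residue(k).aa_type
            assert rama.in_basin(aa, phi, psi)

    def test_fragment_without_store_rejected(self, toy, toy_tree):
        s, _ = toy
        with pytest.raises(ConfigurationError):
            perturb_loop(s, toy_tree, mode="fragment",
                         rng=np.random.default_rng(0))


class TestCCD:
    def test_already_closed_is_noop(self, toy, toy_tree):
        s, _ = toy
        res = ccd_close(s, toy_tree)
        assert res.iterations_used == 0
        assert res.break_deviation < 0.1
        assert np.array_equal(s.coords(), res.closed_structure.coords())

    def test_recloses_opened_loop(self, toy, toy_tree):
        s, _ = toy
        opened = open_loop(s, toy_tree, delta=30.0)
        res = ccd_close(opened, toy_tree, max_sweeps=100, tolerance=0.1)
        assert res.break_deviation < 0.1
        assert res.iterations_used <= 100
        # forward-kinematics oracle on the real atoms
        devs = real_break_deviations(res.closed_structure,
                                     toy_tree.cutpoints[0])
        assert max(devs) < 0.1

    def test_break_deviation_monotone_across_sweeps(self, toy, toy_tree):
        s, _ = toy
        opened = open_loop(s, toy_tree, delta=45.0)
        devs = [chainbreak_deviation(opened, toy_tree)]
        for k in (1, 2, 3, 5, 8):
            res = ccd_close(opened, toy_tree, max_sweeps=k, tolerance=1e-9)
            devs.append(res.break_deviation)
        assert all(b <= a + 1e-9 for a, b in zip(devs, devs[1:]))

    def test_per_move_cap_softens_steps(self, toy, toy_tree):
        s, _ = toy
        opened = open_loop(s, toy_tree, delta=25.0)
        cut, cut_next = toy_tree.cutpoints[0]
        before = {(k, n): measure_torsion(opened, toy_tree, k, n)
                  for k in toy_tree.loops[0].mobile_keys
                  for n in ("phi", "psi")
                  if (k, n) not in ((cut, "psi"), (cut_next, "phi"))}
        res = ccd_close(opened, toy_tree, max_sweeps=1, per_move_cap=3.0,
                        tolerance=1e-9)
        for (k, n), v in before.items():
            after = measure_torsion(res.closed_structure, toy_tree, k, n)
            # one sweep: each torsion moved at most once, capped at 3 deg
            assert abs(after - v) < 3.0 + 1e-6

    def test_anchor_untouched(self, toy, toy_tree):
        s, _ = toy
        opened = open_loop(s, toy_tree, delta=40.0)
        res = ccd_close(opened, toy_tree)
        assert np.max(np.abs(
            atom_coords(opened, toy_tree.anchor_keys)
            - atom_coords(res.closed_structure, toy_tree.anchor_keys))) < 1e-9

    def test_nothing_can_move_the_break(self, toy):
        """Degenerate topology: anchor spans to the cutpoint and the
        scaffold C side hangs off the anchor itself, so the N-side mobile
        torsions cannot move either side of the break."""
        s, spec = toy
        resolved = spec.resolve(s)
        anchor_keys = (("B", 10, ""), ("B", 11, ""))
        rl = ResolvedLoop(resolved.spec, resolved.loop_keys, anchor_keys,
                          ("B", 11, ""))
        tree = AnchoredFoldTree(s)
        tree.loops = [rl]
        tree.anchor_keys = anchor_keys
        tree.moving_chain, tree.target_chain = "B", "A"
        t_keys = [r.key for r in s.residues("A")]
        tree._set_root(t_keys[0])
        tree._add_fwd(t_keys[0], t_keys[-1])
        tree._add_jump(t_keys[0], ("B", 10, ""))
        tree._add_bwd(("B", 10, ""), ("B", 1, ""))
        tree._add_fwd(("B", 10, ""), ("B", 11, ""))
        tree._add_jump(("B", 10, ""), ("B", 15, ""))
        tree._add_bwd(("B", 15, ""), ("B", 12, ""))
        tree._add_fwd(("B", 15, ""), ("B", 20, ""))
        tree.cutpoints.append((("B", 11, ""), ("B", 12, "")))
        for num in (6, 7, 8, 9):
            for n in ("phi", "psi", "omega"):
                tree.mobile.add((("B", num, ""), n))
        tree._finish(s)
        with pytest.raises(ClosureError):
            ccd_close(s, tree, rl)


class TestKIC:
    def test_two_mobile_residues_rejected(self, toy):
        s, _ = toy
        with pytest.raises(ValidationError):
            LoopSpec.of("B", 6, 14, 7, 13).resolve(s)

    def test_anchor_pivot_rejected(self, toy, toy_tree):
        s, _ = toy
        loop = toy_tree.loops[0]
        pivots = [loop.mobile_keys[0], toy_tree.anchor_keys[0],
                  loop.mobile_keys[-1]]
        with pytest.raises(ValidationError):
            kic_close(s, toy_tree, pivots=pivots,
                      rng=np.random.default_rng(0))

    def test_solutions_forward_verify(self, toy, toy_tree):
        """Every accepted solution closes the cutpoint to < 1e-4 A by
        direct measurement on the rebuilt structure."""
        s, _ = toy
        rng = np.random.default_rng(21)
        closures = 0
        for trial in range(12):
            opened = perturb_loop(s, toy_tree, mode="small_move",
                                  magnitude=15.0, rng=rng)
            try:
                res = kic_close(opened, toy_tree, rng=rng,
                                resample_nonpivots=False)
            except KICNoSolution:
                continue
            closures += 1
            assert res.break_deviation < 1e-4
            devs = real_break_deviations(res.closed_structure,
                                         toy_tree.cutpoints[0])
            assert max(devs) < 1e-4
        assert closures >= 6

    def test_original_conformation_among_solutions(self, toy, toy_tree):
        s, _ = toy
        loop = toy_tree.loops[0]
        res = kic_close(s, toy_tree, rng=np.random.default_rng(3),
                        resample_nonpivots=False)
        original = {(p, n): measure_torsion(s, toy_tree, p, n)
                    for p in default_pivots(loop) for n in ("phi", "psi")}
        best = min(
            max(abs(sol[k] - original[k]) for k in original)
            for sol in res.solutions)
        assert best < 1e-3

    def test_anchor_untouched(self, toy, toy_tree):
        s, _ = toy
        res = kic_close(s, toy_tree, rng=np.random.default_rng(8))
        assert np.max(np.abs(
            atom_coords(s, toy_tree.anchor_keys)
            - atom_coords(res.closed_structure,
                          toy_tree.anchor_keys))) < 1e-9

    def test_closure_equivalence_with_ccd(self, toy, toy_tree):
        """On small perturbations both methods reach < 0.1 A."""
        s, _ = toy
        rng = np.random.default_rng(5)
        opened = perturb_loop(s, toy_tree, mode="small_move",
                              magnitude=12.0, rng=rng)
        ccd = ccd_close(opened, toy_tree)
        assert ccd.break_deviation < 0.1
        kic = None
        for attempt in range(10):
            try:
                kic = kic_close(opened, toy_tree, rng=rng,
                                resample_nonpivots=False)
                break
            except KICNoSolution:
                continue
        assert kic is not None and kic.break_deviation < 0.1


class TestFragmentStore:
    def test_ramachandran_store_is_basin_valid(self):
        rama = default_model()
        store = build_fragment_store("from_ramachandran", None,
                                     n_fragments=100,
                                     rng=np.random.default_rng(7))
        assert len(store) == 100
        for window in store.windows:
            for phi, psi, omega in window:
                assert rama.in_basin("ALA", phi, psi)
                assert omega == 180.0

    def test_harvest_from_ideal_helix(self):
        residues = make_ideal_chain("H", ["ALA"] * 10,
                                    [(-57.0, -47.0, 180.0)] * 10)
        s = Structure()
        for r in residues:
            s.add_residue(r)
        store = build_fragment_store("from_structures", [s])
        assert len(store) > 0
        for window in store.windows:
            for phi, psi, _ in window:
                assert abs(phi - (-57.0)) < 5.0
                assert abs(psi - (-47.0)) < 5.0

    def test_file_round_trip(self, tmp_path):
        store = build_fragment_store("from_ramachandran", None,
                                     n_fragments=10,
                                     rng=np.random.default_rng(1))
        path = tmp_path / "frags.txt"
        store.save(path)
        loaded = FragmentStore.load(path)
        a = np.array(store.windows)
        b = np.array(loaded.windows)
        assert np.allclose(a, b, atol=1e-3)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            build_fragment_store("from_structures", [])
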