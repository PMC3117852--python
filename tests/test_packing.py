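import itertools

import numpy as np
import pytest

from anchorloop import (DesignSpec, RotamerSet, design_sequence,
                        detect_movable_region, pack_rotamers,
                        score_structure)
from anchorloop.errors import ValidationError
from anchorloop.packing import _PackerTask
from anchorloop.sidechains import replace_sidechain
from conftest import atom_coords


def brute_force_region(structure, resolved_loop, neighbor_radius=10.0,
                       interface_radius=5.0):
    """O(n^2) re-derivation of the movable region."""
    loop_keys = set(resolved_loop.loop_keys)
    region = set(loop_keys)
    residues = structure.residues()

    def center(r):
        name = "CA" if r.aa_type == "GLY" or not r.has_atom("CB") else "CB"
        return r.atom(name).position

    for r in residues:
        for lk in loop_keys:
            if np.linalg.norm(center(r)
                              - center(structure.residue(lk))) \
                    <= neighbor_radius:
                region.add(r.key)
                break
    for r in residues:
        for other in residues:
            if other.key[0] == r.key[0]:
                continue
            done = False
            for a in r.atoms:
                for b in other.atoms:
                    if np.linalg.norm(a.position - b.position) \
                            <= interface_radius:
                        region.add(r.key)
                        done = True
                        break
                if done:
                    break
            if done:
                break
    return region


class TestDetectMovableRegion:
    def test_separated_chains_no_loops_empty(self, toy):
        s, _ = toy
        far = s.copy()
        for r in far.residues("B"):
            for a in r.atoms:
                a.position = a.position + np.array([50.0, 0.0, 0.0])
        assert detect_movable_region(far, []) == set()

    def test_matches_brute_force_oracle(self, toy):
        s, spec = toy
        resolved = spec.resolve(s)
        got = detect_movable_region(s, [spec])
        assert got == brute_force_region(s, resolved)

    def test_anchor_in_region_but_never_designable(self, toy, toy_tree,
                                                   fullatom_weights):
        s, spec = toy
        region = detect_movable_region(s, [spec])
        anchor = toy_tree.anchor_keys[0]
        assert anchor in region  # repacking context includes the anchor
        with pytest.raises(ValidationError):
            design_sequence(s, region,
                            DesignSpec({anchor: frozenset({"ALA"})}),
                            fullatom_weights, np.random.default_rng(0),
                            anchor_keys=toy_tree.anchor_keys)

    def test_bad_radii_rejected(self, toy):
        s, spec = toy
        with pytest.raises(ValidationError):
            detect_movable_region(s, [spec], neighbor_radius=-1.0)


def _restricted_rotamer_set(structure, positions, max_per_pos=5):
    rs = RotamerSet.build(structure, positions)
    for key in rs.candidates:
        rs.candidates[key] = rs.candidates[key][:max_per_pos]
    return rs


def _exhaustive_minimum(structure, positions, rotamer_set, weights,
                        cutpoints):
    """Oracle: enumerate every assignment, rebuild the full structure via
    the public side-chain machinery, and score it from scratch."""
    best = np.inf
    options = [range(len(rotamer_set[k])) for k in positions]
    for combo in itertools.product(*options):
        work = structure.copy()
        for key, ci in zip(positions, combo):
            cand = rotamer_set[key][ci]
            if cand.atoms is None:
                continue
            replace_sidechain(work.residue(key), cand.aa, cand.chis)
        total = score_structure(work, weights, "fullatom",
                                cutpoints).total_score
        best = min(best, total)
    return best


class TestPackRotamers:
    def test_current_only_leaves_structure_unchanged(self, toy,
                                                     fullatom_weights):
        s, spec = toy
        region = detect_movable_region(s, [spec])
        rs = RotamerSet.build(s, region, current_only=True)
        out = pack_rotamers(s, region, fullatom_weights,
                            np.random.default_rng(0), rotamer_set=rs)
        assert np.array_equal(s.coords(), out.coords())

    def test_frozen_region_bitwise_safe(self, toy, fullatom_weights):
        s, spec = toy
        region = detect_movable_region(s, [spec])
        out = pack_rotamers(s, region, fullatom_weights,
                            np.random.default_rng(4))
        frozen = [r.key for r in s.residues() if r.key not in region]
        if frozen:
            assert np.array_equal(atom_coords(s, frozen),
                                  atom_coords(out, frozen))

    def test_never_raises_score(self, toy, toy_tree, fullatom_weights):
        s, spec = toy
        region = detect_movable_region(s, [spec])
        before = score_structure(s, fullatom_weights, "fullatom",
                                 toy_tree.cutpoints).total_score
        out = pack_rotamers(s, region, fullatom_weights,
                            np.random.default_rng(4))
        after = score_structure(out, fullatom_weights, "fullatom",
                                toy_tree.cutpoints).total_score
        assert after <= before + 1e-9

    def test_seeded_determinism(self, toy, fullatom_weights):
        s, spec = toy
        region = detect_movable_region(s, [spec])
        a = pack_rotamers(s, region, fullatom_weights,
                          np.random.default_rng(7))
        b = pack_rotamers(s, region, fullatom_weights,
                          np.random.default_rng(7))
        assert np.array_equal(a.coords(), b.coords())

    def test_empty_region_rejected(self, toy, fullatom_weights):
        s, _ = toy
        with pytest.raises(ValidationError):
            pack_rotamers(s, [], fullatom_weights, np.random.default_rng(0))

    def test_finds_exhaustive_minimum_with_engineered_clash(
            self, toy, toy_tree, fullatom_weights):
        """Two adjacent-in-space LEU side chains forced into a clash: the
        packer must find the global minimum of the enumerated rotamer
        space."""
        s, spec = toy
        work = s.copy()
        positions = [("B", 8, ""), ("B", 12, "")]
        for key in positions:
            replace_sidechain(work.residue(key), "LEU", (-60.0, -60.0))
        rs = _restricted_rotamer_set(work, positions, max_per_pos=5)
        oracle = _exhaustive_minimum(work, positions, rs, fullatom_weights,
                                     toy_tree.cutpoints)
        packed = pack_rotamers(work, positions, fullatom_weights,
                               np.random.default_rng(1), rotamer_set=rs)
        got = score_structure(packed, fullatom_weights, "fullatom",
                              toy_tree.cutpoints).total_score
        assert got == pytest.approx(oracle, abs=1e-6)

    def test_annealed_never_worse_than_greedy(self, toy, fullatom_weights):
        s, spec = toy
        rng_master = np.random.default_rng(100)
        cutpoints = []
        for trial in range(20):
            positions = sorted(
                {("B", int(n), "") for n in
                 rng_master.choice([7, 8, 9, 12, 13], size=3, replace=False)})
            work = s.copy()
            for key in positions:
                chi = tuple(rng_master.choice([-60.0, 60.0, 180.0], size=2))
                replace_sidechain(work.residue(key), "LEU", chi)
            rs = _restricted_rotamer_set(work, positions, max_per_pos=4)
            seed = int(rng_master.integers(2**31 - 1))
            task_rng = np.random.default_rng(seed)
            annealed = pack_rotamers(work, positions, fullatom_weights,
                                     task_rng, rotamer_set=rs)
            greedy = pack_rotamers(work, positions, fullatom_weights,
                                   np.random.default_rng(seed),
                                   rotamer_set=rs, greedy=True)
            ea = score_structure(annealed, fullatom_weights, "fullatom",
                                 cutpoints).total_score
            eg = score_structure(greedy, fullatom_weights, "fullatom",
                                 cutpoints).total_score
            assert ea <= eg + 1e-9


class TestDesign:
    def test_empty_spec_reduces_to_repack(self, toy, fullatom_weights):
        s, spec = toy
        positions = [("B", 8, ""), ("B", 12, "")]
        a = design_sequence(s, positions, DesignSpec({}), fullatom_weights,
                            np.random.default_rng(3))
        b = pack_rotamers(s, positions, fullatom_weights,
                          np.random.default_rng(3))
        assert np.array_equal(a.coords(), b.coords())

    def test_identity_choice_matches_enumeration(self, toy, toy_tree,
                                                 fullatom_weights):
        """A clash-adjacent position allowed {ALA, GLY} must end with the
        identity the exhaustive enumeration prefers."""
        s, _ = toy
        work = s.copy()
        pos = ("B", 9, "")
        clasher = ("B", 11, "")
        replace_sidechain(work.residue(pos), "LEU", (-60.0, -60.0))
        replace_sidechain(work.residue(clasher), "TRP", (-60.0, -60.0))
        ds = DesignSpec({pos: frozenset({"ALA", "GLY"})})
        rs = RotamerSet.build(work, [pos], design_spec=ds)
        oracle_scores = {}
        for ci, cand in enumerate(rs[pos]):
            trial = work.copy()
            if cand.atoms is not None:
                replace_sidechain(trial.residue(pos), cand.aa, cand.chis)
            oracle_scores[ci] = score_structure(
                trial, fullatom_weights, "fullatom",
                toy_tree.cutpoints).total_score
        best_aa = rs[pos][min(oracle_scores, key=oracle_scores.get)].aa
        designed = design_sequence(work, [pos], ds, fullatom_weights,
                                   np.random.default_rng(2),
                                   rotamer_set=rs)
        assert designed.residue(pos).aa_type == best_aa

    def test_positions_outside_spec_keep_identity(self, toy,
                                                  fullatom_weights):
        s, spec = toy
        positions = [("B", 8, ""), ("B", 12, "")]
        ds = DesignSpec({("B", 8, ""): frozenset({"SER", "ALA"})})
        out = design_sequence(s, positions, ds, fullatom_weights,
                              np.random.default_rng(5))
        assert out.residue(("B", 12, "")).aa_type == \
            s.residue(("B", 12, "")).aa_type

    def test_design_spec_file_round_trip(self, tmp_path):
        path = tmp_path / "spec.txt"
        path.write_text("B 8 ALA,GLY,SER\nB 12A LEU\n")
        ds = DesignSpec.from_file(path)
        assert ds.positions[("B", 8, "")] == frozenset({"ALA", "GLY", "SER"})
        assert ds.positions[("B", 12, "A")] == frozenset({"LEU"})

    def test_unknown_amino_acid_rejected(self):
        with pytest.raises(ValidationError):
            DesignSpec({("B", 1, ""): frozenset({"XXX"})})
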