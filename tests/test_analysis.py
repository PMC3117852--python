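import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from anchorloop import (analyze_interface, analyze_loops,
                        compute_rmsd_metrics, compute_sasa, read_pdb,
                        score_structure, write_outputs)
from anchorloop.analysis import MetricsRecord, interface_residue_keys
from anchorloop.errors import InterfaceError
from anchorloop.geometry import BOND_C_N
from anchorloop.scoring import AtomTable, interaction_terms
from anchorloop.structure import Atom, Residue, Structure


def _translate_chain(structure, chain_id, shift):
    out = structure.copy()
    for r in out.residues(chain_id):
        for a in r.atoms:
            a.position = a.position + np.asarray(shift, dtype=float)
    return out


class TestRmsdMetrics:
    def test_identity_all_zero(self, toy):
        s, spec = toy
        rec = compute_rmsd_metrics(s, s, [spec])
        for attr in ("CA_sup_RMSD", "I_sup_bb_RMSD", "ch1_CA_RMSD",
                     "ch1_CA_sup_RMSD", "ch2_CA_RMSD", "ch2_CA_sup_RMSD",
                     "loop_CA_sup_RMSD"):
            assert getattr(rec, attr) == pytest.approx(0.0, abs=1e-9)

    def test_translated_moving_chain_gives_lrmsd_five(self, toy):
        """Closed form: translating the moving chain by 5 A leaves the
        nonmoving-chain superposition at identity, so LRMSD = 5.000."""
        s, spec = toy
        model = _translate_chain(s, "B", [5.0, 0.0, 0.0])
        rec = compute_rmsd_metrics(s, model, [spec])
        assert rec.ch2_CA_RMSD == pytest.approx(5.0, abs=1e-6)
        assert rec.ch1_CA_RMSD == pytest.approx(0.0, abs=1e-9)
        # the moving chain is internally unchanged
        assert rec.ch2_CA_sup_RMSD == pytest.approx(0.0, abs=1e-6)

    def test_global_rotation_superposition_invariance(self, toy):
        s, spec = toy
        R = Rotation.from_euler("y", 37, degrees=True).as_matrix()
        model = s.copy()
        for _, a in model.atoms():
            a.position = R @ a.position + np.array([1.0, -2.0, 0.5])
        rec = compute_rmsd_metrics(s, model, [spec])
        assert rec.CA_sup_RMSD < 1e-6
        assert rec.I_sup_bb_RMSD < 1e-6
        assert rec.loop_CA_sup_RMSD < 1e-6
        assert rec.ch1_CA_sup_RMSD < 1e-6
        assert rec.ch1_CA_RMSD > 1.0  # non-sup metrics see the motion


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        s = Structure()
        s.add_residue(Residue("A", 1, "", "ALA",
                              [Atom("C", "C", [0.0, 0.0, 0.0])]))
        area = compute_sasa(s)[0]
        expected = 4.0 * np.pi * (1.70 + 1.4) ** 2
        assert area == pytest.approx(expected, rel=0.01)

    @pytest.mark.parametrize("d", [2.5, 3.2, 4.5])
    def test_two_spheres_buried_cap_closed_form(self, d):
        s = Structure()
        s.add_residue(Residue("A", 1, "", "ALA",
                              [Atom("C", "C", [0.0, 0.0, 0.0])]))
        s.add_residue(Residue("B", 1, "", "ALA",
                              [Atom("C", "C", [d, 0.0, 0.0])]))
        R = 1.70 + 1.4
        h = R - d / 2.0  # equal spheres: the cap height is symmetric
        expected_each = 4.0 * np.pi * R**2 - 2.0 * np.pi * R * h
        areas = compute_sasa(s)
        assert areas[0] == pytest.approx(expected_each, rel=0.02)
        assert areas[1] == pytest.approx(expected_each, rel=0.02)

    def test_dsasa_is_per_atom_burial_sum(self, toy, fullatom_weights):
        """dSASA_int equals the summed per-atom burial over both chains."""
        s, _ = toy
        rec = analyze_interface(s, fullatom_weights)
        complex_areas = compute_sasa(s)
        from anchorloop.structure import Structure
        per_atom_free = []
        for cid in s.chain_ids:
            alone = Structure({cid: [r.copy() for r in s.residues(cid)]})
            per_atom_free.extend(compute_sasa(alone))
        burial = np.array(per_atom_free) - complex_areas
        assert rec.dSASA_int == pytest.approx(float(burial.sum()), abs=1e-6)

    def test_separated_chains_bury_nothing(self, toy, fullatom_weights):
        s, _ = toy
        apart = _translate_chain(s, "B", [100.0, 0.0, 0.0])
        rec = analyze_interface(apart, fullatom_weights)
        assert abs(rec.dSASA_int) < 1.0  # quadrature noise only


class TestInterfaceAnalyzer:
    def test_single_chain_rejected(self, fullatom_weights):
        s = Structure()
        s.add_residue(Residue("A", 1, "", "ALA",
                              [Atom("C", "C", [0.0, 0.0, 0.0])]))
        with pytest.raises(InterfaceError):
            analyze_interface(s, fullatom_weights)

    def test_pre_separated_chains_no_binding_energy(self, toy,
                                                    fullatom_weights):
        s, _ = toy
        apart = _translate_chain(s, "B", [500.0, 0.0, 0.0])
        rec = analyze_interface(apart, fullatom_weights)
        assert rec.dG_separated == pytest.approx(0.0, abs=1e-9)
        assert rec.dG_cross == pytest.approx(0.0, abs=1e-12)

    def test_dg_cross_matches_pairwise_sum_oracle(self, toy,
                                                  fullatom_weights):
        """Double-loop oracle: summing single-residue-pair cross-chain
        energies reproduces dG_cross."""
        s, _ = toy
        rec = analyze_interface(s, fullatom_weights)
        total = 0.0
        uid = {}
        i = 0
        for cid in s.chain_ids:
            for seq, r in enumerate(s.residues(cid)):
                uid[r.key] = (i, 0 if cid == "A" else 1, seq)
                i += 1
        for ra in s.residues("A"):
            for rb in s.residues("B"):
                ua, ca, sa = uid[ra.key]
                ub, cb, sb = uid[rb.key]
                ta = AtomTable([(ua, ca, sa, ra.aa_type, ra.atoms)])
                tb = AtomTable([(ub, cb, sb, rb.aa_type, rb.atoms)])
                t, _ = interaction_terms(ta, tb)
                total += (fullatom_weights.get("steric_rep") * t["steric_rep"]
                          + fullatom_weights.get("steric_atr")
                          * t["steric_atr"]
                          + fullatom_weights.get("hbond") * t["hbond"])
        assert rec.dG_cross == pytest.approx(total, abs=1e-9)

    def test_scaled_fields_are_definitional(self, toy, fullatom_weights):
        s, _ = toy
        rec = analyze_interface(s, fullatom_weights)
        assert rec.dG_separated_per_dSASAx100 == pytest.approx(
            rec.dG_separated / rec.dSASA_int * 100.0, abs=1e-9)
        assert rec.dG_cross_per_dSASAx100 == pytest.approx(
            rec.dG_cross / rec.dSASA_int * 100.0, abs=1e-9)

    def test_stable_under_chain_order_swap(self, toy, fullatom_weights):
        s, _ = toy
        swapped = Structure()
        for r in s.residues("B"):
            swapped.add_residue(r.copy())
        for r in s.residues("A"):
            swapped.add_residue(r.copy())
        a = analyze_interface(s, fullatom_weights)
        b = analyze_interface(swapped, fullatom_weights)
        assert a.dSASA_int == pytest.approx(b.dSASA_int, abs=1e-6)
        assert a.dG_cross == pytest.approx(b.dG_cross, abs=1e-9)
        assert a.dG_separated == pytest.approx(b.dG_separated, abs=1e-6)


class TestLoopAnalyzer:
    def test_ideal_loop_peptide_bonds(self, toy, fullatom_weights):
        s, spec = toy
        reports, lam = analyze_loops(s, [spec], fullatom_weights)
        for rep in reports:
            if rep.pbnd_dst is not None:
                assert rep.pbnd_dst == pytest.approx(BOND_C_N, abs=1e-6)
                assert not rep.flagged
            assert rep.chainbreak == pytest.approx(0.0, abs=1e-9)

    def test_stretched_bond_flagged(self, toy, toy_tree, fullatom_weights):
        s, spec = toy
        work = s.copy()
        cut, cut_next = toy_tree.cutpoints[0]
        # stretch one peptide bond to ~1.35 A by nudging the next residue
        res_next = work.residue(cut_next)
        u = res_next.atom("N").position \
            - work.residue(cut).atom("C").position
        u = u / np.linalg.norm(u)
        for a in res_next.atoms:
            a.position = a.position + 0.021 * u
        reports, _ = analyze_loops(work, [spec], fullatom_weights)
        by_key = {r.key: r for r in reports}
        assert by_key[cut].flagged
        flagged = [r.key for r in reports if r.flagged]
        assert flagged == [cut]

    def test_lam_total_is_summation_of_reports(self, toy, fullatom_weights):
        from anchorloop.scoring import rotamer_pref_energy
        s, spec = toy
        reports, lam = analyze_loops(s, [spec], fullatom_weights)
        manual = sum(
            fullatom_weights.get("rama") * r.rama
            + fullatom_weights.get("omega") * r.omega_score
            + fullatom_weights.get("chainbreak") * r.chainbreak
            + fullatom_weights.get("rotamer_pref")
            * rotamer_pref_energy(s.residue(r.key).aa_type)
            for r in reports)
        assert lam == pytest.approx(manual, abs=1e-9)


class TestWriters:
    def _record(self, toy, toy_tree, fullatom_weights, description):
        from anchorloop.protocol import TrajectoryRecord
        s, spec = toy
        report = score_structure(s, fullatom_weights, "fullatom",
                                 toy_tree.cutpoints)
        metrics = compute_rmsd_metrics(s, s, [spec]).merge(
            analyze_interface(s, fullatom_weights))
        reports, lam = analyze_loops(s, [spec], fullatom_weights)
        metrics.LAM_total = lam
        return TrajectoryRecord(s, report, metrics, reports, {}, [],
                                description)

    def test_scorefile_header_once_and_description_pattern(
            self, toy, toy_tree, fullatom_weights, tmp_path):
        scorefile = tmp_path / "out.sc"
        for i in (1, 2):
            rec = self._record(toy, toy_tree, fullatom_weights,
                               f"TOY_{i:04d}")
            write_outputs(rec, scorefile, tmp_path / f"out_{i}.pdb")
        lines = scorefile.read_text().strip().splitlines()
        assert len(lines) == 3
        header = lines[0].split()
        assert header[0] == "CA_sup_RMSD"
        assert header[-1] == "description"
        assert "dG_cross/dSASAx100" in header
        assert lines[1].split()[-1] == "TOY_0001"
        assert lines[2].split()[-1] == "TOY_0002"

    def test_written_pdb_round_trips(self, toy, toy_tree, fullatom_weights,
                                     tmp_path):
        rec = self._record(toy, toy_tree, fullatom_weights, "TOY_0001")
        pdb_path = tmp_path / "model.pdb"
        write_outputs(rec, tmp_path / "sc.sc", pdb_path)
        text = pdb_path.read_text()
        # footer blocks in section order
        for block in ("BEGIN SCORE TABLE", "BEGIN LOOP ANALYSIS",
                      "SEQUENCE:", "BEGIN INTERFACE ANALYSIS",
                      "INTERFACE SELECTION"):
            assert block in text
        reread = read_pdb(pdb_path)
        s, _ = toy
        assert np.allclose(s.coords(), reread.coords(), atol=5e-4)
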