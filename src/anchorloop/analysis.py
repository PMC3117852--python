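"""Result analysis: RMSD metric suite, interface analyzer, loop analyzer
and output writers.

The RMSD fields follow the scorefile schema of the modeling protocol:
``loop_CA_sup_RMSD`` (loop recapitulation), ``I_sup_bb_RMSD`` (IRMSD,
interface shape) and ``ch2_CA_RMSD`` (LRMSD, rigid-body placement of the
moving chain after superposition on the nonmoving chain) are the headline
quality measures.  Interface analysis reports buried SASA, two binding
energies (cross-chain pair sum and separated-state difference) and buried
unsatisfied polar atoms.  The loop analyzer emphasizes the closure-relevant
terms (rama, rotamer preference, omega, chainbreak) and peptide bond
lengths, flagging bonds that stray more than 0.02 A from 1.329 A.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import biotite.structure as bst
import numpy as np

from .errors import InterfaceError, ScoringError, ValidationError
from .geometry import BOND_C_N, kabsch, rmsd
from .kinematics import measure_torsion
from .loops import LoopSpec, ResolvedLoop
from .ramachandran import default_model
from .scoring import (AtomTable, ScoreWeights, _omega_term, chainbreak_term,
                      interaction_terms, rotamer_pref_energy, score_structure)
from .structure import ResidueKey, Structure, write_pdb

PBND_IDEAL = BOND_C_N
PBND_FLAG = 0.02


@dataclass
class MetricsRecord:
    """One scorefile row (the Table-style output schema)."""

    CA_sup_RMSD: float = 0.0
    I_sup_bb_RMSD: float = 0.0
    ch1_CA_RMSD: float = 0.0
    ch1_CA_sup_RMSD: float = 0.0
    ch2_CA_RMSD: float = 0.0
    ch2_CA_sup_RMSD: float = 0.0
    loop_CA_sup_RMSD: float = 0.0
    dSASA_int: float = 0.0
    dG_cross: float = 0.0
    dG_cross_per_dSASAx100: float = 0.0
    dG_separated: float = 0.0
    dG_separated_per_dSASAx100: float = 0.0
    delta_unsatHbonds: int = 0
    total_score: float = 0.0
    LAM_total: float = 0.0
    description: str = ""

    def merge(self, other: "MetricsRecord") -> "MetricsRecord":
        out = MetricsRecord(**{f.name: getattr(self, f.name)
                               for f in dc_fields(self)})
        for f in dc_fields(other):
            v = getattr(other, f.name)
            if f.name == "description":
                out.description = v or out.description
            elif v:
                setattr(out, f.name, v)
        return out


#: scorefile column headers, in order (slash names as printed)
SCOREFILE_COLUMNS = [
    ("CA_sup_RMSD", "CA_sup_RMSD"),
    ("I_sup_bb_RMSD", "I_sup_bb_RMSD"),
    ("ch1_CA_RMSD", "ch1_CA_RMSD"),
    ("ch1_CA_sup_RMSD", "ch1_CA_sup_RMSD"),
    ("ch2_CA_RMSD", "ch2_CA_RMSD"),
    ("ch2_CA_sup_RMSD", "ch2_CA_sup_RMSD"),
    ("loop_CA_sup_RMSD", "loop_CA_sup_RMSD"),
    ("dSASA_int", "dSASA_int"),
    ("dG_cross", "dG_cross"),
    ("dG_cross/dSASAx100", "dG_cross_per_dSASAx100"),
    ("dG_separated", "dG_separated"),
    ("dG_separated/dSASAx100", "dG_separated_per_dSASAx100"),
    ("delta_unsatHbonds", "delta_unsatHbonds"),
    ("total_score", "total_score"),
    ("LAM_total", "LAM_total"),
    ("description", "description"),
]


# ---------------------------------------------------------------------------
# RMSD metrics
# ---------------------------------------------------------------------------

def _matched_ca(reference, model, keys):
    ref = np.array([reference.residue(k).atom("CA").position for k in keys])
    mod = np.array([model.residue(k).atom("CA").position for k in keys])
    return ref, mod


def _sup_rmsd(ref, mod):
    if len(ref) < 3:
        return rmsd(ref, mod)
    R, t = kabsch(ref, mod)
    return rmsd(ref, mod @ R.T + t)


def interface_residue_keys(structure: Structure, cutoff: float = 5.0
                           ) -> list[ResidueKey]:
    """Residues with any heavy atom within ``cutoff`` of another chain."""
    by_chain = {c: np.array([a.position for r in structure.residues(c)
                             for a in r.atoms]) for c in structure.chain_ids}
    out = []
    for res in structure.residues():
        own = np.array([a.position for a in res.atoms])
        for cid, other in by_chain.items():
            if cid == res.key[0]:
                continue
            d = np.linalg.norm(own[:, None, :] - other[None, :, :], axis=2)
            if d.min() <= cutoff:
                out.append(res.key)
                break
    return out


def compute_rmsd_metrics(
    reference: Structure,
    model: Structure,
    loop_specs,
    moving_chain: str | None = None,
) -> MetricsRecord:
    """RMSD fields of the metrics record, comparing ``model`` to the
    unmodified ``reference``.

    ``ch2_CA_RMSD`` (LRMSD) superposes the whole model on the nonmoving
    chain's CA atoms and then measures the moving chain -- a rigid-body
    placement measure.  "sup" variants superpose on the measured atoms
    themselves.
    """
    ref_keys = [r.key for r in reference.residues()]
    mod_keys = [r.key for r in model.residues()]
    if ref_keys != mod_keys:
        raise ValidationError("reference and model residues differ")

    loops = [s if isinstance(s, ResolvedLoop) else s.resolve(reference)
             for s in loop_specs]
    if moving_chain is None and loops:
        moving_chain = loops[0].chain_id
    chains = reference.chain_ids
    ch1 = next((c for c in chains if c != moving_chain), chains[0])
    ch2 = moving_chain if moving_chain is not None else \
        (chains[1] if len(chains) > 1 else chains[0])

    rec = MetricsRecord()
    ref_all, mod_all = _matched_ca(reference, model, ref_keys)
    rec.CA_sup_RMSD = _sup_rmsd(ref_all, mod_all)

    ikeys = interface_residue_keys(reference)
    if ikeys:
        ref_bb, mod_bb = [], []
        for k in ikeys:
            for name in ("N", "CA", "C", "O"):
                if reference.residue(k).has_atom(name) \
                        and model.residue(k).has_atom(name):
                    ref_bb.append(reference.residue(k).atom(name).position)
                    mod_bb.append(model.residue(k).atom(name).position)
        rec.I_sup_bb_RMSD = _sup_rmsd(np.array(ref_bb), np.array(mod_bb))

    k1 = [r.key for r in reference.residues(ch1)]
    k2 = [r.key for r in reference.residues(ch2)]
    ref1, mod1 = _matched_ca(reference, model, k1)
    ref2, mod2 = _matched_ca(reference, model, k2)
    rec.ch1_CA_RMSD = rmsd(ref1, mod1)
    rec.ch1_CA_sup_RMSD = _sup_rmsd(ref1, mod1)
    rec.ch2_CA_sup_RMSD = _sup_rmsd(ref2, mod2)
    # LRMSD: superpose the complex on the nonmoving chain, measure ch2
    R, t = kabsch(ref1, mod1)
    rec.ch2_CA_RMSD = rmsd(ref2, mod2 @ R.T + t)

    if loops:
        loop_keys = [k for lp in loops for k in lp.loop_keys]
        ref_l, mod_l = _matched_ca(reference, model, loop_keys)
        rec.loop_CA_sup_RMSD = _sup_rmsd(ref_l, mod_l)
    return rec


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def _to_atom_array(structure: Structure) -> bst.AtomArray:
    atoms = list(structure.atoms())
    arr = bst.AtomArray(len(atoms))
    for i, (res, atom) in enumerate(atoms):
        arr.chain_id[i] = res.chain_id
        arr.res_id[i] = res.number
        arr.ins_code[i] = res.insertion_code
        arr.res_name[i] = res.aa_type
        arr.atom_name[i] = atom.name
        arr.element[i] = atom.element
        arr.coord[i] = atom.position
        arr.hetero[i] = False
    return arr


def compute_sasa(structure: Structure, probe_radius: float = 1.4,
                 n_points: int = 960) -> np.ndarray:
    """Shrake-Rupley solvent-accessible surface area per atom (A^2),
    in :meth:`Structure.atoms` order; deterministic for fixed quadrature."""
    arr = _to_atom_array(structure)
    try:
        areas = bst.sasa(arr, probe_radius=probe_radius,
                         point_number=n_points, vdw_radii="Single")
    except KeyError as exc:
        raise ScoringError(f"no SASA radius for element: {exc}") from exc
    return np.nan_to_num(np.asarray(areas, dtype=float))


def total_sasa(structure: Structure, **kw) -> float:
    return float(compute_sasa(structure, **kw).sum())


def _single_chain(structure: Structure, cid: str) -> Structure:
    return Structure({cid: [r.copy() for r in structure.residues(cid)]})


def _separate_chains(structure: Structure, cid: str,
                     offset: float = 500.0) -> Structure:
    out = structure.copy()
    for r in out.residues(cid):
        for a in r.atoms:
            a.position = a.position + np.array([offset, 0.0, 0.0])
    return out


# ---------------------------------------------------------------------------
# interface analyzer
# ---------------------------------------------------------------------------

def analyze_interface(structure: Structure, weights: ScoreWeights,
                      cutpoints=()) -> MetricsRecord:
    """Buried SASA, binding energies and buried unsatisfied polar atoms.

    dSASA_int = SASA(ch1) + SASA(ch2) - SASA(complex);
    dG_cross sums cross-chain residue-pair energies; dG_separated
    re-scores the complex with the moving chain translated 500 A away
    (without repacking the separated state).
    """
    chains = structure.chain_ids
    if len(chains) < 2:
        raise InterfaceError("interface analysis needs two chains")
    c1, c2 = chains[0], chains[1]

    sasa_complex = total_sasa(structure)
    sasa_1 = total_sasa(_single_chain(structure, c1))
    sasa_2 = total_sasa(_single_chain(structure, c2))
    dsasa = sasa_1 + sasa_2 - sasa_complex

    rec = MetricsRecord()
    rec.dSASA_int = dsasa

    t1 = AtomTable.from_structure(structure, chains={c1})
    t2 = AtomTable.from_structure(structure, chains={c2})
    totals, _ = interaction_terms(t1, t2)
    rec.dG_cross = (weights.get("steric_rep") * totals["steric_rep"]
                    + weights.get("steric_atr") * totals["steric_atr"]
                    + weights.get("hbond") * totals["hbond"])

    bound = score_structure(structure, weights, "fullatom", cutpoints)
    apart = score_structure(_separate_chains(structure, c2), weights,
                            "fullatom", cutpoints)
    rec.total_score = bound.total_score
    rec.dG_separated = bound.total_score - apart.total_score

    rec.delta_unsatHbonds = _count_unsat_polar(structure)
    if dsasa > 1e-6:
        rec.dG_cross_per_dSASAx100 = rec.dG_cross / dsasa * 100.0
        rec.dG_separated_per_dSASAx100 = rec.dG_separated / dsasa * 100.0
    return rec


def _count_unsat_polar(structure: Structure, burial_cutoff: float = 0.01,
                       partner_cutoff: float = 3.5) -> int:
    """Buried interface donor/acceptor heavy atoms with no polar partner
    within the H-bond distance envelope."""
    ikeys = set(interface_residue_keys(structure))
    areas = compute_sasa(structure)
    table = AtomTable.from_structure(structure)
    polar_idx = sorted(set(table.don.tolist()) | set(table.acc.tolist()))
    atoms = list(structure.atoms())
    uid_of = {}
    uid = 0
    for cid in structure.chain_ids:
        for res in structure.residues(cid):
            uid_of[uid] = res.key
            uid += 1
    count = 0
    polar_pos = table.pos[polar_idx]
    polar_uid = table.uid[polar_idx]
    for i in polar_idx:
        key = uid_of[int(table.uid[i])]
        if key not in ikeys:
            continue
        if areas[i] >= burial_cutoff:
            continue
        d = np.linalg.norm(polar_pos - table.pos[i][None, :], axis=1)
        partners = (d < partner_cutoff) & (d > 1e-6) & (polar_uid != table.uid[i])
        if not partners.any():
            count += 1
    return count


# ---------------------------------------------------------------------------
# loop analyzer
# ---------------------------------------------------------------------------

@dataclass
class LoopResidueReport:
    key: ResidueKey
    phi: float | None
    psi: float | None
    omega: float | None
    rama: float
    omega_score: float
    chainbreak: float
    pbnd_dst: float | None
    flagged: bool = False


def analyze_loops(structure: Structure, loop_specs, weights: ScoreWeights,
                  cutpoints=None):
    """Per-loop-residue closure diagnostics plus LAM_total, the weighted
    sum of the closure-relevant terms (rama, rotamer preference, omega,
    chainbreak) over loop residues."""
    loops = [s if isinstance(s, ResolvedLoop) else s.resolve(structure)
             for s in loop_specs]
    if cutpoints is None:
        cutpoints = []
        for lp in loops:
            nxt = structure.neighbor_key(lp.cut_key, +1)
            if nxt is not None:
                cutpoints.append((lp.cut_key, nxt))
    rama_model = default_model()
    reports = []
    lam = 0.0
    cut_map = {}
    for cut in cutpoints:
        v = chainbreak_term(structure, cut)
        cut_map[cut[0]] = cut_map.get(cut[0], 0.0) + 0.5 * v
        cut_map[cut[1]] = cut_map.get(cut[1], 0.0) + 0.5 * v
    for lp in loops:
        for k in lp.loop_keys:
            res = structure.residue(k)
            phi = measure_torsion(structure, None, k, "phi")
            psi = measure_torsion(structure, None, k, "psi")
            omega = measure_torsion(structure, None, k, "omega")
            rama_v = rama_model.score(res.aa_type, phi, psi) \
                if phi is not None and psi is not None else 0.0
            omega_v = _omega_term(res.aa_type, omega) \
                if omega is not None and k not in cut_map else 0.0
            cb_v = cut_map.get(k, 0.0)
            nxt = structure.neighbor_key(k, +1)
            pbnd = None
            if nxt is not None:
                pbnd = float(np.linalg.norm(
                    structure.residue(k).atom("C").position
                    - structure.residue(nxt).atom("N").position))
            flagged = pbnd is not None and abs(pbnd - PBND_IDEAL) > PBND_FLAG
            reports.append(LoopResidueReport(k, phi, psi, omega, rama_v,
                                             omega_v, cb_v, pbnd, flagged))
            lam += (weights.get("rama") * rama_v
                    + weights.get("omega") * omega_v
                    + weights.get("chainbreak") * cb_v
                    + weights.get("rotamer_pref")
                    * rotamer_pref_energy(res.aa_type))
    return reports, float(lam)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _fmt(v):
    if isinstance(v, float):
        return f"{v:.3f}"
    return str(v)


def format_scorefile_row(metrics: MetricsRecord) -> str:
    return " ".join(_fmt(getattr(metrics, attr))
                    for _, attr in SCOREFILE_COLUMNS)


def write_scorefile(metrics_list, path) -> None:
    """Append scorefile rows, writing the header once."""
    path = Path(path)
    lines = []
    if not path.exists() or not path.read_text().strip():
        lines.append(" ".join(col for col, _ in SCOREFILE_COLUMNS))
    for m in (metrics_list if isinstance(metrics_list, (list, tuple))
              else [metrics_list]):
        lines.append(format_scorefile_row(m))
    with path.open("a") as fh:
        fh.write("\n".join(lines) + "\n")


def _footer_blocks(record) -> list[str]:
    """Analysis footer in the result-PDB section order: score table, loop
    analysis, sequence, interface analysis, interface selections."""
    lines = ["# BEGIN SCORE TABLE"]
    sr = record.score_report
    if sr is not None:
        lines.append("# total_score " + _fmt(sr.total_score))
        terms = sorted(sr.term_totals)
        lines.append("# label " + " ".join(terms))
        for key, vals in sr.per_residue.items():
            label = f"{key[0]}{key[1]}{key[2]}"
            lines.append("# " + label + " "
                         + " ".join(_fmt(vals.get(t, 0.0)) for t in terms))
    lines.append("# END SCORE TABLE")
    lines.append("# BEGIN LOOP ANALYSIS")
    lines.append("# residue phi psi omega rama omega_score chainbreak "
                 "pbnd_dst flag")
    for rep in record.loop_reports or []:
        vals = [rep.phi, rep.psi, rep.omega, rep.rama, rep.omega_score,
                rep.chainbreak, rep.pbnd_dst]
        txt = " ".join("NA" if v is None else _fmt(float(v)) for v in vals)
        label = f"{rep.key[0]}{rep.key[1]}{rep.key[2]}"
        lines.append(f"# {label} {txt}" + (" *" if rep.flagged else ""))
    lines.append(f"# LAM_total {_fmt(record.metrics.LAM_total)}")
    lines.append("# END LOOP ANALYSIS")
    st = record.final_structure
    seq = "".join(r.one_letter() for r in st.residues())
    lines.append(f"# SEQUENCE: {seq}")
    lines.append("# BEGIN INTERFACE ANALYSIS")
    m = record.metrics
    for col, attr in SCOREFILE_COLUMNS:
        if attr == "description":
            continue
        lines.append(f"# {col} {_fmt(getattr(m, attr))}")
    lines.append("# END INTERFACE ANALYSIS")
    ikeys = interface_residue_keys(st)
    sel = "+".join(f"{k[1]}{k[2]}" for k in ikeys)
    chains = ",".join(sorted({k[0] for k in ikeys}))
    lines.append(f"# INTERFACE SELECTION: chains {chains} residues {sel}")
    return lines


def write_outputs(record, scorefile_path, pdb_path) -> None:
    """Write one trajectory: a scorefile row (header once) and the result
    PDB with the analysis footer blocks appended."""
    metrics = record.metrics
    metrics.description = record.description
    write_scorefile(metrics, scorefile_path)
    write_pdb(record.final_structure, pdb_path, footer=_footer_blocks(record))
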