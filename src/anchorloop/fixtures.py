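"""Synthetic ideal-geometry fixtures.

The toy anchored complex emulates the study system at miniature scale: a
rigid target helix (chain A) and a scaffold (chain B) whose central surface
loop carries a single anchor residue placed in contact with the target.
Bond lengths and angles are exactly the ideal values used by the kinematics
module, so freshly built fixtures score zero chainbreak and round-trip
through the internal-coordinate machinery to machine precision.

What these fixtures do not emulate: real side-chain diversity (they are
poly-alanine apart from the anchor), crystallographic coordinate noise,
and the packed, funnel-shaped interfaces of real complexes.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .errors import StructureError, ValidationError
from .geometry import (BOND_C_N, BOND_CA_C, BOND_N_CA, ANGLE_CA_C_N,
                       ANGLE_C_N_CA, ANGLE_N_CA_C, place_atom)
from .loops import LoopSpec
from .ramachandran import default_model
from .sidechains import build_residue_atoms
from .structure import Atom, Residue, Structure

HELIX = (-57.0, -47.0)
STRAND = (-130.0, 135.0)


def make_ideal_chain(chain_id: str, aa_types: list[str],
                     torsions: list[tuple[float, float, float]],
                     start_number: int = 1) -> list[Residue]:
    """Build a chain at ideal geometry from per-residue (phi, psi, omega).

    phi of the first residue and psi/omega of the last are not used.
    Side chains come from the ideal templates at their default chis.
    """
    n = len(aa_types)
    if len(torsions) != n:
        raise ValidationError("need one torsion triple per residue")
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    C = CA + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    backbones = [(N, CA, C)]
    for i in range(n - 1):
        _, psi, omega = torsions[i]
        phi_next = torsions[i + 1][0]
        N_, CA_, C_ = backbones[-1]
        Nn = place_atom(N_, CA_, C_, BOND_C_N, ANGLE_CA_C_N, psi)
        CAn = place_atom(CA_, C_, Nn, BOND_N_CA, ANGLE_C_N_CA, omega)
        Cn = place_atom(C_, Nn, CAn, BOND_CA_C, ANGLE_N_CA_C, phi_next)
        backbones.append((Nn, CAn, Cn))

    residues = []
    for i, (aa, (Ni, CAi, Ci)) in enumerate(zip(aa_types, backbones)):
        psi = torsions[i][1] if i < n - 1 else 135.0
        O = place_atom(Ni, CAi, Ci, 1.231, 120.5, psi + 180.0)
        res = Residue(chain_id, start_number + i, "", aa)
        res.atoms = [
            Atom("N", "N", Ni), Atom("CA", "C", CAi),
            Atom("C", "C", Ci), Atom("O", "O", O),
        ]
        res.atoms += build_residue_atoms({"N": Ni, "CA": CAi, "C": Ci}, aa)
        residues.append(res)
    return residues


def make_antiparallel_pair(n: int = 6) -> Structure:
    """Two ideal strands related by a 2-fold axis, placed so the central
    residues form an antiparallel hydrogen-bond ladder."""
    from scipy.spatial.transform import Rotation as _Rot
    base = make_ideal_chain("A", ["ALA"] * n, [(-139.0, 135.0, 180.0)] * n)
    st = Structure()
    for r in base:
        st.add_residue(r.copy())
    R = _Rot.from_rotvec(np.array([0.0, 0.0, 1.0]) * np.pi).as_matrix()
    origin = np.array([4.5, 2.75, -2.0])
    for r in base:
        twin = r.copy()
        twin.chain_id = "B"
        for a in twin.atoms:
            a.position = R @ (a.position - origin) + origin
        st.add_residue(twin)
    return st


def make_toy_anchored_complex(
    n_target: int = 12,
    n_scaffold: int = 20,
    loop_len: int = 9,
    seed: int = 1,
    anchor_aa: str = "LEU",
) -> tuple[Structure, LoopSpec]:
    """Deterministic two-chain toy complex plus its loop specification.

    The scaffold loop sits mid-chain with the anchor at its center; the
    anchor's CB is placed 4 A from a mid-helix target CB, with the scaffold
    body oriented away from the target.
    """
    if loop_len < 5:
        raise ValidationError("loop_len must be >= 5 (anchor + 3 mobile + cut)")
    if n_scaffold < loop_len + 4:
        raise ValidationError("n_scaffold must be >= loop_len + 4")
    if n_target < 5:
        raise ValidationError("n_target must be >= 5")

    rng = np.random.default_rng(seed)
    rama = default_model()

    target = make_ideal_chain("A", ["ALA"] * n_target,
                              [(*HELIX, 180.0)] * n_target)

    loop_i0 = (n_scaffold - loop_len) // 2       # 0-based loop start
    anchor_i = loop_i0 + loop_len // 2
    aa_types = ["ALA"] * n_scaffold
    aa_types[anchor_i] = anchor_aa

    def build_scaffold():
        torsions = []
        for i in range(n_scaffold):
            if loop_i0 <= i < loop_i0 + loop_len:
                phi, psi = rama.sample(aa_types[i], rng)
                torsions.append((phi, psi, 180.0))
            else:
                torsions.append((*HELIX, 180.0))
        return make_ideal_chain("B", aa_types, torsions)

    def worst_overlap(residues):
        """Minimum heavy-atom distance between non-neighbor residue pairs
        involving at least one loop residue."""
        pos, rid, in_loop = [], [], []
        for i, r in enumerate(residues):
            for a in r.atoms:
                pos.append(a.position)
                rid.append(i)
                in_loop.append(loop_i0 <= i < loop_i0 + loop_len)
        pos = np.array(pos)
        rid = np.array(rid)
        in_loop = np.array(in_loop)
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=2)
        mask = (np.abs(rid[:, None] - rid[None, :]) >= 2) & (
            in_loop[:, None] | in_loop[None, :])
        return float(d[mask].min()) if mask.any() else np.inf

    # -- placement geometry ---------------------------------------------
    t_res = target[n_target // 2]
    t_ca = next(a for a in t_res.atoms if a.name == "CA").position
    t_cb = next(a for a in t_res.atoms if a.name == "CB").position
    u = (t_cb - t_ca) / np.linalg.norm(t_cb - t_ca)
    contact = t_cb + 4.0 * u
    t_pos = np.array([a.position for r in target for a in r.atoms])

    def place(residues):
        """Put the anchor CB at the contact point, point the scaffold body
        away from the target, then find the smallest outward shift that
        clears interchain overlaps.  Returns the shift (inf = unusable)."""
        a_res = residues[anchor_i]
        a_cb = next(a for a in a_res.atoms if a.name == "CB").position
        shift = contact - a_cb
        for res in residues:
            for atom in res.atoms:
                atom.position = atom.position + shift
        com = np.mean([a.position for r in residues for a in r.atoms], axis=0)
        w = com - contact
        wn = np.linalg.norm(w)
        if wn > 1e-6:
            rot, _ = Rotation.align_vectors(u[None, :], (w / wn)[None, :])
            R = rot.as_matrix()
            for res in residues:
                for atom in res.atoms:
                    atom.position = R @ (atom.position - contact) + contact
        s_pos = np.array([a.position for r in residues for a in r.atoms])

        def clear_at(t):
            d = np.linalg.norm(
                (s_pos + t * u)[:, None, :] - t_pos[None, :, :], axis=2)
            return float(d.min())

        lo, hi = 0.0, 1.0
        if clear_at(hi) < 2.6:
            return np.inf
        if clear_at(lo) < 2.6:
            for _ in range(20):
                mid = 0.5 * (lo + hi)
                if clear_at(mid) >= 2.6:
                    hi = mid
                else:
                    lo = mid
        else:
            hi = 0.0
        for res in residues:
            for atom in res.atoms:
                atom.position = atom.position + hi * u
        return hi

    # draw loop conformations until one neither folds onto itself nor
    # buries the scaffold in the target
    scaffold = None
    best = (-np.inf, None)
    for _ in range(60):
        cand = build_scaffold()
        sep = worst_overlap(cand)
        shift = place(cand)
        if sep >= 2.6 and np.isfinite(shift):
            scaffold = cand
            break
        score = sep - (0.0 if np.isfinite(shift) else 10.0)
        if score > best[0]:
            best = (score, cand)
    if scaffold is None:
        scaffold = best[1]

    structure = Structure()
    for res in target + scaffold:
        structure.add_residue(res)

    anchor_number = anchor_i + 1
    spec = LoopSpec.of("B", loop_i0 + 1, loop_i0 + loop_len,
                       anchor_number, anchor_number)

    a_atoms = np.array([a.position for a in structure.residue(
        ("B", anchor_number, "")).atoms])
    t_all = np.array([a.position for r in structure.residues("A")
                      for a in r.atoms])
    dmin = np.min(np.linalg.norm(
        a_atoms[:, None, :] - t_all[None, :, :], axis=2))
    if dmin > 5.0:
        raise StructureError("toy fixture lost its anchor-target contact")
    return structure, spec
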