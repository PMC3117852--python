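"""Anchor grafting: build a starting structure for anchored design.

Given (1) a target bound to its natural partner, (2) the anchor residues
extracted from that partner, and (3) a free scaffold, grafting replaces a
stretch of a scaffold surface loop with the anchor's sequence identity and
conformation, re-closes the loop by CCD around the rigid anchor, and
rigidly superposes the modified scaffold so the grafted anchor sits exactly
on the donor's binding pose against the target.  The output (target chain +
modified scaffold chain) is directly usable as protocol input; the scaffold
may still clash with or eclipse the target -- resolving that is the design
protocol's job, not the graft's.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import GraftError, ValidationError
from .geometry import (ANGLE_C_N_CA, ANGLE_CA_C_N, BOND_C_N, BOND_CA_C,
                       BOND_N_CA, ANGLE_N_CA_C, kabsch, place_atom, rmsd)
from .kinematics import build_graft_tree, measure_torsion
from .loop_closure import ccd_close, perturb_loop
from .loops import LoopSpec
from .structure import Residue, ResidueKey, ResidueSpan, Structure, select_span


@dataclass(frozen=True)
class GraftSpec:
    """Where the anchor goes: the scaffold loop and the contiguous loop
    positions the anchor will occupy (no net insertion or deletion -- the
    graft replaces exactly as many scaffold residues as the anchor has)."""

    scaffold_loop: ResidueSpan
    occupy: ResidueSpan

    def validate(self, scaffold: Structure, anchor_len: int):
        loop = select_span(scaffold, self.scaffold_loop)
        occ = select_span(scaffold, self.occupy)
        loop_keys = [r.key for r in loop]
        occ_keys = [r.key for r in occ]
        if not set(occ_keys) <= set(loop_keys):
            raise ValidationError("occupied positions must lie in the loop")
        if len(occ_keys) != anchor_len:
            raise ValidationError(
                f"anchor has {anchor_len} residues but {len(occ_keys)} "
                "scaffold positions are to be occupied")
        if anchor_len > len(loop_keys) - 3:
            raise ValidationError(
                "anchor too long: closure needs at least 3 mobile residues "
                "in the loop")
        i0 = loop_keys.index(occ_keys[0])
        if loop_keys[i0:i0 + len(occ_keys)] != occ_keys:
            raise ValidationError("occupied positions must be contiguous")
        return loop_keys, occ_keys

    @staticmethod
    def from_file(path) -> "GraftSpec":
        """Spec file with two lines::

            loop <chain> <start> <stop>
            anchor <chain> <start> <stop>
        """
        loop = occupy = None
        for line in Path(path).read_text().splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            toks = line.split()
            if len(toks) != 4:
                raise ValidationError(
                    "graft spec lines are '<kind> <chain> <start> <stop>'")
            kind, chain, start, stop = toks
            span = ResidueSpan.of(chain, int(start), int(stop))
            if kind == "loop":
                loop = span
            elif kind == "anchor":
                occupy = span
            else:
                raise ValidationError(f"unknown graft spec entry {kind!r}")
        if loop is None or occupy is None:
            raise ValidationError("graft spec needs 'loop' and 'anchor' lines")
        return GraftSpec(loop, occupy)


def extract_anchor(complex_structure: Structure,
                   anchor_span: ResidueSpan) -> Structure:
    """Pull the anchor residues out of the partner chain, coordinates
    unchanged (they stay in the target complex frame)."""
    residues = select_span(complex_structure, anchor_span)
    chains = {r.chain_id for r in residues}
    if len(chains) != 1:
        raise ValidationError("anchor span crosses chains")
    out = Structure()
    for r in residues:
        out.add_residue(r.copy())
    return out


def _backbone_coords(residues) -> np.ndarray:
    return np.array([r.atom(n).position for r in residues
                     for n in ("N", "CA", "C")])


def graft_anchor(
    target: Structure,
    partner_anchor: Structure,
    scaffold: Structure,
    graft_spec: GraftSpec,
    rng: np.random.Generator | None = None,
    max_attempts: int = 20,
    closure_tolerance: float = 0.1,
) -> Structure:
    """Insert the anchor into the scaffold loop, close the loop with CCD
    around the rigid anchor, and align the graft onto the anchor's binding
    pose on the target.

    The junction into the anchor is idealized (ideal peptide geometry at
    the N-side seam; the C-side seam is the closure cutpoint).  Non-loop
    scaffold residues experience one common rigid transform only.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    anchor_res = partner_anchor.residues()
    loop_keys, occ_keys = graft_spec.validate(scaffold, len(anchor_res))

    work = scaffold.copy()
    chain_id = graft_spec.scaffold_loop.chain_id

    # -- place the anchor so the N-side junction has ideal geometry ------
    pre_key = work.neighbor_key(occ_keys[0], -1)
    if pre_key is None:
        raise ValidationError("anchor cannot occupy the first chain position")
    pre = work.residue(pre_key)
    psi_pre = measure_torsion(scaffold, None, pre_key, "psi")
    if psi_pre is None:
        psi_pre = 140.0
    phi_anchor = float(rng.uniform(-140.0, -60.0))
    Npre = pre.atom("N").position
    CApre = pre.atom("CA").position
    Cpre = pre.atom("C").position
    tN = place_atom(Npre, CApre, Cpre, BOND_C_N, ANGLE_CA_C_N, psi_pre)
    tCA = place_atom(CApre, Cpre, tN, BOND_N_CA, ANGLE_C_N_CA, 180.0)
    tC = place_atom(Cpre, tN, tCA, BOND_CA_C, ANGLE_N_CA_C, phi_anchor)
    first = anchor_res[0]
    src = np.array([first.atom(n).position for n in ("N", "CA", "C")])
    R, t = kabsch(np.array([tN, tCA, tC]), src)

    # -- replace the occupied scaffold positions -------------------------
    for occ_key, donor in zip(occ_keys, anchor_res):
        res = work.residue(occ_key)
        res.aa_type = donor.aa_type
        res.atoms = [a.copy() for a in donor.atoms]
        for a in res.atoms:
            a.position = R @ a.position + t

    # -- rebuild the post-anchor seam onto the anchor --------------------
    # the residue(s) between the anchor end and the cutpoint hang off the
    # anchor kinematically; give them ideal-geometry backbones continuing
    # from the grafted anchor so the only break left is at the cutpoint
    spec = LoopSpec(
        graft_spec.scaffold_loop,
        graft_spec.occupy,
    )
    resolved = spec.resolve(work)
    seam_keys = []
    k = work.neighbor_key(occ_keys[-1], +1)
    while k is not None:
        seam_keys.append(k)
        if k == resolved.cut_key:
            break
        k = work.neighbor_key(k, +1)
    prev_key = occ_keys[-1]
    from .sidechains import build_residue_atoms
    for key in seam_keys:
        prev_res = work.residue(prev_key)
        res = work.residue(key)
        Np = prev_res.atom("N").position
        CAp = prev_res.atom("CA").position
        Cp = prev_res.atom("C").position
        psi_prev = float(rng.uniform(-180.0, 180.0))
        phi_here = float(rng.uniform(-150.0, -50.0))
        N = place_atom(Np, CAp, Cp, BOND_C_N, ANGLE_CA_C_N, psi_prev)
        CA = place_atom(CAp, Cp, N, BOND_N_CA, ANGLE_C_N_CA, 180.0)
        C = place_atom(Cp, N, CA, BOND_CA_C, ANGLE_N_CA_C, phi_here)
        res.atoms = build_residue_atoms({"N": N, "CA": CA, "C": C},
                                        res.aa_type, include_backbone=True)
        prev_key = key

    # -- close the loop around the rigid anchor --------------------------
    tree = build_graft_tree(work, spec)
    loop = tree.loops[0]
    closed = None
    result = ccd_close(work, tree, loop, tolerance=closure_tolerance)
    if result.break_deviation < closure_tolerance:
        closed = result.closed_structure
    attempts = 0
    while closed is None and attempts < max_attempts:
        attempts += 1
        perturbed = perturb_loop(work, tree, loop, mode="randomize", rng=rng)
        result = ccd_close(perturbed, tree, loop,
                           tolerance=closure_tolerance)
        if result.break_deviation < closure_tolerance:
            closed = result.closed_structure
    if closed is None:
        raise GraftError(
            f"scaffold loop failed to re-close around the anchor after "
            f"{max_attempts} perturbation attempts "
            f"(best deviation {result.break_deviation:.3f} A)")

    # -- superpose the graft onto the donor pose against the target ------
    grafted = [closed.residue(k) for k in occ_keys]
    R2, t2 = kabsch(_backbone_coords(anchor_res), _backbone_coords(grafted))
    for res in closed.residues(chain_id):
        for a in res.atoms:
            a.position = R2 @ a.position + t2

    out = Structure()
    used_chains = set(target.chain_ids)
    out_chain = chain_id
    while out_chain in used_chains:
        out_chain = chr(ord(out_chain) + 1)
    for cid in target.chain_ids:
        for r in target.residues(cid):
            out.add_residue(r.copy())
    for r in closed.residues(chain_id):
        r2 = r.copy()
        r2.chain_id = out_chain
        out.add_residue(r2)
    return out


def anchor_backbone_rmsd(result: Structure, partner_anchor: Structure,
                         occupied: ResidueSpan) -> float:
    """Backbone RMSD (no superposition) of the grafted anchor against the
    donor coordinates -- the graft fidelity measure."""
    grafted = select_span(result, occupied)
    donor = partner_anchor.residues()
    return rmsd(_backbone_coords(donor), _backbone_coords(grafted))
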