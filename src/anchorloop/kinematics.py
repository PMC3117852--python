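"""Anchored fold-tree kinematics.

A fold tree is a directed spanning structure over residues: peptide edges
propagate coordinates along the chain (forward or backward), jumps carry
rigid transforms between noncontiguous residues, and cutpoints are chain
positions where propagation stops.  The anchored tree makes the anchor
depend on the binding target through a jump and the scaffold depend on the
anchor through its loop, so that torsion changes inside the loop move the
entire scaffold as a rigid body while the anchor stays glued to the target.

Torsion changes are applied as exact axis rotations of the atoms downstream
of the changed bond; atoms not downstream are left bitwise untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .errors import RigidityError, StructureError, ValidationError
from .geometry import dihedral, kabsch, rotation_about_axis, wrap_angle
from .loops import LoopSpec, ResolvedLoop
from .structure import ResidueKey, ResidueSpan, Structure, select_span

TorsionName = str  # "phi" | "psi" | "omega"
TorsionId = tuple[ResidueKey, TorsionName]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValidationError("rotation must be proper (det = +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation",
                           np.asarray(self.translation, dtype=float))

    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other (apply ``other`` first)."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def rotation_angle(self) -> float:
        """Rotation magnitude in degrees."""
        c = (np.trace(self.rotation) - 1.0) / 2.0
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


@dataclass
class _Node:
    key: ResidueKey
    parent: ResidueKey | None
    conn: str  # "root" | "fwd" | "bwd" | "jump"
    order: int
    children: list[ResidueKey] = field(default_factory=list)


class AnchoredFoldTree:
    """Directed kinematic connectivity over the residues of a structure."""

    def __init__(self, structure: Structure):
        self._structure_chains = {c: [r.key for r in structure.residues(c)]
                                  for c in structure.chain_ids}
        self.nodes: dict[ResidueKey, _Node] = {}
        self.root: ResidueKey | None = None
        self.cutpoints: list[tuple[ResidueKey, ResidueKey]] = []
        self.mobile: set[TorsionId] = set()
        self.loops: list[ResolvedLoop] = []
        self.anchor_keys: tuple[ResidueKey, ...] = ()
        self.target_chain: str | None = None
        self.moving_chain: str | None = None
        self._subtree_cache: dict[ResidueKey, tuple[ResidueKey, ...]] = {}

    # -- construction (used by the build_* functions) ---------------------
    def _add(self, key, parent, conn):
        if key in self.nodes:
            raise ValidationError(f"fold tree visits residue {key} twice")
        self.nodes[key] = _Node(key, parent, conn, len(self.nodes))
        if parent is not None:
            self.nodes[parent].children.append(key)

    def _chain_keys(self, chain_id: str) -> list[ResidueKey]:
        return self._structure_chains[chain_id]

    def _index(self, key: ResidueKey) -> int:
        return self._chain_keys(key[0]).index(key)

    def chain_next(self, key: ResidueKey) -> ResidueKey | None:
        keys = self._chain_keys(key[0])
        i = keys.index(key) + 1
        return keys[i] if i < len(keys) else None

    def chain_prev(self, key: ResidueKey) -> ResidueKey | None:
        keys = self._chain_keys(key[0])
        i = keys.index(key) - 1
        return keys[i] if i >= 0 else None

    def _set_root(self, key):
        self.root = key
        self._add(key, None, "root")

    def _add_fwd(self, from_key, to_key):
        keys = self._chain_keys(from_key[0])
        i0, i1 = keys.index(from_key), keys.index(to_key)
        prev = from_key
        for i in range(i0 + 1, i1 + 1):
            self._add(keys[i], prev, "fwd")
            prev = keys[i]

    def _add_bwd(self, from_key, to_key):
        keys = self._chain_keys(from_key[0])
        i0, i1 = keys.index(from_key), keys.index(to_key)
        prev = from_key
        for i in range(i0 - 1, i1 - 1, -1):
            self._add(keys[i], prev, "bwd")
            prev = keys[i]

    def _add_jump(self, parent, child):
        self._add(child, parent, "jump")

    def _finish(self, structure: Structure):
        all_keys = {r.key for r in structure.residues()}
        missing = all_keys - set(self.nodes)
        if missing:
            raise ValidationError(
                f"fold tree does not reach residues: {sorted(missing)[:4]} ...")

    # -- queries ----------------------------------------------------------
    def is_mobile(self, key: ResidueKey, name: TorsionName) -> bool:
        return (key, name) in self.mobile

    def subtree(self, key: ResidueKey) -> tuple[ResidueKey, ...]:
        """The residue and all of its kinematic descendants."""
        if key not in self._subtree_cache:
            out = []
            stack = [key]
            while stack:
                k = stack.pop()
                out.append(k)
                stack.extend(self.nodes[k].children)
            self._subtree_cache[key] = tuple(out)
        return self._subtree_cache[key]

    def jump_children(self, key: ResidueKey) -> list[ResidueKey]:
        return [c for c in self.nodes[key].children
                if self.nodes[c].conn == "jump"]

    def edge_list(self) -> list[str]:
        """Printable edge list for debugging."""
        lines = [f"root {self.root}"]
        for key, node in self.nodes.items():
            if node.parent is not None:
                lines.append(f"{node.conn} {node.parent} -> {key}")
        for a, b in self.cutpoints:
            lines.append(f"cut {a} | {b}")
        return lines

    # -- torsion drive analysis -------------------------------------------
    def torsion_drive(self, key: ResidueKey, name: TorsionName):
        """What a torsion moves.

        Returns ``None`` when the torsion drives nothing in this tree
        (e.g. the psi of a cutpoint residue, which only positions the
        virtual continuation used during closure), else a tuple
        ``(axis, sign, residue_movers, partial)`` where ``axis`` is a pair
        of (key, atom-name), ``residue_movers`` is a list of residue keys
        whose atoms all move, and ``partial`` maps a residue key to the
        tuple of its atom names that stay put.
        """
        node = self.nodes[key]
        prev = self.chain_prev(key)
        nxt = self.chain_next(key)
        prev_is_child = (prev is not None and prev in self.nodes
                         and self.nodes[prev].parent == key
                         and self.nodes[prev].conn == "bwd")
        next_is_child = (nxt is not None and nxt in self.nodes
                         and self.nodes[nxt].parent == key
                         and self.nodes[nxt].conn == "fwd")

        if name == "phi":
            if prev is None:
                return None
            axis = ((key, "N"), (key, "CA"))
            if prev_is_child:
                return axis, -1.0, list(self.subtree(prev)), {}
            if node.conn == "fwd":
                movers = [key]
                partial = {key: ("N", "CA")}
                if next_is_child:
                    movers += list(self.subtree(nxt))
                for jc in self.jump_children(key):
                    movers += list(self.subtree(jc))
                return axis, +1.0, movers, partial
            return None
        if name == "psi":
            if nxt is None:
                return None
            axis = ((key, "CA"), (key, "C"))
            if next_is_child:
                return axis, +1.0, list(self.subtree(nxt)), {}
            if node.conn == "bwd":
                movers = [key]
                partial = {key: ("CA", "C", "O")}
                if prev_is_child:
                    movers += list(self.subtree(prev))
                for jc in self.jump_children(key):
                    movers += list(self.subtree(jc))
                return axis, -1.0, movers, partial
            return None
        if name == "omega":
            if nxt is None:
                return None
            axis = ((key, "C"), (nxt, "N"))
            if next_is_child:
                return axis, +1.0, list(self.subtree(nxt)), {nxt: ("N",)}
            if node.conn == "bwd":
                movers = [key]
                partial = {key: ("C",)}
                if prev_is_child:
                    movers += list(self.subtree(prev))
                for jc in self.jump_children(key):
                    movers += list(self.subtree(jc))
                return axis, -1.0, movers, partial
            return None
        raise ValidationError(f"unknown torsion {name!r}")


# -- torsion measurement ----------------------------------------------------

def measure_torsion(structure: Structure, tree_or_none, key: ResidueKey,
                    name: TorsionName) -> float | None:
    """Chain-based phi/psi/omega in degrees; None at chain termini."""
    chain = structure.residues(key[0])
    idx = structure.chain_index(key)
    r = chain[idx]
    prev_r = chain[idx - 1] if idx > 0 else None
    next_r = chain[idx + 1] if idx + 1 < len(chain) else None
    try:
        if name == "phi":
            if prev_r is None:
                return None
            return dihedral(prev_r.atom("C").position, r.atom("N").position,
                            r.atom("CA").position, r.atom("C").position)
        if name == "psi":
            if next_r is None:
                return None
            return dihedral(r.atom("N").position, r.atom("CA").position,
                            r.atom("C").position, next_r.atom("N").position)
        if name == "omega":
            if next_r is None:
                return None
            return dihedral(r.atom("CA").position, r.atom("C").position,
                            next_r.atom("N").position, next_r.atom("CA").position)
    except StructureError:
        return None
    raise ValidationError(f"unknown torsion {name!r}")


def backbone_torsions(structure: Structure, keys: Iterable[ResidueKey] | None = None
                      ) -> dict[ResidueKey, dict[str, float | None]]:
    """phi/psi/omega for the requested residues (all residues by default)."""
    if keys is None:
        keys = [r.key for r in structure.residues()]
    return {k: {n: measure_torsion(structure, None, k, n)
                for n in ("phi", "psi", "omega")} for k in keys}


# -- rotation application ----------------------------------------------------

def _materialize_movers(structure, residue_movers, partial):
    atoms = []
    for rk in residue_movers:
        skip = partial.get(rk, ())
        for a in structure.residue(rk).atoms:
            if a.name not in skip:
                atoms.append(a)
    return atoms


def rotate_torsion(structure: Structure, tree: AnchoredFoldTree,
                   key: ResidueKey, name: TorsionName, delta: float) -> bool:
    """Rotate one torsion in place by ``delta`` degrees.

    Returns False (and does nothing) when the torsion drives no atoms in
    this tree.
    """
    drive = tree.torsion_drive(key, name)
    if drive is None:
        return False
    (ok, oa), (bk, ba) = drive[0]
    sign, residue_movers, partial = drive[1], drive[2], drive[3]
    origin = structure.residue(ok).atom(oa).position
    axis = structure.residue(bk).atom(ba).position - origin
    R, t = rotation_about_axis(origin, axis, sign * delta)
    for atom in _materialize_movers(structure, residue_movers, partial):
        atom.position = R @ atom.position + t
    return True


def apply_torsions(structure: Structure, tree: AnchoredFoldTree,
                   torsions: Mapping[TorsionId, float],
                   tolerance: float = 1e-9) -> Structure:
    """Return a copy of ``structure`` with the given backbone torsions set.

    Torsion values are absolute targets in degrees.  Changing a torsion at
    a rigid (anchor / core) position raises :class:`RigidityError`; atoms
    not downstream of any changed torsion are bitwise-unchanged.
    """
    out = structure.copy()
    intra_rank = {"fwd": {"phi": 0, "psi": 1, "omega": 2},
                  "bwd": {"omega": 0, "psi": 1, "phi": 2}}

    def sort_key(item):
        (key, name), _ = item
        node = tree.nodes[key]
        conn = "bwd" if node.conn == "bwd" else "fwd"
        return (node.order, intra_rank[conn][name])

    for (key, name), target in sorted(torsions.items(), key=sort_key):
        current = measure_torsion(out, tree, key, name)
        if current is None:
            continue
        delta = wrap_angle(target - current)
        if abs(delta) <= tolerance:
            continue
        if not tree.is_mobile(key, name):
            raise RigidityError(
                f"torsion {name} of rigid position {key} cannot change")
        rotate_torsion(out, tree, key, name, delta)
    return out


# -- tree builders -----------------------------------------------------------

def _check_loop_termini(structure, res: ResolvedLoop):
    chain = [r.key for r in structure.residues(res.chain_id)]
    first, last = res.loop_keys[0], res.loop_keys[-1]
    if chain.index(first) == 0 or chain.index(last) == len(chain) - 1:
        raise ValidationError(
            f"loop {res.spec.loop} touches a chain terminus; at least one "
            "rigid residue is required on each side")


def _mark_mobile(tree: AnchoredFoldTree, res: ResolvedLoop,
                 include_anchor: bool):
    keys = res.loop_keys if include_anchor else res.mobile_keys
    for k in keys:
        for n in ("phi", "psi", "omega"):
            tree.mobile.add((k, n))


def _add_fwd_with_loops(tree, structure, start_key, end_key, loops):
    """Forward peptide run with embedded standard (non-anchored) loops."""
    chain_keys = tree._chain_keys(start_key[0])
    i0, i1 = chain_keys.index(start_key), chain_keys.index(end_key)
    cur = start_key
    for res in sorted(loops, key=lambda r: chain_keys.index(r.loop_keys[0])):
        ls = chain_keys.index(res.loop_keys[0])
        le = chain_keys.index(res.loop_keys[-1])
        if not (i0 < ls and le < i1):
            raise ValidationError(
                f"secondary loop {res.spec.loop} not strictly inside its segment")
        pre = chain_keys[ls - 1]
        post = chain_keys[le + 1]
        cut = res.cut_key
        cut_next = tree.chain_next(cut)
        tree._add_fwd(cur, pre)
        tree._add_fwd(pre, cut)
        tree._add_jump(pre, post)
        if post != cut_next:
            tree._add_bwd(post, cut_next)
        tree.cutpoints.append((cut, cut_next))
        cur = post
    tree._add_fwd(cur, end_key)


def _partition_secondary(structure, tree, secondary):
    """Split standard loops into (target-chain, scaffold N-side, scaffold
    C-side) groups relative to the primary anchored loop."""
    groups = {"target": [], "nside": [], "cside": []}
    primary = tree.loops[0]
    chain_keys = tree._chain_keys(primary.chain_id)
    loop_lo = chain_keys.index(primary.loop_keys[0])
    loop_hi = chain_keys.index(primary.loop_keys[-1])
    for res in secondary:
        if res.chain_id == tree.target_chain:
            groups["target"].append(res)
        elif res.chain_id == primary.chain_id:
            lo = chain_keys.index(res.loop_keys[0])
            hi = chain_keys.index(res.loop_keys[-1])
            if hi < loop_lo:
                groups["nside"].append(res)
            elif lo > loop_hi:
                groups["cside"].append(res)
            else:
                raise ValidationError(
                    "secondary loop overlaps the anchored loop")
        else:
            raise ValidationError(
                f"secondary loop chain {res.chain_id} is in neither partner")
    return groups


def build_anchored_fold_tree(
    structure: Structure,
    loop_specs: LoopSpec | Iterable[LoopSpec],
    allow_anchor_motion: bool = False,
    validate: bool = True,
) -> AnchoredFoldTree:
    """Build the anchored fold tree (one anchored loop plus optional
    standard secondary loops).

    The anchor is parented on the nearest target residue through a rigid
    jump; the scaffold N-side is built backward from the anchor, the
    scaffold C-side hangs off the N-side core through a rigid intra-scaffold
    jump, and the C-terminal half of the loop is built backward from the
    scaffold toward the cutpoint.
    """
    if isinstance(loop_specs, LoopSpec):
        loop_specs = [loop_specs]
    loop_specs = list(loop_specs)
    resolved = [s.resolve(structure) for s in loop_specs]
    anchored = [r for r in resolved if r.anchor_keys]
    if len(anchored) != 1:
        raise ValidationError("exactly one anchored loop is required")
    primary = anchored[0]
    secondary = [r for r in resolved if r is not primary]

    scaffold = primary.chain_id
    targets = [c for c in structure.chain_ids if c != scaffold]
    if not targets:
        raise ValidationError("anchored fold tree requires a target chain")
    target = targets[0]

    tree = AnchoredFoldTree(structure)
    tree.loops = [primary] + secondary
    tree.target_chain = target
    tree.moving_chain = scaffold
    tree.anchor_keys = primary.anchor_keys

    if validate:
        for res in resolved:
            _check_loop_termini(structure, res)
        if (primary.anchor_keys[0] == primary.loop_keys[0]
                or primary.anchor_keys[-1] == primary.loop_keys[-1]):
            raise ValidationError(
                "anchor at a loop terminus leaves too few mobile residues "
                "on the cutpoint side of the loop")

    chain_s = tree._chain_keys(scaffold)
    a_start = primary.anchor_keys[0]
    loop_stop = primary.loop_keys[-1]
    cut = primary.cut_key
    cut_next = tree.chain_next(cut)
    post_loop = chain_s[chain_s.index(loop_stop) + 1]

    groups = _partition_secondary(structure, tree, secondary)

    # target chain
    t_keys = tree._chain_keys(target)
    tree._set_root(t_keys[0])
    _add_fwd_with_loops(tree, structure, t_keys[0], t_keys[-1],
                        groups["target"])

    # jump target -> anchor (nearest CA, deterministic)
    a_ca = structure.residue(a_start).atom("CA").position
    jump_parent = min(
        t_keys,
        key=lambda k: (float(np.linalg.norm(
            structure.residue(k).atom("CA").position - a_ca)), k),
    )
    tree._add_jump(jump_parent, a_start)

    # scaffold N side, built backward from the anchor
    bwd_loops = groups["nside"]
    if bwd_loops:
        _add_bwd_with_loops(tree, structure, a_start, chain_s[0], bwd_loops)
    else:
        tree._add_bwd(a_start, chain_s[0])
    # anchor interior and post-anchor residues up to the cutpoint
    tree._add_fwd(a_start, cut)
    # intra-scaffold rigid jump keeps the scaffold one rigid body
    tree._add_jump(chain_s[0], post_loop)
    if post_loop != cut_next:
        tree._add_bwd(post_loop, cut_next)
    _add_fwd_with_loops(tree, structure, post_loop, chain_s[-1],
                        groups["cside"])
    tree.cutpoints.insert(0, (cut, cut_next))

    tree._finish(structure)
    _mark_mobile(tree, primary, include_anchor=allow_anchor_motion)
    for res in secondary:
        _mark_mobile(tree, res, include_anchor=True)
    return tree


def _add_bwd_with_loops(tree, structure, start_key, end_key, loops):
    """Backward peptide run with embedded standard loops (mirror image of
    :func:`_add_fwd_with_loops`)."""
    chain_keys = tree._chain_keys(start_key[0])
    i0, i1 = chain_keys.index(start_key), chain_keys.index(end_key)
    cur = start_key
    for res in sorted(loops, key=lambda r: -chain_keys.index(r.loop_keys[-1])):
        ls = chain_keys.index(res.loop_keys[0])
        le = chain_keys.index(res.loop_keys[-1])
        if not (i1 < ls and le < i0):
            raise ValidationError(
                f"secondary loop {res.spec.loop} not strictly inside its segment")
        pre = chain_keys[ls - 1]
        post = chain_keys[le + 1]
        cut = res.cut_key
        cut_next = tree.chain_next(cut)
        tree._add_bwd(cur, post)
        if post != cut_next:
            tree._add_bwd(post, cut_next)
        tree._add_jump(post, pre)
        tree._add_fwd(pre, cut)
        tree.cutpoints.append((cut, cut_next))
        cur = pre
    tree._add_bwd(cur, end_key)


def build_standard_fold_tree(
    structure: Structure,
    loop_specs: Iterable[LoopSpec],
    anchor_mobile: bool = True,
) -> AnchoredFoldTree:
    """Standard (non-anchored) loop fold tree: each chain is built forward
    from its first residue, chains are connected by rigid jumps from the
    root, and each loop gets the usual jump-across + mid-loop cutpoint
    treatment.  Used for the displaced-anchor experiment, where the anchor
    must be free to move with its loop."""
    resolved = [s.resolve(structure) for s in loop_specs]
    tree = AnchoredFoldTree(structure)
    tree.loops = list(resolved)
    by_chain: dict[str, list[ResolvedLoop]] = {}
    for r in resolved:
        _check_loop_termini(structure, r)
        by_chain.setdefault(r.chain_id, []).append(r)
        if r.anchor_keys:
            tree.anchor_keys = tuple(tree.anchor_keys) + tuple(r.anchor_keys)
            tree.moving_chain = r.chain_id

    chain_ids = structure.chain_ids
    tree.target_chain = next(
        (c for c in chain_ids if c != tree.moving_chain), chain_ids[0])
    first = chain_ids[0]
    f_keys = tree._chain_keys(first)
    tree._set_root(f_keys[0])
    _add_fwd_with_loops(tree, structure, f_keys[0], f_keys[-1],
                        by_chain.get(first, []))
    for cid in chain_ids[1:]:
        keys = tree._chain_keys(cid)
        tree._add_jump(tree.root, keys[0])
        _add_fwd_with_loops(tree, structure, keys[0], keys[-1],
                            by_chain.get(cid, []))
    tree._finish(structure)
    for res in resolved:
        _mark_mobile(tree, res, include_anchor=anchor_mobile)
    return tree


def build_graft_tree(structure: Structure, loop_spec: LoopSpec,
                     validate: bool = True) -> AnchoredFoldTree:
    """Fold tree for closing a scaffold loop around a freshly grafted,
    rigid anchor: the anchor is the root, so loop closure moves the
    scaffold (as one rigid body, via the intra-scaffold jump) around it."""
    primary = loop_spec.resolve(structure)
    if not primary.anchor_keys:
        raise ValidationError("graft tree requires an anchor span")
    tree = AnchoredFoldTree(structure)
    tree.loops = [primary]
    tree.anchor_keys = primary.anchor_keys
    tree.moving_chain = primary.chain_id
    if validate:
        _check_loop_termini(structure, primary)

    chain_s = tree._chain_keys(primary.chain_id)
    a_start = primary.anchor_keys[0]
    loop_stop = primary.loop_keys[-1]
    cut = primary.cut_key
    cut_next = tree.chain_next(cut)
    post_loop = chain_s[chain_s.index(loop_stop) + 1]

    tree._set_root(a_start)
    tree._add_bwd(a_start, chain_s[0])
    tree._add_fwd(a_start, cut)
    tree._add_jump(chain_s[0], post_loop)
    if post_loop != cut_next:
        tree._add_bwd(post_loop, cut_next)
    tree._add_fwd(post_loop, chain_s[-1])
    tree.cutpoints.append((cut, cut_next))
    # other chains (if any) hang rigidly off the root
    for cid in structure.chain_ids:
        if cid == primary.chain_id:
            continue
        keys = tree._chain_keys(cid)
        tree._add_jump(tree.root, keys[0])
        tree._add_fwd(keys[0], keys[-1])
    tree._finish(structure)
    _mark_mobile(tree, primary, include_anchor=False)
    return tree


# -- rigid-body extraction ---------------------------------------------------

def rigid_transform_between(reference: Structure, model: Structure,
                            span: ResidueSpan) -> RigidTransform:
    """Least-squares rigid transform mapping the reference span's CA atoms
    onto the model's."""
    ref_res = select_span(reference, span)
    mod_res = select_span(model, span)
    if [r.key for r in ref_res] != [r.key for r in mod_res]:
        raise ValidationError("span residues differ between structures")
    ref = np.array([r.atom("CA").position for r in ref_res])
    mod = np.array([r.atom("CA").position for r in mod_res])
    if len(ref) < 3:
        raise ValidationError("need at least 3 CA atoms for a rigid fit")
    R, t = kabsch(mod, ref)
    return RigidTransform(R, t)


def scaffold_core_keys(tree: AnchoredFoldTree, structure: Structure
                       ) -> list[ResidueKey]:
    """Scaffold residues outside every mobile loop."""
    loop_keys = {k for res in tree.loops for k in res.loop_keys}
    return [r.key for r in structure.residues(tree.moving_chain)
            if r.key not in loop_keys]
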