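"""Loop perturbation and anchor-aware closure.

Two closure algorithms are provided.  CCD (cyclic coordinate descent)
iterates over the mobile phi/psi torsions of a broken loop, each step
choosing the analytic rotation that best superposes three virtual
ideal-geometry continuation atoms onto their real counterparts across the
cutpoint.  KIC (kinematic closure) resamples the non-pivot torsions from
the Ramachandran model and solves for the phi/psi of three pivot residues
so the chain is exactly continuous at the cutpoint; the solver here drives
the four closure conditions (peptide bond length, the two flanking bond
angles, trans omega) to zero numerically and multi-starts to enumerate
distinct solutions.

Anchor residues are excluded from perturbation, from CCD's torsion sweep
and from the KIC pivot/non-pivot sets: the anchor acts as a rigid segment
inside the loop and is never touched.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

from .errors import (ClosureError, ConfigurationError, KICNoSolution,
                     ValidationError)
from .geometry import (ANGLE_C_N_CA, ANGLE_CA_C_N, BOND_C_N, BOND_N_CA,
                       bond_angle, dihedral, place_atom, rotation_about_axis,
                       wrap_angle)
from .kinematics import (AnchoredFoldTree, apply_torsions, measure_torsion)
from .loops import ResolvedLoop
from .ramachandran import RamachandranModel, default_model
from .structure import Structure


@dataclass
class ClosureResult:
    closed_structure: Structure
    break_deviation: float
    iterations_used: int
    solution_count: int = 1
    #: KIC only: every distinct converged pivot-torsion vector, as a list of
    #: {(residue, torsion): degrees} mappings (the applied one included)
    solutions: list | None = None


def _loop_or_default(tree: AnchoredFoldTree, loop: ResolvedLoop | None
                     ) -> ResolvedLoop:
    if loop is not None:
        return loop
    if not tree.loops:
        raise ValidationError("fold tree has no loops")
    return tree.loops[0]


# ---------------------------------------------------------------------------
# perturbers
# ---------------------------------------------------------------------------

def perturb_loop(
    structure: Structure,
    tree: AnchoredFoldTree,
    loop: ResolvedLoop | None = None,
    mode: str = "randomize",
    magnitude: float = 5.0,
    rng: np.random.Generator | None = None,
    fragments: "FragmentStore | None" = None,
    rama: RamachandranModel | None = None,
) -> Structure:
    """Perturb the mobile, non-anchor torsions of a loop.

    ``randomize`` draws fresh basin samples for every mobile residue;
    ``small_move`` adds uniform noise within +-magnitude degrees and clamps
    the result back into the Ramachandran basins; ``fragment`` replaces a
    3-residue window of torsions with a stored fragment.
    """
    loop = _loop_or_default(tree, loop)
    rama = rama or default_model()
    rng = rng if rng is not None else np.random.default_rng(0)
    mobile = [k for k in loop.mobile_keys if tree.is_mobile(k, "phi")]
    overrides: dict = {}

    if mode == "randomize":
        for k in mobile:
            phi, psi = rama.sample(structure.residue(k).aa_type, rng)
            overrides[(k, "phi")] = phi
            overrides[(k, "psi")] = psi
    elif mode == "small_move":
        if magnitude == 0:
            return structure.copy()
        for k in mobile:
            aa = structure.residue(k).aa_type
            phi = measure_torsion(structure, tree, k, "phi")
            psi = measure_torsion(structure, tree, k, "psi")
            if phi is None or psi is None:
                continue
            phi = phi + rng.uniform(-magnitude, magnitude)
            psi = psi + rng.uniform(-magnitude, magnitude)
            phi, psi = rama.clamp(aa, wrap_angle(phi), wrap_angle(psi))
            overrides[(k, "phi")] = phi
            overrides[(k, "psi")] = psi
    elif mode == "fragment":
        if fragments is None or len(fragments) == 0:
            raise ConfigurationError("fragment perturbation needs a "
                                     "non-empty fragment store")
        windows = _mobile_windows(tree, loop)
        if not windows:
            raise ConfigurationError(
                "no 3-residue window of consecutive mobile residues")
        window = windows[rng.integers(len(windows))]
        frag = fragments.windows[rng.integers(len(fragments))]
        for k, (phi, psi, omega) in zip(window, frag):
            overrides[(k, "phi")] = phi
            overrides[(k, "psi")] = psi
            overrides[(k, "omega")] = omega
    else:
        raise ValidationError(f"unknown perturbation mode {mode!r}")

    return apply_torsions(structure, tree, overrides)


def _mobile_windows(tree: AnchoredFoldTree, loop: ResolvedLoop):
    """All chain-consecutive 3-residue windows of mobile loop residues."""
    mobile = set(loop.mobile_keys)
    out = []
    keys = loop.loop_keys
    for i in range(len(keys) - 2):
        w = keys[i:i + 3]
        if all(k in mobile for k in w):
            out.append(tuple(w))
    return out


# ---------------------------------------------------------------------------
# CCD
# ---------------------------------------------------------------------------

class _Break:
    """Cutpoint bookkeeping: real atoms plus the virtual ideal-geometry
    continuation atoms on either side of the break."""

    def __init__(self, structure: Structure, tree: AnchoredFoldTree,
                 loop: ResolvedLoop):
        self.c = loop.cut_key
        self.d = tree.chain_next(self.c)
        if self.d is None:
            raise ClosureError("cutpoint at chain terminus")
        self.psi_v = measure_torsion(structure, tree, self.c, "psi")
        self.phi_v = measure_torsion(structure, tree, self.d, "phi")

    def points(self, structure: Structure):
        rc = structure.residue(self.c)
        rd = structure.residue(self.d)
        Nc, CAc, Cc = (rc.atom(n).position for n in ("N", "CA", "C"))
        Nd, CAd, Cd = (rd.atom(n).position for n in ("N", "CA", "C"))
        vN = place_atom(Nc, CAc, Cc, BOND_C_N, ANGLE_CA_C_N, self.psi_v)
        vCA = place_atom(CAc, Cc, vN, BOND_N_CA, ANGLE_C_N_CA, 180.0)
        vC = place_atom(Cd, CAd, Nd, BOND_C_N, ANGLE_C_N_CA, self.phi_v)
        # moving/fixed pairs: (real C | virtual C), (virtual N | real N),
        # (virtual CA | real CA); first member is on the N side of the break
        return [(Cc, vC), (vN, Nd), (vCA, CAd)]

    def deviation(self, structure: Structure) -> float:
        return float(np.sqrt(sum(
            np.sum((a - b) ** 2) for a, b in self.points(structure))))


def chainbreak_deviation(structure: Structure, tree: AnchoredFoldTree,
                         loop: ResolvedLoop | None = None) -> float:
    """Virtual-pair break deviation of a loop's cutpoint (Angstrom)."""
    loop = _loop_or_default(tree, loop)
    return _Break(structure, tree, loop).deviation(structure)


def _ccd_moved_break_atoms(tree, drive, brk):
    """Which of the six break points move under a torsion drive."""
    _, _, movers, partial = drive
    mover_set = set(movers)

    def moved(key, atom):
        return key in mover_set and atom not in partial.get(key, ())

    n_side = []
    if moved(brk.c, "C"):
        n_side.append(0)  # real C moves; virtuals vN/vCA ride along
    if any(moved(brk.c, a) for a in ("N", "CA", "C")):
        n_side.extend([1, 2])
    c_side = []
    if any(moved(brk.d, a) for a in ("N", "CA", "C")):
        c_side.append(0)  # virtual C rides the C-side stub
    if moved(brk.d, "N"):
        c_side.append(1)
    if moved(brk.d, "CA"):
        c_side.append(2)
    return sorted(set(n_side)), sorted(set(c_side))


def ccd_close(
    structure: Structure,
    tree: AnchoredFoldTree,
    loop: ResolvedLoop | None = None,
    max_sweeps: int = 100,
    tolerance: float = 0.1,
    per_move_cap: float | None = None,
    torsion_subset: list | None = None,
) -> ClosureResult:
    """Cyclic coordinate descent closure of one loop's cutpoint.

    Sweeps the mobile non-anchor phi/psi torsions in chain order; each step
    applies the closed-form rotation minimizing the summed squared
    distances between the three virtual/real cross-cutpoint atom pairs
    (optionally capped at ``per_move_cap`` degrees for refinement-phase
    moves).  The break deviation is non-increasing across steps.
    """
    loop = _loop_or_default(tree, loop)
    work = structure.copy()
    brk = _Break(work, tree, loop)

    candidates = torsion_subset
    if candidates is None:
        candidates = [(k, n) for k in loop.mobile_keys for n in ("phi", "psi")]
    # classify each candidate once (tree topology is static)
    plans = []
    for key, name in candidates:
        if not tree.is_mobile(key, name):
            continue
        if (key, name) == (brk.c, "psi"):
            plans.append(("virt_psi", None))
            continue
        if (key, name) == (brk.d, "phi"):
            plans.append(("virt_phi", None))
            continue
        drive = tree.torsion_drive(key, name)
        if drive is None:
            continue
        n_side, c_side = _ccd_moved_break_atoms(tree, drive, brk)
        if n_side and c_side:
            continue  # moves both sides rigidly: no effect on the break
        if not n_side and not c_side:
            continue
        plans.append(("atoms", (key, name, drive, n_side, c_side)))
    if not plans:
        raise ClosureError("no mobile torsion can move the chainbreak")

    if max_sweeps < 1 or brk.deviation(work) < tolerance:
        return ClosureResult(work, brk.deviation(work), 0)

    sweeps = 0
    for sweep in range(max_sweeps):
        sweeps = sweep + 1
        # alternate sweep direction: helps escape shallow CCD stalls
        ordered = plans if sweep % 2 == 0 else plans[::-1]
        for kind, payload in ordered:
            pairs = brk.points(work)
            if kind == "virt_psi":
                rc = work.residue(brk.c)
                origin = rc.atom("CA").position
                axis = rc.atom("C").position - origin
                moving = [pairs[1][0], pairs[2][0]]
                fixed = [pairs[1][1], pairs[2][1]]
                theta = _ccd_angle(origin, axis, moving, fixed, per_move_cap)
                brk.psi_v = wrap_angle(brk.psi_v + theta)
            elif kind == "virt_phi":
                rd = work.residue(brk.d)
                origin = rd.atom("N").position
                axis = rd.atom("CA").position - origin
                moving = [pairs[0][1]]
                fixed = [pairs[0][0]]
                theta = _ccd_angle(origin, axis, moving, fixed, per_move_cap)
                brk.phi_v = wrap_angle(brk.phi_v - theta)
            else:
                key, name, drive, n_side, c_side = payload
                (ok, oa), (bk, ba) = drive[0]
                origin = work.residue(ok).atom(oa).position
                axis = work.residue(bk).atom(ba).position - origin
                if n_side:
                    moving = [pairs[i][0] for i in n_side]
                    fixed = [pairs[i][1] for i in n_side]
                else:
                    moving = [pairs[i][1] for i in c_side]
                    fixed = [pairs[i][0] for i in c_side]
                theta = _ccd_angle(origin, axis, moving, fixed, per_move_cap)
                if abs(theta) > 1e-12:
                    R, t = rotation_about_axis(origin, axis, theta)
                    from .kinematics import _materialize_movers
                    for atom in _materialize_movers(work, drive[2], drive[3]):
                        atom.position = R @ atom.position + t
        if brk.deviation(work) < tolerance:
            break
    dev = brk.deviation(work)
    if dev >= tolerance and per_move_cap is None and len(loop.mobile_keys) >= 3:
        # CCD can stall in a shallow local minimum of its point-matching
        # objective; polish by solving the three default pivot torsions
        # exactly from the stalled conformation
        polished = _pivot_polish(work, tree, loop)
        if polished is not None:
            pol_dev = _Break(polished, tree, loop).deviation(polished)
            if pol_dev < dev:
                work, dev = polished, pol_dev
    return ClosureResult(work, dev, sweeps)


def _pivot_polish(structure, tree, loop):
    """Exact-closure refinement of a pivot-torsion triple starting from
    the current conformation; several deterministic triples are tried.
    Returns None when no solve succeeds."""
    mobile = list(loop.mobile_keys)
    n = len(mobile)
    triples = [tuple(default_pivots(loop))]
    if n > 3:
        triples.append((mobile[0], mobile[1], mobile[-1]))
        triples.append((mobile[0], mobile[-2], mobile[-1]))
    if n > 4:
        triples.append((mobile[1], mobile[n // 2], mobile[-2]))
    for pivots in triples:
        ws = _PivotWorkspace(structure, tree, loop, list(pivots))
        x0 = ws.start[np.argsort(ws.x_order, kind="stable")]
        res = least_squares(ws.residuals, np.asarray(x0, dtype=float),
                            method="trf", xtol=1e-14, ftol=1e-14,
                            gtol=1e-14, max_nfev=100)
        if np.linalg.norm(res.fun) > 1e-6:
            continue
        overrides = {}
        for i, p in enumerate(pivots):
            overrides[(p, "phi")] = float(wrap_angle(res.x[2 * i]))
            overrides[(p, "psi")] = float(wrap_angle(res.x[2 * i + 1]))
        return apply_torsions(structure, tree, overrides)
    return None


def _ccd_angle(origin, axis, moving, fixed, cap):
    """Closed-form CCD rotation angle (degrees) about (origin, axis) that
    minimizes sum |fixed_k - rotated(moving_k)|^2."""
    u = axis / np.linalg.norm(axis)
    a = b = 0.0
    for M, F in zip(moving, fixed):
        center = origin + np.dot(M - origin, u) * u
        r = M - center
        s = np.cross(u, r)
        f = F - center
        a += float(np.dot(f, r))
        b += float(np.dot(f, s))
    if a == 0.0 and b == 0.0:
        return 0.0
    theta = float(np.degrees(np.arctan2(b, a)))
    if cap is not None:
        theta = float(np.clip(theta, -cap, cap))
    return theta


# ---------------------------------------------------------------------------
# KIC
# ---------------------------------------------------------------------------

def default_pivots(loop: ResolvedLoop) -> list:
    """First, middle-most and last mobile non-anchor residues."""
    mobile = list(loop.mobile_keys)
    if len(mobile) < 3:
        raise ValidationError(
            "an absolute minimum of three mobile positions is required "
            "for kinematic closure")
    return [mobile[0], mobile[len(mobile) // 2], mobile[-1]]


class _PivotWorkspace:
    """Positions of the four real break atoms as a function of the six
    pivot torsions, via incremental axis rotations on a small tracked
    point set."""

    def __init__(self, structure, tree, loop, pivots):
        brk = _Break(structure, tree, loop)
        self.c, self.d = brk.c, brk.d
        tracked = [(self.c, "CA"), (self.c, "C"), (self.d, "N"), (self.d, "CA")]
        torsions = []
        for p in pivots:
            for name in ("phi", "psi"):
                torsions.append((p, name))
            for a in ("N", "CA", "C"):
                if (p, a) not in tracked:
                    tracked.append((p, a))
        self.tracked = tracked
        self.t_index = {t: i for i, t in enumerate(tracked)}
        self.base = np.array(
            [structure.residue(k).atom(a).position for k, a in tracked])

        intra = {"fwd": {"phi": 0, "psi": 1}, "bwd": {"psi": 0, "phi": 1}}
        entries = []
        for key, name in torsions:
            start = measure_torsion(structure, tree, key, name)
            drive = tree.torsion_drive(key, name)
            node = tree.nodes[key]
            conn = "bwd" if node.conn == "bwd" else "fwd"
            rank = (node.order, intra[conn][name])
            if drive is None:
                entries.append((rank, None, None, None, start))
                continue
            (ok, oa), (bk, ba) = drive[0]
            sign, movers, partial = drive[1], drive[2], drive[3]
            mover_set = set(movers)
            moved_idx = [i for i, (k, a) in enumerate(tracked)
                         if k in mover_set and a not in partial.get(k, ())]
            axis_idx = (self._pt(structure, ok, oa), self._pt(structure, bk, ba))
            entries.append((rank, axis_idx, sign, np.array(moved_idx, dtype=int),
                            start))
        order = sorted(range(len(entries)), key=lambda i: entries[i][0])
        self.entries = [entries[i] for i in order]
        self.x_order = list(order)  # map entry -> x component
        self.start = np.array([e[4] for e in self.entries])

    def _pt(self, structure, key, atom):
        if (key, atom) not in self.t_index:
            self.t_index[(key, atom)] = len(self.tracked)
            self.tracked.append((key, atom))
            pos = structure.residue(key).atom(atom).position
            self.base = np.vstack([self.base, pos[None, :]])
        return self.t_index[(key, atom)]

    def positions(self, x: np.ndarray) -> np.ndarray:
        pts = self.base.copy()
        for (rank, axis_idx, sign, moved, start), xi in zip(
                self.entries, x[self.x_order]):
            if axis_idx is None or len(moved) == 0:
                continue
            delta = wrap_angle(float(xi) - start)
            if abs(delta) < 1e-13:
                continue
            origin = pts[axis_idx[0]]
            axis = pts[axis_idx[1]] - origin
            R, t = rotation_about_axis(origin, axis, sign * delta)
            pts[moved] = pts[moved] @ R.T + t
        return pts

    def residuals(self, x: np.ndarray) -> np.ndarray:
        pts = self.positions(x)
        CAc = pts[self.t_index[(self.c, "CA")]]
        Cc = pts[self.t_index[(self.c, "C")]]
        Nd = pts[self.t_index[(self.d, "N")]]
        CAd = pts[self.t_index[(self.d, "CA")]]
        scale = BOND_C_N  # express angle errors on an Angstrom-like scale
        return np.array([
            float(np.linalg.norm(Cc - Nd)) - BOND_C_N,
            np.deg2rad(bond_angle(CAc, Cc, Nd) - ANGLE_CA_C_N) * scale,
            np.deg2rad(bond_angle(Cc, Nd, CAd) - ANGLE_C_N_CA) * scale,
            np.deg2rad(wrap_angle(dihedral(CAc, Cc, Nd, CAd) - 180.0)) * scale,
        ])


def kic_close(
    structure: Structure,
    tree: AnchoredFoldTree,
    loop: ResolvedLoop | None = None,
    pivots: list | None = None,
    rng: np.random.Generator | None = None,
    resample_nonpivots: bool = True,
    random_pivots: bool = False,
    n_starts: int = 4,
    rama: RamachandranModel | None = None,
) -> ClosureResult:
    """Kinematic closure: solve pivot phi/psi for exact cutpoint continuity.

    Raises :class:`KICNoSolution` (a retry signal -- the caller resamples)
    when no start converges to a geometrically valid solution.
    """
    loop = _loop_or_default(tree, loop)
    rama = rama or default_model()
    rng = rng if rng is not None else np.random.default_rng(0)
    mobile = list(loop.mobile_keys)
    if len(mobile) < 3:
        raise ValidationError(
            "an absolute minimum of three mobile positions is required "
            "for kinematic closure")
    anchor_set = set(loop.anchor_keys)
    if pivots is None:
        if random_pivots and len(mobile) > 3:
            idx = sorted(rng.choice(len(mobile), size=3, replace=False))
            pivots = [mobile[i] for i in idx]
        else:
            pivots = default_pivots(loop)
    pivots = list(pivots)
    if len(pivots) != 3:
        raise ValidationError("exactly three pivot residues are required")
    for p in pivots:
        if p in anchor_set:
            raise ValidationError(
                "anchor positions are excluded from the allowable pivots")
        if p not in mobile:
            raise ValidationError(f"pivot {p} is not a mobile loop residue")

    # resample non-pivot torsions from the Ramachandran model
    pivot_set = set(pivots)
    if resample_nonpivots:
        overrides = {}
        for k in mobile:
            if k in pivot_set:
                continue
            phi, psi = rama.sample(structure.residue(k).aa_type, rng)
            overrides[(k, "phi")] = phi
            overrides[(k, "psi")] = psi
        work = apply_torsions(structure, tree, overrides)
    else:
        work = structure.copy()

    ws = _PivotWorkspace(work, tree, loop, pivots)
    x_current = ws.start[np.argsort(ws.x_order, kind="stable")]
    # ws.start is in entry order; map back to the (pivot, phi/psi) order
    x0s = [x_current]
    for _ in range(n_starts - 1):
        draw = []
        for p in pivots:
            phi, psi = rama.sample(work.residue(p).aa_type, rng)
            draw.extend([phi, psi])
        x0s.append(np.array(draw))

    solutions = []
    nfev = 0
    for x0 in x0s:
        res = least_squares(ws.residuals, np.asarray(x0, dtype=float),
                            method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14,
                            max_nfev=100)
        nfev += res.nfev
        if np.linalg.norm(res.fun) > 1e-6:
            continue
        x = np.array([wrap_angle(v) for v in res.x])
        if any(np.max(np.abs([wrap_angle(a - b) for a, b in zip(x, s)])) < 0.5
               for s in solutions):
            continue
        solutions.append(x)
    if not solutions:
        raise KICNoSolution(
            "no real closure solution for the sampled non-pivot torsions")

    chosen = solutions[int(rng.integers(len(solutions)))]
    overrides = {}
    for i, p in enumerate(pivots):
        overrides[(p, "phi")] = float(chosen[2 * i])
        overrides[(p, "psi")] = float(chosen[2 * i + 1])
    closed = apply_torsions(work, tree, overrides)
    dev = float(np.linalg.norm(ws.residuals(np.asarray(chosen, dtype=float))))
    as_maps = [
        {(p, n): float(x[2 * i + j])
         for i, p in enumerate(pivots) for j, n in enumerate(("phi", "psi"))}
        for x in solutions
    ]
    return ClosureResult(closed, dev, nfev, solution_count=len(solutions),
                         solutions=as_maps)


# ---------------------------------------------------------------------------
# fragment store
# ---------------------------------------------------------------------------

class FragmentStore:
    """Sequence-nonspecific 3-residue (phi, psi, omega) windows."""

    def __init__(self, windows):
        self.windows = [tuple(tuple(float(v) for v in res) for res in w)
                        for w in windows]
        for w in self.windows:
            if len(w) != 3 or any(len(r) != 3 for r in w):
                raise ValidationError("fragments are 3 residues x 3 angles")

    def __len__(self):
        return len(self.windows)

    def save(self, path) -> None:
        lines = [" ".join(f"{v:.4f}" for res in w for v in res)
                 for w in self.windows]
        Path(path).write_text("\n".join(lines) + "\n")

    @staticmethod
    def load(path) -> "FragmentStore":
        windows = []
        for line in Path(path).read_text().splitlines():
            vals = [float(t) for t in line.split()]
            if len(vals) != 9:
                raise ConfigurationError(
                    "fragment lines carry nine angle columns")
            windows.append([vals[0:3], vals[3:6], vals[6:9]])
        return FragmentStore(windows)


def build_fragment_store(
    mode: str,
    inputs,
    n_fragments: int = 200,
    rng: np.random.Generator | None = None,
    rama: RamachandranModel | None = None,
) -> FragmentStore:
    """Build a fragment store either by sampling Ramachandran basins
    (``from_ramachandran``; ``inputs`` is ignored and may be None) or by
    harvesting consecutive torsion windows from structures
    (``from_structures``; ``inputs`` is a list of Structures or PDB paths).
    """
    rama = rama or default_model()
    if mode == "from_ramachandran":
        rng = rng if rng is not None else np.random.default_rng(0)
        windows = []
        for _ in range(n_fragments):
            w = []
            for _ in range(3):
                phi, psi = rama.sample("ALA", rng)
                w.append((phi, psi, 180.0))
            windows.append(w)
        return FragmentStore(windows)
    if mode == "from_structures":
        from .structure import read_pdb
        if not inputs:
            raise ConfigurationError("from_structures needs at least one input")
        windows = []
        for item in inputs:
            st = item if isinstance(item, Structure) else read_pdb(item)
            for cid in st.chain_ids:
                chain = st.residues(cid)
                tors = []
                for r in chain:
                    tors.append(tuple(
                        measure_torsion(st, None, r.key, n)
                        for n in ("phi", "psi", "omega")))
                for i in range(1, len(chain) - 3):
                    w = tors[i:i + 3]
                    if all(v is not None for res in w for v in res):
                        windows.append([tuple(res) for res in w])
        if not windows:
            raise ConfigurationError("no complete torsion windows found")
        return FragmentStore(windows)
    raise ValidationError(f"unknown fragment mode {mode!r}")
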