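"""The simplified two-resolution scorefunction.

Two presets exist: ``centroid`` scores residue-level interaction centers
(CB, or CA for glycine) plus backbone terms, and is used by the broad
perturbation phase; ``fullatom`` adds all-atom sterics, a distance+angle
Gaussian hydrogen-bond term and a rotamer-preference surrogate, and is
used by refinement.  Shared terms: a parametric Ramachandran score, a
harmonic omega preference (trans, with cis allowed for proline), the
chainbreak term that penalizes geometric discontinuity at loop cutpoints
(default weight 2), and harmonic coordinate constraints.

This is a deliberately self-contained potential; it does not attempt to
reproduce any published all-atom energy function.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .errors import ScoringError, RigidityError, ValidationError
from .geometry import (BOND_C_N, IDEAL_C_CA_NEXT, IDEAL_CA_N_NEXT, distance,
                       wrap_angle)
from .kinematics import AnchoredFoldTree, apply_torsions, measure_torsion
from .ramachandran import default_model
from .sidechains import n_rotatable_chis
from .structure import Residue, ResidueKey, Structure

TERMS = ("steric_rep", "steric_atr", "rama", "omega", "hbond",
         "rotamer_pref", "chainbreak", "constraint")

#: alias kept for users reading scorefiles produced by other suites: the
#: rotamer-preference surrogate fills the role usually called "dunbrack"
TERM_ALIASES = {"dunbrack": "rotamer_pref"}

_LJ_EPS = 0.12
_LJ_CUTOFF = 8.0
_LJ_RAMP = 0.6     # fraction of sigma where the linear ramp takes over
_LJ_CAP = 100.0    # per-pair repulsion cap
_OMEGA_SCALE = 20.0  # degrees of omega deviation that cost 1.0 raw unit

_HB_D0, _HB_SD = 2.9, 0.35
_HB_TH0, _HB_STH = 120.0, 35.0
_HB_DMAX = 4.0

_SC_DONORS = {
    "ARG": ("NE", "NH1", "NH2"), "ASN": ("ND2",), "GLN": ("NE2",),
    "HIS": ("ND1", "NE2"), "LYS": ("NZ",), "SER": ("OG",),
    "THR": ("OG1",), "TRP": ("NE1",), "TYR": ("OH",),
}
_SC_ACCEPTORS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "ASN": ("OD1",),
    "GLN": ("OE1",), "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",),
    "HIS": ("ND1", "NE2"),
}
_ACCEPTOR_BASE = {
    "O": "C", "OD1": "CG", "OD2": "CG", "OE1": "CD", "OE2": "CD",
    "OG": "CB", "OG1": "CB", "OH": "CZ", "ND1": "CG", "NE2": "CD2",
}


def _load_radii():
    text = (resources.files("anchorloop") / "data" / "radii.json").read_text()
    return json.loads(text)


_RADII = _load_radii()


def element_radius(element: str) -> float:
    try:
        return _RADII["element"][element.upper()]
    except KeyError:
        raise ScoringError(f"no van der Waals radius for element {element!r}")


def centroid_radius(aa: str) -> float:
    return _RADII["centroid"].get(aa, 2.5)


def rotamer_pref_energy(aa: str) -> float:
    """-log of the uniform rotamer weight: log(number of grid rotamers)."""
    n = 3 ** min(n_rotatable_chis(aa), 2)
    return float(np.log(n))


@dataclass
class ScoreWeights:
    """Per-term weights; presets are shipped as plain-text data files."""

    name: str
    weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for term, w in self.weights.items():
            if term not in TERMS:
                raise ValidationError(f"unknown score term {term!r}")
            if w < 0:
                raise ValidationError(f"negative weight for {term}")

    def get(self, term: str) -> float:
        return self.weights.get(term, 0.0)

    def replace(self, **kw) -> "ScoreWeights":
        w = dict(self.weights)
        w.update(kw)
        return ScoreWeights(self.name, w)

    @staticmethod
    def from_file(path, name: str | None = None) -> "ScoreWeights":
        weights = {}
        for line in Path(path).read_text().splitlines():
            line = line.split("#")[0].strip()
            if not line:
                continue
            term, value = line.split()
            term = TERM_ALIASES.get(term, term)
            weights[term] = float(value)
        return ScoreWeights(name or Path(path).stem, weights)

    @staticmethod
    def preset(name: str) -> "ScoreWeights":
        if name not in ("centroid", "fullatom"):
            raise ValidationError(f"unknown preset {name!r}")
        path = resources.files("anchorloop") / "data" / f"weights_{name}.txt"
        return ScoreWeights.from_file(str(path), name)


@dataclass
class ScoreReport:
    """Weighted total plus raw per-term and per-residue breakdowns."""

    total_score: float
    term_totals: dict[str, float]
    per_residue: dict[ResidueKey, dict[str, float]]
    weights: ScoreWeights

    def recompute_total(self) -> float:
        return sum(self.weights.get(t) * v for t, v in self.term_totals.items())


@dataclass(frozen=True)
class HarmonicConstraint:
    """score = weight * (d - d0)^2 between two named atoms."""

    atom_a: tuple[ResidueKey, str]
    atom_b: tuple[ResidueKey, str]
    d0: float
    weight: float = 0.5

    def value(self, structure: Structure) -> float:
        a = structure.residue(self.atom_a[0]).atom(self.atom_a[1]).position
        b = structure.residue(self.atom_b[0]).atom(self.atom_b[1]).position
        return self.weight * (distance(a, b) - self.d0) ** 2


# ---------------------------------------------------------------------------
# atom tables and nonbonded terms
# ---------------------------------------------------------------------------

class AtomTable:
    """Flat arrays for one interaction group.

    Entries are (uid, chain_index, position-in-chain, Residue-like atom
    list); exclusion of same-residue and chain-adjacent pairs uses the
    uid / chain / seqpos columns.
    """

    def __init__(self, entries):
        pos, rad, uid, chain, seq = [], [], [], [], []
        don_idx, acc_idx, acc_base = [], [], []
        for e_uid, e_chain, e_seq, aa, atoms in entries:
            names = {a.name: a for a in atoms}
            for a in atoms:
                i = len(pos)
                pos.append(a.position)
                rad.append(element_radius(a.element))
                uid.append(e_uid)
                chain.append(e_chain)
                seq.append(e_seq)
                if (a.name == "N" and aa != "PRO") or \
                        a.name in _SC_DONORS.get(aa, ()):
                    don_idx.append(i)
                if a.name == "O" or a.name in _SC_ACCEPTORS.get(aa, ()):
                    base = _ACCEPTOR_BASE.get(a.name)
                    if base in names:
                        acc_idx.append(i)
                        acc_base.append(names[base].position)
        self.pos = np.array(pos).reshape(-1, 3)
        self.radius = np.array(rad)
        self.uid = np.array(uid, dtype=int)
        self.chain = np.array(chain, dtype=int)
        self.seq = np.array(seq, dtype=int)
        self.don = np.array(don_idx, dtype=int)
        self.acc = np.array(acc_idx, dtype=int)
        self.acc_base = (np.array(acc_base).reshape(-1, 3)
                         if acc_base else np.zeros((0, 3)))

    def __len__(self):
        return len(self.pos)

    @staticmethod
    def from_structure(structure: Structure, centroid: bool = False,
                       chains=None) -> "AtomTable":
        """Build a table for the whole structure or (``chains``) a subset
        of its chains; numbering stays global so tables built from the
        same structure compose consistently."""
        entries = []
        chain_map = {c: i for i, c in enumerate(structure.chain_ids)}
        uid = 0
        for cid in structure.chain_ids:
            for seq, res in enumerate(structure.residues(cid)):
                uid += 1
                if chains is not None and cid not in chains:
                    continue
                if centroid:
                    atoms = [_centroid_atom(res)]
                else:
                    atoms = res.atoms
                entries.append((uid - 1, chain_map[cid], seq, res.aa_type,
                                atoms))
        return AtomTable(entries)


def _centroid_atom(res: Residue):
    from .structure import Atom
    name = "CA" if res.aa_type == "GLY" else "CB"
    if not res.has_atom(name):
        raise ScoringError(
            f"residue {res.label} is missing its interaction center ({name})")
    a = res.atom(name)
    return Atom(a.name, a.element, a.position)


def _exclusion_mask(ta: AtomTable, tb: AtomTable) -> np.ndarray:
    same_res = ta.uid[:, None] == tb.uid[None, :]
    adjacent = (ta.chain[:, None] == tb.chain[None, :]) & (
        np.abs(ta.seq[:, None] - tb.seq[None, :]) <= 1)
    return same_res | adjacent


def _lj_pair_matrices(ta, tb, sigma_scale=1.0, centroid_radii=None):
    d = np.linalg.norm(ta.pos[:, None, :] - tb.pos[None, :, :], axis=2)
    sigma = (ta.radius[:, None] + tb.radius[None, :]) * sigma_scale
    with np.errstate(divide="ignore", over="ignore"):
        x6 = (sigma / np.maximum(d, 1e-6)) ** 6
        e = _LJ_EPS * (x6 * x6 - 2.0 * x6)
    rep = np.where(d < sigma, e + _LJ_EPS, 0.0)
    # linear ramp with a cap inside 0.6 sigma
    d_ramp = _LJ_RAMP * sigma
    x6r = (1.0 / _LJ_RAMP) ** 6
    e_at = _LJ_EPS * (x6r * x6r - 2.0 * x6r)
    slope = _LJ_EPS * 12.0 * (-(x6r * x6r) + x6r) / d_ramp
    ramped = np.minimum(e_at + slope * (d - d_ramp) + _LJ_EPS, _LJ_CAP)
    rep = np.where(d < d_ramp, ramped, rep)
    atr = np.where(d < sigma, -_LJ_EPS, e)
    cut = d >= _LJ_CUTOFF
    rep = np.where(cut, 0.0, rep)
    atr = np.where(cut, 0.0, atr)
    return rep, atr, d


def _hbond_matrix(ta: AtomTable, tb: AtomTable, excl: np.ndarray):
    """Gaussian distance+angle H-bond energies between donors of ``ta``
    and acceptors of ``tb``.  Returns (energies, donor uid, acceptor uid)."""
    if len(ta.don) == 0 or len(tb.acc) == 0:
        return (np.zeros(0), np.zeros(0, dtype=int), np.zeros(0, dtype=int))
    dpos = ta.pos[ta.don]
    apos = tb.pos[tb.acc]
    bpos = tb.acc_base
    d = np.linalg.norm(dpos[:, None, :] - apos[None, :, :], axis=2)
    v1 = bpos[None, :, :] - apos[None, :, :]
    v2 = dpos[:, None, :] - apos[None, :, :]
    cosang = np.sum(v1 * v2, axis=2) / np.maximum(
        np.linalg.norm(v1, axis=2) * np.linalg.norm(v2, axis=2), 1e-9)
    theta = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    e = -np.exp(-0.5 * ((d - _HB_D0) / _HB_SD) ** 2) \
        * np.exp(-0.5 * ((theta - _HB_TH0) / _HB_STH) ** 2)
    mask = (d < _HB_DMAX) & ~excl[np.ix_(ta.don, tb.acc)]
    e = np.where(mask, e, 0.0)
    keep = np.nonzero(e)
    return (e[keep],
            ta.uid[ta.don][keep[0]], tb.uid[tb.acc][keep[1]])


def interaction_terms(ta: AtomTable, tb: AtomTable, same_group: bool = False,
                      centroid: bool = False):
    """Raw steric_rep / steric_atr / hbond between two atom groups.

    Returns (term_totals, per_uid) where per_uid maps residue uid to its
    half-share of each pair term.
    """
    totals = {"steric_rep": 0.0, "steric_atr": 0.0, "hbond": 0.0}
    if len(ta) == 0 or len(tb) == 0:
        return totals, {}
    n_uid = int(max(ta.uid.max(), tb.uid.max())) + 1
    acc = {t: np.zeros(n_uid) for t in totals}

    excl = _exclusion_mask(ta, tb)
    rep, atr, _ = _lj_pair_matrices(ta, tb)
    pairmask = ~excl
    if same_group:
        pairmask &= np.triu(np.ones_like(excl, dtype=bool), k=1)
    rep = np.where(pairmask, rep, 0.0)
    atr = np.where(pairmask, atr, 0.0)
    totals["steric_rep"] = float(rep.sum())
    totals["steric_atr"] = float(atr.sum())
    for mat, term in ((rep, "steric_rep"), (atr, "steric_atr")):
        np.add.at(acc[term], ta.uid, 0.5 * mat.sum(axis=1))
        np.add.at(acc[term], tb.uid, 0.5 * mat.sum(axis=0))
    if not centroid:
        pairs = [(ta, ta, excl)] if same_group else \
            [(ta, tb, excl), (tb, ta, excl.T)]
        for (t1, t2, ex) in pairs:
            e, du, au = _hbond_matrix(t1, t2, ex)
            totals["hbond"] += float(e.sum())
            np.add.at(acc["hbond"], du, 0.5 * e)
            np.add.at(acc["hbond"], au, 0.5 * e)

    per_uid: dict[int, dict[str, float]] = {}
    nonzero = set()
    for t in totals:
        nonzero.update(np.nonzero(acc[t])[0].tolist())
    for u in nonzero:
        per_uid[int(u)] = {t: float(acc[t][u]) for t in totals}
    return totals, per_uid


# ---------------------------------------------------------------------------
# whole-structure scoring
# ---------------------------------------------------------------------------

def chainbreak_term(structure: Structure,
                    cutpoint: tuple[ResidueKey, ResidueKey]) -> float:
    """Sum of squared deviations of the three cross-cutpoint distances
    from their ideal-geometry values (before weighting)."""
    c_key, d_key = cutpoint
    try:
        rc, rd = structure.residue(c_key), structure.residue(d_key)
        Cc, CAc = rc.atom("C").position, rc.atom("CA").position
        Nd, CAd = rd.atom("N").position, rd.atom("CA").position
    except Exception as exc:
        raise ScoringError(f"chainbreak atoms missing at {cutpoint}: {exc}")
    return float(
        (np.linalg.norm(Cc - Nd) - BOND_C_N) ** 2
        + (np.linalg.norm(CAc - Nd) - IDEAL_CA_N_NEXT) ** 2
        + (np.linalg.norm(Cc - CAd) - IDEAL_C_CA_NEXT) ** 2
    )


def _omega_term(aa: str, omega: float) -> float:
    dev = abs(wrap_angle(omega - 180.0))
    if aa == "PRO":
        dev = min(dev, abs(wrap_angle(omega)))
    return (dev / _OMEGA_SCALE) ** 2


def score_structure(
    structure: Structure,
    weights: ScoreWeights,
    representation: str = "fullatom",
    cutpoints=(),
    constraints=(),
) -> ScoreReport:
    """Deterministic weighted score with per-residue breakdown.

    ``cutpoints`` lists loop chainbreaks as (residue, next-residue) key
    pairs; ``constraints`` is an iterable of :class:`HarmonicConstraint`.
    """
    if representation not in ("centroid", "fullatom"):
        raise ValidationError(f"unknown representation {representation!r}")
    centroid = representation == "centroid"
    rama = default_model()

    table = AtomTable.from_structure(structure, centroid=centroid)
    totals, per_uid = interaction_terms(table, table, same_group=True,
                                        centroid=centroid)
    uid_to_key = {}
    uid = 0
    for cid in structure.chain_ids:
        for res in structure.residues(cid):
            uid_to_key[uid] = res.key
            uid += 1

    per_residue: dict[ResidueKey, dict[str, float]] = {
        k: {t: 0.0 for t in TERMS} for k in uid_to_key.values()}
    for u, terms in per_uid.items():
        for t, v in terms.items():
            per_residue[uid_to_key[u]][t] += v

    term_totals = {t: 0.0 for t in TERMS}
    term_totals.update(totals)

    for res in structure.residues():
        phi = measure_torsion(structure, None, res.key, "phi")
        psi = measure_torsion(structure, None, res.key, "psi")
        if phi is not None and psi is not None:
            v = rama.score(res.aa_type, phi, psi)
            per_residue[res.key]["rama"] = v
            term_totals["rama"] += v
        omega = measure_torsion(structure, None, res.key, "omega")
        nxt = structure.neighbor_key(res.key, +1)
        across_cut = any(res.key == c for c, _ in cutpoints)
        if omega is not None and not across_cut:
            v = _omega_term(res.aa_type, omega)
            per_residue[res.key]["omega"] = v
            term_totals["omega"] += v
        if not centroid:
            v = rotamer_pref_energy(res.aa_type)
            per_residue[res.key]["rotamer_pref"] = v
            term_totals["rotamer_pref"] += v

    for cut in cutpoints:
        v = chainbreak_term(structure, cut)
        term_totals["chainbreak"] += v
        per_residue[cut[0]]["chainbreak"] += 0.5 * v
        per_residue[cut[1]]["chainbreak"] += 0.5 * v

    for cst in constraints:
        v = cst.value(structure)
        term_totals["constraint"] += v
        per_residue[cst.atom_a[0]]["constraint"] += v

    total = sum(weights.get(t) * v for t, v in term_totals.items())
    return ScoreReport(float(total), term_totals, per_residue, weights)


# ---------------------------------------------------------------------------
# displacement constraints
# ---------------------------------------------------------------------------

def make_displacement_constraints(
    structure: Structure,
    anchor: ResidueKey,
    k_partners: int = 4,
    weight: float = 0.5,
) -> list[HarmonicConstraint]:
    """Harmonic constraints between the anchor CA and the ``k_partners``
    closest alpha carbons across the interface, rest distances set to the
    current distances (weight 0.5: half a score unit at 1 A deviation)."""
    anchor_res = structure.residue(anchor)
    a_ca = anchor_res.atom("CA").position
    partners = []
    for res in structure.residues():
        if res.chain_id == anchor[0] or not res.has_atom("CA"):
            continue
        partners.append((distance(a_ca, res.atom("CA").position), res.key))
    if len(partners) < k_partners:
        raise ValidationError(
            f"need {k_partners} cross-interface CA partners, "
            f"found {len(partners)}")
    partners.sort()
    return [
        HarmonicConstraint((anchor, "CA"), (key, "CA"), d0, weight)
        for d0, key in partners[:k_partners]
    ]


# ---------------------------------------------------------------------------
# torsion-space minimization
# ---------------------------------------------------------------------------

def minimize_torsions(
    structure: Structure,
    tree: AnchoredFoldTree,
    movable,
    weights: ScoreWeights,
    tolerance: float = 1e-3,
    representation: str = "fullatom",
    cutpoints=None,
    constraints=(),
    max_iter: int = 30,
    gradient_step: float = 1e-3,
) -> Structure:
    """Gradient-based descent over a set of mobile torsions.

    The final score never exceeds the initial score; anchor and core
    positions are untouched (requesting them raises
    :class:`RigidityError`).
    """
    if cutpoints is None:
        cutpoints = tree.cutpoints
    movable = [t for t in movable]
    for t in movable:
        if not tree.is_mobile(*t):
            raise RigidityError(f"torsion {t} is not mobile in this tree")
    movable = [t for t in movable if tree.torsion_drive(*t) is not None]
    if not movable:
        return structure.copy()

    x0 = np.array([measure_torsion(structure, tree, k, n)
                   for k, n in movable], dtype=float)

    best = {"x": x0.copy(), "f": None}

    def objective(x):
        st = apply_torsions(structure, tree,
                            {t: float(v) for t, v in zip(movable, x)})
        f = score_structure(st, weights, representation, cutpoints,
                            constraints).total_score
        if best["f"] is None or f < best["f"]:
            best["f"] = f
            best["x"] = np.array(x, dtype=float)
        return f

    f0 = objective(x0)
    if not np.isfinite(f0):
        raise ScoringError("non-finite score at minimization start")
    minimize(objective, x0, method="L-BFGS-B", jac=None,
             options={"maxiter": max_iter, "ftol": 1e-12, "gtol": tolerance,
                      "eps": gradient_step})
    if best["f"] is not None and best["f"] < f0:
        return apply_torsions(structure, tree,
                              {t: float(v) for t, v in zip(movable, best["x"])})
    return structure.copy()
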