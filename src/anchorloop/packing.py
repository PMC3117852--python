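"""Side-chain repacking and interface sequence design.

The packable region is detected automatically: loop residues, their
neighbors, and interface residues are included; protein cores and distal
surfaces are frozen.  Packing is simulated annealing over a small
backbone-independent rotamer library (chi1/chi2 on a -60/60/180 grid,
pruned by intra-residue clash, plus the input conformation); design uses
the identical machinery with per-position identity choices from a
:class:`DesignSpec`.  The pair-decomposed packer energy (sterics, H-bonds,
rotamer preference) matches the full scorefunction exactly for the atoms
it moves, so packing can never raise the total score.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .kinematics import measure_torsion
from .loops import LoopSpec, ResolvedLoop
from .ramachandran import default_model
from .scoring import (AtomTable, ScoreWeights, _omega_term,
                      interaction_terms, rotamer_pref_energy)
from .sidechains import (STANDARD_AAS, build_residue_atoms, intra_clash,
                         measure_chis, n_rotatable_chis)
from .structure import Residue, ResidueKey, Structure

CHI_GRID = (-60.0, 60.0, 180.0)


# ---------------------------------------------------------------------------
# region detection
# ---------------------------------------------------------------------------

def detect_movable_region(
    structure: Structure,
    loop_specs,
    neighbor_radius: float = 10.0,
    interface_radius: float = 5.0,
) -> set[ResidueKey]:
    """Loop residues + CB neighbors of loops + interface residues.

    The complement of this set is frozen during packing and design.
    """
    if neighbor_radius <= 0 or interface_radius <= 0:
        raise ValidationError("radii must be positive")
    loop_keys: set[ResidueKey] = set()
    for spec in loop_specs:
        res = spec if isinstance(spec, ResolvedLoop) else spec.resolve(structure)
        loop_keys.update(res.loop_keys)

    residues = structure.residues()
    centers = {}
    for r in residues:
        name = "CA" if r.aa_type == "GLY" or not r.has_atom("CB") else "CB"
        centers[r.key] = r.atom(name).position

    region = set(loop_keys)
    if loop_keys:
        loop_centers = np.array([centers[k] for k in loop_keys])
        for r in residues:
            d = np.linalg.norm(loop_centers - centers[r.key][None, :], axis=1)
            if d.min() <= neighbor_radius:
                region.add(r.key)

    by_chain = {c: np.array([a.position for r in structure.residues(c)
                             for a in r.atoms]) for c in structure.chain_ids}
    for r in residues:
        own = np.array([a.position for a in r.atoms])
        for cid, other in by_chain.items():
            if cid == r.key[0]:
                continue
            d = np.linalg.norm(own[:, None, :] - other[None, :, :], axis=2)
            if d.min() <= interface_radius:
                region.add(r.key)
                break
    return region


# ---------------------------------------------------------------------------
# design specification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """Allowed amino-acid identities per position.

    Positions absent from the spec keep their native identity (repack
    only).  The text format is one position per line::

        <chain> <resnum>[icode] <AAA,BBB,...>

    e.g. ``B 14 ALA,GLY,SER``.
    """

    positions: dict[ResidueKey, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        for key, aas in self.positions.items():
            for aa in aas:
                if aa not in STANDARD_AAS:
                    raise ValidationError(f"unknown amino acid {aa!r} at {key}")

    def allowed(self, key: ResidueKey, native: str) -> list[str]:
        if key not in self.positions:
            return [native]
        aas = set(self.positions[key]) | {native}
        return sorted(aas)

    @staticmethod
    def from_file(path) -> "DesignSpec":
        positions = {}
        for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#")[0].strip()
            if not line:
                continue
            toks = line.split()
            if len(toks) != 3:
                raise ValidationError(
                    f"design spec line {ln}: expected 'chain resnum AAs'")
            chain, resid, aas = toks
            icode = ""
            if resid[-1].isalpha():
                resid, icode = resid[:-1], resid[-1]
            key = (chain, int(resid), icode)
            positions[key] = frozenset(a.strip().upper()
                                       for a in aas.split(","))
        return DesignSpec(positions)


# ---------------------------------------------------------------------------
# rotamers
# ---------------------------------------------------------------------------

@dataclass
class Rotamer:
    aa: str
    chis: tuple[float, ...]
    atoms: list | None     # None marks the input ("current") conformation
    weight: float = 1.0


class RotamerSet:
    """Per-position rotamer candidates; the input conformation is always
    candidate 0 and per-amino-acid weights are uniform."""

    def __init__(self, candidates: dict[ResidueKey, list[Rotamer]]):
        self.candidates = candidates

    def __getitem__(self, key):
        return self.candidates[key]

    @staticmethod
    def build(structure: Structure, positions,
              design_spec: DesignSpec | None = None,
              current_only: bool = False) -> "RotamerSet":
        candidates = {}
        for key in sorted(positions):
            res = structure.residue(key)
            backbone = {n: res.atom(n).position for n in ("N", "CA", "C")}
            if res.has_atom("O"):
                backbone["O"] = res.atom("O").position
            cands = [Rotamer(res.aa_type, measure_chis(res), None)]
            if not current_only:
                allowed = (design_spec.allowed(key, res.aa_type)
                           if design_spec else [res.aa_type])
                for aa in allowed:
                    nchi = min(n_rotatable_chis(aa), 2)
                    grids = itertools.product(CHI_GRID, repeat=nchi) \
                        if nchi else [()]
                    for chis in grids:
                        atoms = build_residue_atoms(backbone, aa, tuple(chis))
                        if intra_clash(backbone, atoms):
                            continue
                        cands.append(Rotamer(aa, tuple(chis), atoms))
            # uniform weights per amino acid
            by_aa = {}
            for c in cands:
                by_aa.setdefault(c.aa, []).append(c)
            for group in by_aa.values():
                for c in group:
                    c.weight = 1.0 / len(group)
            candidates[key] = cands
        return RotamerSet(candidates)


# ---------------------------------------------------------------------------
# pair-decomposed packer energies
# ---------------------------------------------------------------------------

class _PackerTask:
    def __init__(self, structure: Structure, region, weights: ScoreWeights,
                 rotamer_set: RotamerSet):
        self.structure = structure
        self.weights = weights
        self.positions = sorted(k for k in region)
        self.rotamers = rotamer_set

        uid, meta = 0, {}
        for cid_i, cid in enumerate(structure.chain_ids):
            for seq, res in enumerate(structure.residues(cid)):
                meta[res.key] = (uid, cid_i, seq)
                uid += 1
        self.meta = meta

        region_set = set(self.positions)
        context_entries = []
        for cid in structure.chain_ids:
            for res in structure.residues(cid):
                u, c, s = meta[res.key]
                if res.key in region_set:
                    atoms = [a for a in res.atoms
                             if a.name in ("N", "CA", "C", "O")]
                else:
                    atoms = res.atoms
                context_entries.append((u, c, s, res.aa_type, atoms))
        self.context = AtomTable(context_entries)

        rama = default_model()
        self.tables: dict[tuple[ResidueKey, int], AtomTable] = {}
        self.one_body: dict[ResidueKey, list[float]] = {}
        for key in self.positions:
            u, c, s = meta[key]
            res = structure.residue(key)
            phi = measure_torsion(structure, None, key, "phi")
            psi = measure_torsion(structure, None, key, "psi")
            omega = measure_torsion(structure, None, key, "omega")
            obs = []
            for ci, cand in enumerate(rotamer_set[key]):
                atoms = cand.atoms
                if atoms is None:
                    atoms = res.sidechain_atoms()
                table = AtomTable([(u, c, s, cand.aa, atoms)])
                self.tables[(key, ci)] = table
                totals, _ = interaction_terms(table, self.context)
                e = self._weighted(totals) \
                    + weights.get("rotamer_pref") * rotamer_pref_energy(cand.aa)
                # identity-dependent backbone terms (GLY/PRO classes)
                if phi is not None and psi is not None:
                    e += weights.get("rama") * rama.score(cand.aa, phi, psi)
                if omega is not None:
                    e += weights.get("omega") * _omega_term(cand.aa, omega)
                obs.append(e)
            self.one_body[key] = obs
        self._pair_cache: dict = {}

    def _weighted(self, totals):
        w = self.weights
        return (w.get("steric_rep") * totals["steric_rep"]
                + w.get("steric_atr") * totals["steric_atr"]
                + w.get("hbond") * totals["hbond"])

    def two_body(self, key_i, ci, key_j, cj) -> float:
        if key_i > key_j:
            key_i, ci, key_j, cj = key_j, cj, key_i, ci
        tag = (key_i, ci, key_j, cj)
        if tag not in self._pair_cache:
            totals, _ = interaction_terms(self.tables[(key_i, ci)],
                                          self.tables[(key_j, cj)])
            self._pair_cache[tag] = self._weighted(totals)
        return self._pair_cache[tag]

    def total(self, assign: dict[ResidueKey, int]) -> float:
        e = sum(self.one_body[k][ci] for k, ci in assign.items())
        for i, ki in enumerate(self.positions):
            for kj in self.positions[i + 1:]:
                e += self.two_body(ki, assign[ki], kj, assign[kj])
        return e

    def delta(self, assign, key, new_ci) -> float:
        old_ci = assign[key]
        if new_ci == old_ci:
            return 0.0
        d = self.one_body[key][new_ci] - self.one_body[key][old_ci]
        for kj in self.positions:
            if kj == key:
                continue
            d += self.two_body(key, new_ci, kj, assign[kj]) \
                - self.two_body(key, old_ci, kj, assign[kj])
        return d

    def apply(self, assign: dict[ResidueKey, int]) -> Structure:
        out = self.structure.copy()
        for key, ci in assign.items():
            cand = self.rotamers[key][ci]
            if cand.atoms is None:
                continue  # input conformation: leave the residue untouched
            res = out.residue(key)
            backbone = [a for a in res.atoms if a.name in ("N", "CA", "C", "O")]
            res.aa_type = cand.aa
            res.atoms = backbone + [a.copy() for a in cand.atoms]
        return out


DEFAULT_SCHEDULE = ((10.0, 1.0), (3.0, 1.0), (1.0, 1.0), (0.3, 1.0))


def _optimize(task: _PackerTask, rng: np.random.Generator,
              schedule, greedy: bool):
    assign = {k: 0 for k in task.positions}
    best = dict(assign)
    e = task.total(assign)
    best_e = e
    # greedy single pass; annealing warm-starts from it, so the annealed
    # result can never be worse than greedy
    for key in task.positions:
        cis = range(len(task.rotamers[key]))
        deltas = [task.delta(assign, key, ci) for ci in cis]
        assign[key] = int(np.argmin(deltas))
    e = task.total(assign)
    if e < best_e:
        best, best_e = dict(assign), e
    if greedy:
        return best, best_e
    n_cand = sum(len(task.rotamers[k]) for k in task.positions)
    for temp, factor in schedule:
        for _ in range(max(1, int(factor * n_cand))):
            key = task.positions[int(rng.integers(len(task.positions)))]
            ci = int(rng.integers(len(task.rotamers[key])))
            d = task.delta(assign, key, ci)
            if d <= 0 or rng.random() < np.exp(-d / temp):
                assign[key] = ci
                e += d
                if e < best_e:
                    best, best_e = dict(assign), e
    return best, best_e


def pack_rotamers(
    structure: Structure,
    region,
    weights: ScoreWeights,
    rng: np.random.Generator,
    rotamer_set: RotamerSet | None = None,
    schedule=DEFAULT_SCHEDULE,
    greedy: bool = False,
) -> Structure:
    """Fixed-sequence rotamer relaxation over ``region`` by simulated
    annealing.  Atoms outside the region are bitwise-unchanged, and the
    result never scores worse than the input."""
    region = sorted(set(region))
    if not region:
        raise ValidationError("packing region is empty")
    if rotamer_set is None:
        rotamer_set = RotamerSet.build(structure, region)
    task = _PackerTask(structure, region, weights, rotamer_set)
    best, _ = _optimize(task, rng, schedule, greedy)
    return task.apply(best)


def design_sequence(
    structure: Structure,
    region,
    design_spec: DesignSpec,
    weights: ScoreWeights,
    rng: np.random.Generator,
    anchor_keys=(),
    rotamer_set: RotamerSet | None = None,
    schedule=DEFAULT_SCHEDULE,
) -> Structure:
    """Sequence design: identical machinery to :func:`pack_rotamers` with
    identity choices expanded per the design spec.  Anchor positions are
    never designable -- the anchor carries its donor sequence identity."""
    anchor_set = set(anchor_keys)
    for key in design_spec.positions:
        if key in anchor_set:
            raise ValidationError(
                f"anchor position {key} may not be designed")
    region = sorted(set(region))
    if not region:
        raise ValidationError("design region is empty")
    if rotamer_set is None:
        rotamer_set = RotamerSet.build(structure, region,
                                       design_spec=design_spec)
    task = _PackerTask(structure, region, weights, rotamer_set)
    best, _ = _optimize(task, rng, schedule, greedy=False)
    return task.apply(best)
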