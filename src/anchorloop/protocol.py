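"""The anchored-design protocol driver.

A trajectory has two Metropolis Monte Carlo phases.  The perturbation
phase works in the centroid representation and samples aggressively: each
cycle perturbs the loop (Ramachandran randomization or fragments), closes
it (CCD and/or KIC), minimizes the mobile torsions and applies the
Metropolis criterion.  The refinement phase works fullatom with small
moves, softened (capped) CCD steps, per-cycle rotamer repacking of the
automatically detected movable region, and optional sequence design every
``refine_repack_interval`` cycles.  Fragment moves are never used during
refinement.

Because the fold tree fixes the anchor to the target, loop sampling doubles
as rigid-body sampling of the scaffold: no separate docking moves exist or
are needed.  Benchmark modes re-predict a complex after deleting the loop
conformation and interface side chains; relaxed-native modes measure drift
from the correct answer; the displacement experiment starts the anchor up
to 1 A off its crystal position (a cube of volume 8 A^3), lets it move, and
restrains it with four harmonic CA constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import (LoopResidueReport, MetricsRecord, analyze_interface,
                       analyze_loops, compute_rmsd_metrics)
from .errors import ClosureError, KICNoSolution, ProtocolError, ValidationError
from .kinematics import (AnchoredFoldTree, build_anchored_fold_tree,
                         build_standard_fold_tree)
from .loop_closure import FragmentStore, ccd_close, kic_close, perturb_loop
from .loops import LoopSpec
from .packing import (DesignSpec, detect_movable_region, design_sequence,
                      pack_rotamers)
from .ramachandran import default_model
from .scoring import (HarmonicConstraint, ScoreReport, ScoreWeights,
                      make_displacement_constraints, minimize_torsions,
                      score_structure)
from .sidechains import replace_sidechain
from .structure import Structure

QUICK_PACK_SCHEDULE = ((3.0, 0.5), (1.0, 0.5), (0.3, 0.5))


@dataclass
class ProtocolConfig:
    """Protocol knobs; defaults are 500 perturbation and 1000 refinement
    cycles with repacking/design every 100 refinement cycles."""

    perturb_cycles: int = 500
    refine_cycles: int = 1000
    refine_repack_interval: int = 100
    temperature: float = 0.8
    closure_mode: str = "both"        # "ccd" | "kic" | "both" (alternating)
    refine_only: bool = False
    design: bool = False
    design_spec: DesignSpec | None = None
    seed: int = 0
    perturb_magnitude: float = 5.0    # refine-phase small-move size, degrees
    ccd_refine_cap: float = 10.0      # softened CCD per-move cap, degrees
    closure_tolerance: float = 0.1    # Angstrom
    retry_budget: int = 20            # closure retries per cycle
    minimize_iters: int = 3
    fragments: FragmentStore | None = None
    chainbreak_weight: float | None = None   # override the preset weight

    def validate(self):
        if self.closure_mode not in ("ccd", "kic", "both"):
            raise ValidationError(
                f"unknown closure mode {self.closure_mode!r}")
        if self.temperature <= 0:
            raise ValidationError("temperature must be positive")
        if self.perturb_cycles < 0 or self.refine_cycles < 0:
            raise ValidationError("cycle counts must be non-negative")
        if self.design:
            if self.refine_repack_interval < 50:
                raise ValidationError(
                    "refine_repack_interval should not be less than 50")
            if self.refine_repack_interval > self.refine_cycles / 4:
                raise ValidationError(
                    "refine_repack_interval should not be more than 1/4 "
                    "of the total refine cycles")

    def weights(self, representation: str) -> ScoreWeights:
        w = ScoreWeights.preset(representation)
        if self.chainbreak_weight is not None:
            w = w.replace(chainbreak=self.chainbreak_weight)
        return w


@dataclass
class TrajectoryRecord:
    final_structure: Structure
    score_report: ScoreReport | None
    metrics: MetricsRecord
    loop_reports: list[LoopResidueReport] | None
    acceptance: dict
    log: list[str]
    description: str


def metropolis_step(current_score: float, proposed_score: float,
                    temperature: float, rng: np.random.Generator) -> bool:
    """Accept downhill moves always; uphill with probability exp(-dE/T)."""
    if not (np.isfinite(current_score) and np.isfinite(proposed_score)):
        raise ProtocolError("non-finite score in Metropolis step")
    if temperature <= 0:
        raise ProtocolError("temperature must be positive")
    if proposed_score <= current_score:
        return True
    return bool(rng.random()
                < np.exp(-(proposed_score - current_score) / temperature))


def draw_displacement(rng: np.random.Generator) -> np.ndarray:
    """Uniform draw inside the +-1 A cube (volume 8 A^3)."""
    return rng.uniform(-1.0, 1.0, size=3)


def _mobile_torsions(tree: AnchoredFoldTree):
    # phi/psi only: omega stays trans during minimization
    return sorted(t for t in tree.mobile if t[1] != "omega")


def _closure_method(mode: str, cycle: int) -> str:
    if mode == "both":
        return "ccd" if cycle % 2 == 0 else "kic"
    return mode


class _MonteCarlo:
    """Current/lowest bookkeeping with an acceptance log."""

    def __init__(self, structure, score, tag, log):
        self.current = structure
        self.current_score = score
        self.best = structure
        self.best_score = score
        self.accepted = 0
        self.rejected = 0
        self.closure_failures = 0
        self.accepted_scores: list[float] = []
        self.tag = tag
        self.log = log

    def consider(self, structure, score, temperature, rng) -> bool:
        if metropolis_step(self.current_score, score, temperature, rng):
            self.current = structure
            self.current_score = score
            self.accepted += 1
            self.accepted_scores.append(score)
            if score < self.best_score:
                self.best = structure
                self.best_score = score
            return True
        self.rejected += 1
        return False

    def stats(self):
        return {
            "accepted": self.accepted,
            "rejected": self.rejected,
            "closure_failures": self.closure_failures,
            "final_score": self.current_score,
            "best_score": self.best_score,
            "accepted_scores": list(self.accepted_scores),
        }


def _closed_candidate(mc, tree, config, rng, method, phase):
    """One perturb+close attempt with the per-cycle retry budget.
    Returns a closed structure or None (cycle rejected)."""
    loop = tree.loops[0]
    for _ in range(config.retry_budget):
        try:
            if method == "kic":
                if phase == "perturb":
                    res = kic_close(mc.current, tree, loop, rng=rng,
                                    random_pivots=True)
                else:
                    cand = perturb_loop(mc.current, tree, loop,
                                        mode="small_move",
                                        magnitude=config.perturb_magnitude,
                                        rng=rng)
                    res = kic_close(cand, tree, loop, rng=rng,
                                    resample_nonpivots=False)
            else:
                if phase == "perturb":
                    mode = "fragment" if config.fragments is not None \
                        else "randomize"
                    cand = perturb_loop(mc.current, tree, loop, mode=mode,
                                        rng=rng, fragments=config.fragments)
                    res = ccd_close(cand, tree, loop,
                                    tolerance=config.closure_tolerance)
                else:
                    cand = perturb_loop(mc.current, tree, loop,
                                        mode="small_move",
                                        magnitude=config.perturb_magnitude,
                                        rng=rng)
                    res = ccd_close(cand, tree, loop,
                                    tolerance=config.closure_tolerance,
                                    per_move_cap=config.ccd_refine_cap)
            if res.break_deviation < config.closure_tolerance:
                return res.closed_structure
        except KICNoSolution:
            continue
        except ClosureError as exc:
            raise ProtocolError(f"unclosable loop: {exc}") from exc
        mc.closure_failures += 1
    return None


def _reclose_all(structure, tree, config, capped: bool):
    """Re-close every loop after minimization (which may trade a little
    chainbreak for other terms).  Returns None when a loop will not close."""
    work = structure
    for loop in tree.loops:
        res = ccd_close(work, tree, loop,
                        tolerance=config.closure_tolerance,
                        per_move_cap=config.ccd_refine_cap if capped
                        else None)
        if res.break_deviation >= config.closure_tolerance:
            return None
        work = res.closed_structure
    return work


def run_perturb_phase(
    structure: Structure,
    loop_specs,
    config: ProtocolConfig,
    rng: np.random.Generator,
    tree: AnchoredFoldTree | None = None,
    constraints=(),
    log: list | None = None,
):
    """Centroid-mode broad sampling.  Returns (last-accepted structure,
    lowest-score structure, stats)."""
    config.validate()
    log = log if log is not None else []
    if tree is None:
        tree = build_anchored_fold_tree(structure, loop_specs)
    weights = config.weights("centroid")
    cutpoints = tree.cutpoints
    movable = _mobile_torsions(tree)

    log.append("phase centroid-perturb start")
    score0 = score_structure(structure, weights, "centroid", cutpoints,
                             constraints).total_score
    mc = _MonteCarlo(structure.copy(), score0, "perturb", log)
    for cycle in range(config.perturb_cycles):
        method = _closure_method(config.closure_mode, cycle)
        cand = _closed_candidate(mc, tree, config, rng, method, "perturb")
        if cand is None:
            mc.rejected += 1
            continue
        cand = minimize_torsions(cand, tree, movable, weights,
                                 representation="centroid",
                                 cutpoints=cutpoints,
                                 constraints=constraints,
                                 max_iter=config.minimize_iters)
        cand = _reclose_all(cand, tree, config, capped=False)
        if cand is None:
            mc.rejected += 1
            continue
        s = score_structure(cand, weights, "centroid", cutpoints,
                            constraints).total_score
        mc.consider(cand, s, config.temperature, rng)
    log.append(
        f"phase centroid-perturb end: {mc.accepted} accepted, "
        f"{mc.rejected} rejected")
    return mc.current, mc.best, mc.stats()


def run_refine_phase(
    structure: Structure,
    loop_specs,
    config: ProtocolConfig,
    rng: np.random.Generator,
    tree: AnchoredFoldTree | None = None,
    constraints=(),
    reference: Structure | None = None,
    description: str = "TRAJ_0001",
    log: list | None = None,
) -> TrajectoryRecord:
    """Fullatom refinement with periodic design; returns the lowest-score
    structure with full analysis attached."""
    config.validate()
    log = log if log is not None else []
    if tree is None:
        tree = build_anchored_fold_tree(structure, loop_specs)
    weights = config.weights("fullatom")
    cutpoints = tree.cutpoints
    movable = _mobile_torsions(tree)
    resolved = tree.loops

    log.append("phase fullatom-refine start")
    score0 = score_structure(structure, weights, "fullatom", cutpoints,
                             constraints).total_score
    mc = _MonteCarlo(structure.copy(), score0, "refine", log)
    for cycle in range(config.refine_cycles):
        method = _closure_method(config.closure_mode, cycle)
        cand = _closed_candidate(mc, tree, config, rng, method, "refine")
        if cand is None:
            mc.rejected += 1
            continue
        region = detect_movable_region(cand, resolved)
        do_design = (config.design and config.design_spec is not None
                     and (cycle + 1) % config.refine_repack_interval == 0)
        if do_design:
            log.append(f"cycle {cycle + 1}: full design/repack")
            cand = design_sequence(cand, region, config.design_spec, weights,
                                   rng, anchor_keys=tree.anchor_keys)
        else:
            cand = pack_rotamers(cand, region, weights, rng,
                                 schedule=QUICK_PACK_SCHEDULE)
        cand = minimize_torsions(cand, tree, movable, weights,
                                 representation="fullatom",
                                 cutpoints=cutpoints,
                                 constraints=constraints,
                                 max_iter=config.minimize_iters)
        cand = _reclose_all(cand, tree, config, capped=True)
        if cand is None:
            mc.rejected += 1
            continue
        s = score_structure(cand, weights, "fullatom", cutpoints,
                            constraints).total_score
        mc.consider(cand, s, config.temperature, rng)
    log.append(
        f"phase fullatom-refine end: {mc.accepted} accepted, "
        f"{mc.rejected} rejected")

    final = mc.best
    report = score_structure(final, weights, "fullatom", cutpoints,
                             constraints)
    metrics = MetricsRecord()
    if reference is not None:
        metrics = compute_rmsd_metrics(reference, final, resolved,
                                       moving_chain=tree.moving_chain)
    if len(final.chain_ids) >= 2:
        metrics = metrics.merge(analyze_interface(final, weights, cutpoints))
    loop_reports, lam = analyze_loops(final, resolved, weights, cutpoints)
    metrics.LAM_total = lam
    metrics.total_score = report.total_score
    metrics.description = description
    return TrajectoryRecord(final, report, metrics, loop_reports,
                            mc.stats(), log, description)


# ---------------------------------------------------------------------------
# benchmark and experiment drivers
# ---------------------------------------------------------------------------

def _discard_structure_information(structure, tree, config, rng, log):
    """Prediction-mode preprocessing: delete the mobile loop conformation
    (fresh Ramachandran draw, re-closed) and the movable-region side-chain
    conformations (reset to ideal template chis)."""
    loop = tree.loops[0]
    work = None
    for _ in range(config.retry_budget):
        cand = perturb_loop(structure, tree, loop, mode="randomize", rng=rng)
        res = ccd_close(cand, tree, loop, tolerance=config.closure_tolerance)
        if res.break_deviation < config.closure_tolerance:
            work = res.closed_structure
            break
    if work is None:
        raise ProtocolError("could not build a closed randomized start")
    region = detect_movable_region(work, tree.loops)
    for key in region:
        res = work.residue(key)
        if res.aa_type not in ("GLY", "ALA"):
            replace_sidechain(res, res.aa_type, ())
        elif res.aa_type == "ALA":
            replace_sidechain(res, "ALA", ())
    log.append("discarded loop conformation and movable side chains")
    return work


def run_benchmark(
    structure: Structure,
    loop_specs,
    config: ProtocolConfig,
    rng: np.random.Generator | None = None,
    mode: str = "prediction",
    description: str = "TOY_0001",
) -> TrajectoryRecord:
    """Benchmark driver.

    ``prediction`` deletes the loop conformation and movable side chains
    and runs both phases; ``relaxed_native`` starts from the intact input;
    ``conservative_relaxed_native`` additionally skips the centroid phase.
    RMSD metrics are computed against the unmodified input.
    """
    if mode not in ("prediction", "relaxed_native",
                    "conservative_relaxed_native"):
        raise ValidationError(f"unknown benchmark mode {mode!r}")
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    reference = structure.copy()
    tree = build_anchored_fold_tree(structure, loop_specs)
    log: list[str] = [f"benchmark mode {mode}"]

    work = structure.copy()
    if mode == "prediction":
        work = _discard_structure_information(work, tree, config, rng, log)
    skip_centroid = (mode == "conservative_relaxed_native"
                     or config.refine_only)
    if not skip_centroid:
        work, _, _ = run_perturb_phase(work, loop_specs, config, rng,
                                       tree=tree, log=log)
    return run_refine_phase(work, loop_specs, config, rng, tree=tree,
                            reference=reference, description=description,
                            log=log)


def run_displacement_experiment(
    structure: Structure,
    loop_specs,
    config: ProtocolConfig,
    rng: np.random.Generator | None = None,
    description: str = "DISP_0001",
) -> TrajectoryRecord:
    """Anchor-displacement control: translate the moving side to a random
    position within +-1 A per axis, free the anchor (standard loop fold
    tree), and restrain its CA to the original position through the four
    closest cross-interface alpha carbons (harmonic, 0.5 at 1 A)."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    reference = structure.copy()
    anchored_tree = build_anchored_fold_tree(structure, loop_specs)
    anchor_key = anchored_tree.anchor_keys[0]
    constraints = make_displacement_constraints(structure, anchor_key, 4)

    work = structure.copy()
    shift = draw_displacement(rng)
    for res in work.residues(anchored_tree.moving_chain):
        for a in res.atoms:
            a.position = a.position + shift
    log = [f"displaced moving chain by {np.round(shift, 3).tolist()}",
           "anchor mobile: standard loop fold tree with 4 CA constraints"]

    tree = build_standard_fold_tree(work, loop_specs, anchor_mobile=True)
    if not config.refine_only:
        work, _, _ = run_perturb_phase(work, loop_specs, config, rng,
                                       tree=tree, constraints=constraints,
                                       log=log)
    record = run_refine_phase(work, loop_specs, config, rng, tree=tree,
                              constraints=constraints, reference=reference,
                              description=description, log=log)
    return record


def run_trajectories(
    structure: Structure,
    loop_specs,
    config: ProtocolConfig,
    nstruct: int,
    mode: str = "prediction",
    tag: str = "TOY",
) -> list[TrajectoryRecord]:
    """nstruct independent trajectories with derived seeds and
    zero-padded description labels (TAG_0001, TAG_0002, ...)."""
    records = []
    for i in range(nstruct):
        rng = np.random.default_rng((config.seed + 7919 * i) % (2**31 - 1))
        description = f"{tag}_{i + 1:04d}"
        if mode == "displaced":
            rec = run_displacement_experiment(structure, loop_specs, config,
                                              rng, description)
        else:
            rec = run_benchmark(structure, loop_specs, config, rng, mode,
                                description)
        records.append(rec)
    return records
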