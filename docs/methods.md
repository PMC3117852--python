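# Methods

This note records the models, parameter choices and numerical conventions
behind `anchorloop`, and what the synthetic test system does and does not
establish.

## Kinematic model

Residues are identified by `(chain, number, insertion_code)` in author
numbering; insertion-code residues count as loop positions. The fold tree
is a directed spanning structure: peptide edges propagate coordinates
forward or backward along the chain, jumps carry rigid transforms between
noncontiguous residues, and a cutpoint per mobile loop stops propagation.

The anchored tree roots in the target chain, jumps to the first anchor
residue from the target residue with the nearest CA (a deterministic
choice; any target residue would do, since the target is rigid), builds
the scaffold N-side backward from the anchor, and attaches the scaffold
C-side to the N-side core by a rigid intra-scaffold jump so that the
scaffold stays one rigid body. The default cutpoint is the loop residue
immediately C-terminal of the anchor span, which maximizes the number of
torsions contributing to rigid-body motion; the C-terminal loop half is
built backward from the scaffold toward the cutpoint. An anchor at a loop
terminus is rejected (no room for the cutpoint / too few mobile residues
on the cutpoint side). Plain (non-anchored) loops use the standard
jump-across + mid-loop-cutpoint tree and are supported as secondary loops,
default off.

Torsion changes are applied as exact axis rotations of the atoms
downstream of the changed bond, with absolute target angles re-measured
between successive rotations; atoms not downstream are bitwise untouched.
Convention details worth knowing:

* phi moves the residue's own C/O/CB/side chain plus everything
  downstream (the side chain rides the phi rotation, keeping the
  N–CA–C/CB geometry rigid);
* psi moves only downstream residues — the carbonyl O is attached to its
  own residue's N/CA/C frame rather than to the next residue's N, so psi
  does not re-orient O. This sacrifices exact carbonyl planarity with
  respect to the following residue in exchange for strictly local,
  branch-free update rules; the hydrogen-bond term tolerates it, and
  peptide-bond geometry itself is controlled by the closure machinery and
  the chainbreak term;
* the psi of the cutpoint residue and the phi of its successor drive
  nothing real in the tree (their roles are taken by the virtual
  continuation atoms during closure) and are skipped if set.

Ideal internal geometry: N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, angles
N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°. These values build the
fixtures, the virtual cutpoint atoms and the closure conditions, and
1.329 Å is the reference the loop analyzer flags peptide bonds against
(threshold 0.02 Å).

## Loop closure

**CCD.** Each cutpoint carries three virtual/real atom pairs: the real
C of the cutpoint residue against a virtual C continued from the next
residue's stub, and virtual N/CA continued from the cutpoint residue
against the real N/CA of the next residue. The break deviation is the
root-sum-square of the three pair separations; when it is below the
tolerance the three real cross-cutpoint distances deviate from ideal by
no more than the same amount (so a tolerance of τ guarantees a chainbreak
term ≤ 3τ²). A sweep visits the mobile non-anchor phi/psi torsions in
chain order (alternating direction between sweeps); each step applies the
closed-form rotation angle that minimizes the summed squared pair
separations, optionally clamped to a per-move cap (10° in refinement,
where moves are deliberately softened). The objective is non-increasing
per step, hence per sweep. Defaults: tolerance 0.1 Å, 100 sweeps. CCD can
stall in a shallow local minimum of its point-matching objective a few
percent of the time; uncapped closure then polishes by solving one of a
few deterministic pivot-triples exactly (below), which in practice closes
every randomly opened toy loop.

**KIC.** Non-pivot mobile torsions are resampled from the Ramachandran
model; the phi/psi of three pivot residues (by default the first,
middle-most and last mobile non-anchor residues; optionally a random
eligible triple) are solved so that the cutpoint is exactly continuous.
The solver drives four conditions — peptide bond length 1.329 Å, the two
flanking bond angles, and trans omega — to zero by trust-region least
squares on a small workspace that tracks only the break atoms and pivot
axes (angle residuals are scaled by 1.329 Å/rad so all residuals share an
Angstrom-like scale). Multi-start (current torsions plus Ramachandran
draws) enumerates distinct solutions; one is chosen uniformly at random.
No converged start is a retry signal (`KICNoSolution`): the caller
resamples, which is how the protocol uses it (20 retries per cycle, then
the cycle counts as rejected). Anchor residues are excluded from pivots
and from non-pivot resampling. Closure forces the cutpoint peptide trans;
cis peptides can survive anywhere else.

**Ramachandran model.** Three residue classes (general, glycine,
proline) of 2–4 Gaussian basins each, parameters in the versioned
`data/rama.json`. Samples are truncated at 2.5σ so every draw lies inside
a basin; small moves are clamped back to the nearest basin boundary; the
score is the floored −log density. This compact parametric stand-in keeps
the artifact self-contained; it is coarser than a statistical torsion
library and is one reason no claim is made about absolute conformational
propensities.

## Scorefunction

Two presets (shipped as plain-text `term weight` files):

| term | centroid | fullatom | form |
|---|---|---|---|
| steric_rep / steric_atr | 1.0 / 0.2 | 0.55 / 0.8 | 12-6 on Σ of vdW radii (C 1.70, N 1.55, O 1.52, S 1.80 Å), ε 0.12, cutoff 8 Å, linear ramp inside 0.6σ capped at 100 per pair; centroid mode uses one interaction center per residue (CB, CA for glycine) with per-amino-acid radii from `data/radii.json` |
| rama | 0.6 | 0.45 | Ramachandran −log density |
| omega | 0.5 | 0.5 | (Δ/20°)² about 180° (0° also allowed for proline) |
| hbond | – | 1.2 | −Gaussian(d − 2.9 Å, σ 0.35) × Gaussian(θ − 120°, σ 35°) over donor/acceptor heavy-atom pairs (no explicit hydrogens; θ at the acceptor base) |
| rotamer_pref | – | 0.56 | log of the grid-rotamer count per identity (uniform weights); fills the role usually called "dunbrack" and is accepted under that alias in weights files |
| chainbreak | 2.0 | 2.0 | Σ of squared deviations of the three cross-cutpoint distances from ideal |
| constraint | 1.0 | 1.0 | Σ w·(d−d₀)²; displacement constraints use w = 0.5, i.e. half a unit at 1 Å |

Nonbonded exclusions: same residue and chain-adjacent residues, for both
sterics and hydrogen bonds. All terms except constraints are invariant
under global rigid motion. The potential is intentionally self-contained
and makes no attempt to reproduce any published all-atom energy; scores
are comparable only within this package.

Torsion minimization is L-BFGS-B with two-point numeric gradients over
the mobile phi/psi (omega held trans), best-evaluation tracking so the
returned structure never scores worse than the input. Because
minimization can trade a little chainbreak against other terms, each
Monte Carlo cycle re-closes all loops after minimizing and rejects the
cycle if a loop will not re-close.

## Packing and design

The movable region is loops ∪ residues with CB within 10 Å of a loop CB ∪
residues with any heavy atom within 5 Å of the other chain (both radii
configurable; values are conventional contact definitions). The rotamer
library is backbone-independent: chi1/chi2 on the −60/60/180 grid, pruned
when a built side chain folds back within 2.4 Å of its own backbone, plus
the input conformation (always candidate 0, so a no-op pack is bitwise
exact). Packing is simulated annealing over that space, warm-started from
a greedy single pass so the annealed result can never be worse than
greedy. The pair-decomposed packer energy (sterics + H-bonds +
rotamer preference + the identity-dependent rama/omega one-body terms)
matches the full scorefunction exactly for the atoms packing can move,
which is what makes the exhaustive-enumeration equivalence tests possible.
Design expands identity choices per position from a plain-text design
spec; anchor positions are never designable (the anchor carries its donor
identity by construction).

## Protocol

Per perturbation cycle (centroid): perturb (Ramachandran randomization,
or fragments when a store is supplied) → close (CCD and KIC alternate in
`both` mode; the mixing rule is a package choice) → minimize → re-close →
Metropolis at temperature 0.8. Per refinement cycle (fullatom): small
move (±5° clamped to basins) → capped CCD or pinned-non-pivot KIC →
repack the movable region (design instead every
`refine_repack_interval` cycles when design is on; the interval must be
≥ 50 and ≤ refine_cycles/4) → minimize → re-close → Metropolis. Fragment
moves never run during refinement. The reported structure is the
lowest-score accepted structure (recover-lowest). Temperature 0.8 is a
declared default — constant within each phase.

Benchmark modes: `prediction` first deletes the mobile loop conformation
(fresh Ramachandran draw, re-closed — a random draw avoids biasing the
start toward any particular conformation) and resets movable-region side
chains to ideal template chis; `relaxed_native` skips the deletion;
`conservative_relaxed_native` additionally skips the centroid phase. RMSD
metrics are always computed against the unmodified input.

The displacement experiment translates the moving side by a uniform draw
from the ±1 Å cube (volume 8 Å³), switches to the standard loop tree so
the anchor becomes mobile with its loop, and restrains the anchor CA to
its original position through harmonic constraints to the four closest
cross-interface alpha carbons (0.5 score units at 1 Å). Rooting the
displaced run in the standard tree is this package's way of "letting the
anchor move": jump degrees of freedom are deliberately out of scope, so
anchor motion relative to the target must flow through loop torsions.

## Analysis

`ch2_CA_RMSD` (LRMSD) superposes the whole model on the nonmoving chain's
CA atoms before measuring the moving chain, so it reads as a rigid-body
placement error; `I_sup_bb_RMSD` (IRMSD) takes backbone atoms of residues
with any heavy atom within 5 Å of the other chain (a declared cutoff —
the interface set is defined on the reference). SASA is Shrake–Rupley
via biotite with 960 points per atom and the per-element radius table,
probe 1.4 Å — deterministic for a fixed quadrature. `dG_separated`
re-scores the complex with the second chain translated 500 Å away,
without repacking the separated state (the simpler default; repacking
would lower the separated reference). Buried unsatisfied polar atoms:
donor/acceptor heavy atoms on interface residues with SASA < 0.01 Ų and
no polar partner within 3.5 Å. `dSASA_int` is two-sided burial
(SASA(ch1) + SASA(ch2) − SASA(complex)). `LAM_total` is the weighted sum
of rama, rotamer preference, omega and chainbreak over loop residues.

## The synthetic system, and what passing tests show

`make_toy_anchored_complex` builds, at exactly ideal geometry, a
12-residue poly-alanine target helix and a 20-residue scaffold whose
central 9-residue loop carries one leucine anchor; the anchor CB is
placed 4 Å from a mid-helix target CB with the scaffold body oriented
away and pushed out until no interchain atom pair is closer than 2.6 Å.
Loop torsions are drawn from the Ramachandran basins, rejecting draws
that fold the scaffold onto itself. Everything is a pure function of the
seed. Sizes (12/20/9) were chosen as the smallest system with a genuine
two-chain interface, a closable loop with ≥ 3 mobile residues on either
side of the anchor, and sub-second score evaluations.

What the fixture does **not** emulate: real side-chain diversity (it is
poly-alanine plus one leucine), coordinate noise, packed funnel-shaped
interfaces, multi-loop interplay, and the size of real complexes. Green
tests therefore establish the *contracts* — anchor rigidity, closure
accuracy, packer optimality, metric definitions, Monte Carlo behavior —
not predictive accuracy on crystallographic complexes, which would
require a fuller energy model and orders of magnitude more sampling.

The acceptance script runs 100-opening CCD reclosure, 12 verified KIC
closures, 10,000 Metropolis trials, 20,000 displacement draws, 3
prediction and 2 relaxed-native trajectories at 25 perturbation + 25
refinement cycles; these sizes keep a complete re-run within a few
minutes on one CPU while leaving the measured quantities stable across
seeds.

## Known limitations

* No jump minimization or rigid-body moves: all relative motion flows
  through loop torsions by design.
* No insertions or deletions: grafting replaces exactly as many scaffold
  residues as the anchor has; length variants are produced by editing the
  spec, not the graft.
* Proline backbone sampling uses the restricted basin model but the ring
  is not closed kinematically (ring chis are never sampled).
* Carbonyl-oxygen orientation is frame-attached (see kinematics above).
* The packer's omega one-body term does not special-case cutpoint
  residues; it matters only when designing proline at a cutpoint.
* `analyze_interface` treats the first two chains as the interface pair.
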