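"""Scan structures for candidate anchor regions.

An anchor-friendly site is a loop-dominated stretch of one chain whose
residues make many contacts across a chain-chain interface.  Secondary
structure is assigned three-state (helix / strand / loop) from backbone
hydrogen-bond patterns using the classic electrostatic dipole model with
the conventional -0.5 kcal/mol cutoff; cross-interface neighbors are
counted between residue interaction centers (CB, CA for glycine).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .structure import ResidueKey, ResidueSpan, Structure

HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_Q1Q2_F = 0.084 * 332.0


@dataclass
class ResidueReport:
    key: ResidueKey
    ss: str                      # H | E | L
    cross_neighbors: int
    aa_type: str = ""


@dataclass
class RegionSummary:
    span: ResidueSpan
    length: int
    loop_fraction: float
    max_neighbors: int
    total_neighbors: int


# ---------------------------------------------------------------------------
# secondary structure
# ---------------------------------------------------------------------------

def _backbone_hbond_energies(structure: Structure):
    """Kabsch-Sander electrostatic H-bond energies between backbone
    CO (acceptor residue) and NH (donor residue) pairs.

    The amide hydrogen is placed 1.0 A from N, anti-parallel to the
    preceding residue's carbonyl.  Returns {(donor_key, acceptor_key): E}
    for pairs below the cutoff.
    """
    entries = []
    for cid in structure.chain_ids:
        chain = structure.residues(cid)
        for i, res in enumerate(chain):
            n = res.atom("N").position
            ca = res.atom("CA").position
            c = res.atom("C").position
            o = res.atom("O").position if res.has_atom("O") else None
            h = None
            if i > 0 and res.aa_type != "PRO":
                prev = chain[i - 1]
                if prev.has_atom("C") and prev.has_atom("O"):
                    v = prev.atom("C").position - prev.atom("O").position
                    h = n + v / np.linalg.norm(v)
            entries.append((res.key, cid, i, n, h, c, o, ca))

    out = {}
    for dk, dc, di, n, h, _, _, _ in entries:
        if h is None:
            continue
        for ak, ac, ai, _, _, c, o, _ in entries:
            if o is None:
                continue
            if dk == ak or (dc == ac and abs(di - ai) < 2):
                continue
            d_on = np.linalg.norm(o - n)
            if d_on > 5.2:
                continue
            e = _Q1Q2_F * (1.0 / d_on
                           + 1.0 / np.linalg.norm(c - h)
                           - 1.0 / np.linalg.norm(o - h)
                           - 1.0 / np.linalg.norm(c - n))
            if e < HBOND_ENERGY_CUTOFF:
                out[(dk, ak)] = float(e)
    return out


def assign_secondary_structure(structure: Structure) -> dict[ResidueKey, str]:
    """Three-state assignment: helix from consecutive i->i+4 turns,
    strand from parallel/antiparallel bridge patterns, else loop."""
    hbonds = _backbone_hbond_energies(structure)
    codes = {r.key: "L" for r in structure.residues()}

    for cid in structure.chain_ids:
        chain = [r.key for r in structure.residues(cid)]
        n = len(chain)
        if n < 3:
            continue
        turn = [False] * n
        for i in range(n - 4):
            # CO of residue i accepts from NH of residue i+4
            if (chain[i + 4], chain[i]) in hbonds:
                turn[i] = True
        for i in range(n - 1):
            if turn[i] and turn[i + 1]:
                for j in range(i + 1, min(i + 5, n)):
                    codes[chain[j]] = "H"

    # bridges (strand ladders)
    all_keys = []
    for cid in structure.chain_ids:
        chain = [r.key for r in structure.residues(cid)]
        for i, k in enumerate(chain):
            all_keys.append((cid, i, k, chain))
    for cid_i, i, ki, chain_i in all_keys:
        for cid_j, j, kj, chain_j in all_keys:
            if (cid_i, i) >= (cid_j, j):
                continue
            if cid_i == cid_j and abs(i - j) < 3:
                continue
            anti = (kj, ki) in hbonds and (ki, kj) in hbonds
            para = False
            if 0 < i < len(chain_i) - 1:
                para = ((chain_i[i + 1], kj) in hbonds
                        and (kj, chain_i[i - 1]) in hbonds)
            if 0 < j < len(chain_j) - 1 and not para:
                para = ((chain_j[j + 1], ki) in hbonds
                        and (ki, chain_j[j - 1]) in hbonds)
            if anti or para:
                if codes[ki] != "H":
                    codes[ki] = "E"
                if codes[kj] != "H":
                    codes[kj] = "E"
    return codes


# ---------------------------------------------------------------------------
# cross-interface neighbors
# ---------------------------------------------------------------------------

def count_cross_interface_neighbors(structure: Structure,
                                    radius: float = 8.0
                                    ) -> dict[ResidueKey, int]:
    """Per residue: how many residues on other chains have their
    interaction center (CB, CA for glycine) within ``radius``."""
    keys, centers, chains = [], [], []
    for r in structure.residues():
        name = "CA" if r.aa_type == "GLY" or not r.has_atom("CB") else "CB"
        keys.append(r.key)
        centers.append(r.atom(name).position)
        chains.append(r.key[0])
    centers = np.array(centers)
    chains = np.array(chains)
    d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=2)
    cross = chains[:, None] != chains[None, :]
    counts = ((d <= radius) & cross).sum(axis=1)
    return {k: int(c) for k, c in zip(keys, counts)}


def per_residue_reports(structure: Structure, radius: float = 8.0
                        ) -> list[ResidueReport]:
    ss = assign_secondary_structure(structure)
    counts = count_cross_interface_neighbors(structure, radius)
    return [ResidueReport(r.key, ss[r.key], counts[r.key], r.aa_type)
            for r in structure.residues()]


# ---------------------------------------------------------------------------
# region summaries
# ---------------------------------------------------------------------------

def summarize_regions(
    reports: list[ResidueReport],
    min_length: int = 4,
    min_loop_fraction: float = 0.75,
    min_neighbors: int = 5,
) -> list[RegionSummary]:
    """Maximal contiguous loop-dominated runs meeting all thresholds,
    ranked by total cross-interface neighbors (descending).

    Runs of pure loop are found first; adjacent runs separated by a single
    non-loop residue are merged while the merged loop fraction stays at or
    above the threshold.
    """
    by_chain: dict[str, list[ResidueReport]] = {}
    for rep in reports:
        by_chain.setdefault(rep.key[0], []).append(rep)

    regions = []
    for chain_reports in by_chain.values():
        runs = []  # (start_idx, stop_idx) of pure-L runs
        i = 0
        n = len(chain_reports)
        while i < n:
            if chain_reports[i].ss == "L":
                j = i
                while j + 1 < n and chain_reports[j + 1].ss == "L":
                    j += 1
                runs.append([i, j])
                i = j + 1
            else:
                i += 1
        # merge across single non-loop gaps while the fraction holds
        merged = True
        while merged and len(runs) > 1:
            merged = False
            for a in range(len(runs) - 1):
                lo, hi = runs[a], runs[a + 1]
                if hi[0] - lo[1] == 2:
                    length = hi[1] - lo[0] + 1
                    n_loop = sum(1 for r in chain_reports[lo[0]:hi[1] + 1]
                                 if r.ss == "L")
                    if n_loop / length >= min_loop_fraction:
                        runs[a] = [lo[0], hi[1]]
                        del runs[a + 1]
                        merged = True
                        break
        for lo, hi in runs:
            window = chain_reports[lo:hi + 1]
            length = len(window)
            if length < min_length:
                continue
            n_loop = sum(1 for r in window if r.ss == "L")
            frac = n_loop / length
            if frac < min_loop_fraction:
                continue
            counts = [r.cross_neighbors for r in window]
            if max(counts) < min_neighbors:
                continue
            first, last = window[0].key, window[-1].key
            regions.append(RegionSummary(
                ResidueSpan.of(first[0], (first[1], first[2]),
                               (last[1], last[2])),
                length, frac, max(counts), sum(counts)))
    regions.sort(key=lambda r: -r.total_neighbors)
    return regions


def suggest_loop_span(structure: Structure, anchor: ResidueKey,
                      ss_codes: dict[ResidueKey, str] | None = None
                      ) -> ResidueSpan:
    """Accumulate residues out from the anchor in both directions until
    non-loop secondary structure (or a chain terminus) is encountered."""
    if ss_codes is None:
        ss_codes = assign_secondary_structure(structure)
    if ss_codes.get(anchor) != "L":
        raise ValidationError(
            f"anchor {anchor} is not in a loop (assigned "
            f"{ss_codes.get(anchor)!r})")
    chain = [r.key for r in structure.residues(anchor[0])]
    i = chain.index(anchor)
    lo = i
    while lo - 1 >= 0 and ss_codes[chain[lo - 1]] == "L":
        lo -= 1
    hi = i
    while hi + 1 < len(chain) and ss_codes[chain[hi + 1]] == "L":
        hi += 1
    first, last = chain[lo], chain[hi]
    return ResidueSpan.of(anchor[0], (first[1], first[2]), (last[1], last[2]))
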