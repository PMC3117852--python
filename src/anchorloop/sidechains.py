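"""Side-chain geometry: ideal residue templates and chi manipulation.

Heavy-atom templates come from biotite's chemical-component library.  A
side chain is rebuilt by superposing the template N/CA/C triad onto the
residue backbone and then rotating the template about its chi axes.  Only
chi1 and chi2 are treated as rotatable (the packing module samples them on
a coarse grid); more distal chis keep their template values.
"""

from __future__ import annotations

from functools import lru_cache

import biotite.structure.info as struc_info
import numpy as np

from .errors import ValidationError
from .geometry import dihedral, kabsch, rotation_about_axis
from .structure import Atom, Residue

BACKBONE_SET = frozenset({"N", "CA", "C", "O", "OXT"})

# chi1/chi2 definitions: the distal atom of each dihedral
# chi1 = N-CA-CB-<g>, chi2 = CA-CB-<g>-<d>
CHI_GAMMA = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "CYS": "SG", "GLN": "CG",
    "GLU": "CG", "HIS": "CG", "ILE": "CG1", "LEU": "CG", "LYS": "CG",
    "MET": "CG", "PHE": "CG", "SER": "OG", "THR": "OG1", "TRP": "CG",
    "TYR": "CG", "VAL": "CG1",
}
CHI_DELTA = {
    "ARG": "CD", "ASN": "OD1", "ASP": "OD1", "GLN": "CD", "GLU": "CD",
    "HIS": "ND1", "ILE": "CD1", "LEU": "CD1", "LYS": "CD", "MET": "SD",
    "PHE": "CD1", "TRP": "CD1", "TYR": "CD1",
}

STANDARD_AAS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)


@lru_cache(maxsize=None)
def _template(aa: str):
    """Heavy-atom ideal template: (names, elements, coords, bonds)."""
    if aa not in STANDARD_AAS:
        raise ValidationError(f"unknown amino acid {aa!r}")
    arr = struc_info.residue(aa)
    heavy = (arr.element != "H") & (arr.atom_name != "OXT")
    idx = np.where(heavy)[0]
    names = tuple(arr.atom_name[idx])
    elements = tuple(arr.element[idx])
    coords = arr.coord[idx].astype(float)
    remap = {old: new for new, old in enumerate(idx)}
    bonds = set()
    for a, b, _ in arr.bonds.as_array():
        if a in remap and b in remap:
            bonds.add((remap[a], remap[b]))
    return names, elements, coords, frozenset(bonds)


@lru_cache(maxsize=None)
def _adjacency(aa: str) -> dict[str, tuple[str, ...]]:
    names, _, _, bonds = _template(aa)
    adj: dict[str, set[str]] = {n: set() for n in names}
    for a, b in bonds:
        adj[names[a]].add(names[b])
        adj[names[b]].add(names[a])
    return {k: tuple(sorted(v)) for k, v in adj.items()}


@lru_cache(maxsize=None)
def _downstream_of_bond(aa: str, from_atom: str, through_atom: str) -> tuple[str, ...]:
    """Atoms reachable from ``through_atom`` without crossing back over
    ``from_atom`` -- the set rotated by the chi about that bond."""
    adj = _adjacency(aa)
    seen = {from_atom, through_atom}
    stack = [through_atom]
    out = []
    while stack:
        cur = stack.pop()
        for nxt in adj[cur]:
            if nxt not in seen:
                seen.add(nxt)
                out.append(nxt)
                stack.append(nxt)
    return tuple(sorted(out))


def n_rotatable_chis(aa: str) -> int:
    if aa in ("ALA", "GLY", "PRO"):
        return 0  # proline's ring chi is not sampled
    n = 1 if aa in CHI_GAMMA else 0
    if aa in CHI_DELTA:
        n = 2
    return n


def chi_axes(aa: str) -> list[tuple[str, str, str, str]]:
    """Dihedral atom quadruples for the rotatable chis of ``aa``."""
    axes = []
    if aa in CHI_GAMMA and n_rotatable_chis(aa) >= 1:
        axes.append(("N", "CA", "CB", CHI_GAMMA[aa]))
    if aa in CHI_DELTA and n_rotatable_chis(aa) >= 2:
        axes.append(("CA", "CB", CHI_GAMMA[aa], CHI_DELTA[aa]))
    return axes


def measure_chis(residue: Residue) -> tuple[float, ...]:
    chis = []
    for quad in chi_axes(residue.aa_type):
        try:
            pts = [residue.atom(n).position for n in quad]
        except Exception:
            return tuple(chis)
        chis.append(dihedral(*pts))
    return tuple(chis)


def build_residue_atoms(
    backbone: dict[str, np.ndarray],
    aa: str,
    chis: tuple[float, ...] = (),
    include_backbone: bool = False,
) -> list[Atom]:
    """Build heavy atoms for ``aa`` on the given backbone.

    ``backbone`` must contain N, CA and C positions.  The ideal template is
    rigidly fit onto that triad; chi1/chi2 are then set to the requested
    values.  Returns side-chain atoms (plus O), or all atoms when
    ``include_backbone``.
    """
    names, elements, coords, _ = _template(aa)
    name_to_i = {n: i for i, n in enumerate(names)}
    tri = np.array([coords[name_to_i[n]] for n in ("N", "CA", "C")])
    ref = np.array([backbone[n] for n in ("N", "CA", "C")])
    R, t = kabsch(ref, tri)
    placed = coords @ R.T + t

    for chi_i, quad in enumerate(chi_axes(aa)):
        if chi_i >= len(chis):
            break
        p = [placed[name_to_i[n]] for n in quad]
        current = dihedral(*p)
        delta = chis[chi_i] - current
        Rr, tr = rotation_about_axis(p[1], p[2] - p[1], delta)
        movers = _downstream_of_bond(aa, quad[1], quad[2])
        for n in movers:
            i = name_to_i[n]
            placed[i] = Rr @ placed[i] + tr

    out = []
    for i, n in enumerate(names):
        if not include_backbone and n in ("N", "CA", "C", "O"):
            continue
        out.append(Atom(n, str(elements[i]), placed[i].copy()))
    return out


def replace_sidechain(residue: Residue, aa: str, chis: tuple[float, ...]) -> None:
    """Swap the residue's identity/side chain in place, keeping N/CA/C/O."""
    backbone = {n: residue.atom(n).position for n in ("N", "CA", "C")}
    if residue.has_atom("O"):
        backbone["O"] = residue.atom("O").position
    new_atoms = [a for a in residue.atoms if a.name in ("N", "CA", "C", "O")]
    new_atoms += build_residue_atoms(backbone, aa, chis)
    residue.aa_type = aa
    residue.atoms = new_atoms


def intra_clash(
    backbone: dict[str, np.ndarray],
    sidechain_atoms: list[Atom],
    threshold: float = 2.4,
) -> bool:
    """True when a built side chain folds back onto its own backbone.

    Grid rotamers whose atoms beyond CB come within ``threshold`` Angstrom
    of the residue's own N, C or O are pruned by the packing module.
    """
    probes = [a.position for a in sidechain_atoms if a.name not in ("CB", "O")]
    if not probes:
        return False
    targets = [backbone[n] for n in ("N", "C", "O") if n in backbone]
    for p in probes:
        for t in targets:
            if np.linalg.norm(p - t) < threshold:
                return True
    return False
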