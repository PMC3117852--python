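"""Hierarchical coordinate model and PDB input/output.

Residues are identified by ``(chain_id, number, insertion_code)`` exactly as
in the source file; the package never renumbers, because loop and anchor
spans are quoted in author numbering and insertion-code residues (36, 36A,
36B ...) count as distinct loop positions.

Reading goes through :mod:`gemmi`; HETATM records (waters, ligands,
cryoprotectants) are dropped by default and only blank/'A' altlocs are kept,
mirroring the usual preparation of two-chain complexes for modeling.  The
writer emits plain fixed-width ATOM records so that analysis footer blocks
can be appended to the same file.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

from .errors import PDBParseError, SpanLookupError, StructureError, ValidationError

BACKBONE_ATOMS = ("N", "CA", "C")

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

ResidueKey = tuple[str, int, str]


@dataclass
class Atom:
    """A single atom: PDB name, element symbol and Angstrom position."""

    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not self.name:
            raise StructureError("atom with empty name")
        if not np.all(np.isfinite(self.position)):
            raise StructureError(f"non-finite coordinates for atom {self.name}")

    def copy(self) -> "Atom":
        new = object.__new__(Atom)
        new.name = self.name
        new.element = self.element
        new.position = self.position.copy()
        new.occupancy = self.occupancy
        new.b_factor = self.b_factor
        return new


@dataclass
class Residue:
    chain_id: str
    number: int
    insertion_code: str = ""
    aa_type: str = "ALA"
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return (self.chain_id, self.number, self.insertion_code)

    @property
    def label(self) -> str:
        return f"{self.chain_id}{self.number}{self.insertion_code}"

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise StructureError(f"residue {self.label} has no atom {name!r}")

    def has_atom(self, name: str) -> bool:
        return any(a.name == name for a in self.atoms)

    def has_backbone(self) -> bool:
        return all(self.has_atom(n) for n in BACKBONE_ATOMS)

    def interaction_center(self) -> Atom:
        """Residue-level interaction center: CB, or CA for glycine."""
        name = "CA" if self.aa_type == "GLY" else "CB"
        if not self.has_atom(name):
            name = "CA"
        return self.atom(name)

    def sidechain_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.name not in ("N", "CA", "C", "O")]

    def one_letter(self) -> str:
        return AA3_TO_1.get(self.aa_type, "X")

    def copy(self) -> "Residue":
        return Residue(self.chain_id, self.number, self.insertion_code,
                       self.aa_type, [a.copy() for a in self.atoms])


@dataclass(frozen=True)
class ResidueSpan:
    """An inclusive residue range on one chain.

    ``start``/``stop`` are ``(number, insertion_code)`` pairs; plain integers
    are accepted and treated as blank insertion codes.
    """

    chain_id: str
    start: tuple[int, str]
    stop: tuple[int, str]

    @staticmethod
    def of(chain_id: str, start, stop) -> "ResidueSpan":
        def norm(x):
            if isinstance(x, int):
                return (x, "")
            return (int(x[0]), str(x[1]))
        return ResidueSpan(chain_id, norm(start), norm(stop))


class Structure:
    """Ordered chains of ordered residues."""

    def __init__(self, chains: dict[str, list[Residue]] | None = None):
        self.chains: dict[str, list[Residue]] = dict(chains or {})
        if chains is not None and not self.chains:
            raise StructureError("structure must contain at least one chain")
        self._index: dict[ResidueKey, Residue] = {}
        self._reindex()

    def _reindex(self) -> None:
        self._index = {}
        self._chain_pos: dict[ResidueKey, int] = {}
        for cid, residues in self.chains.items():
            for i, r in enumerate(residues):
                if r.chain_id != cid:
                    raise StructureError(
                        f"residue {r.label} filed under chain {cid}")
                if r.key in self._index:
                    raise StructureError(f"duplicate residue {r.label}")
                self._index[r.key] = r
                self._chain_pos[r.key] = i

    # -- construction -----------------------------------------------------
    def add_residue(self, residue: Residue) -> None:
        if residue.key in self._index:
            raise StructureError(f"duplicate residue {residue.label}")
        chain = self.chains.setdefault(residue.chain_id, [])
        chain.append(residue)
        self._index[residue.key] = residue
        self._chain_pos[residue.key] = len(chain) - 1

    def copy(self) -> "Structure":
        s = Structure()
        for cid, residues in self.chains.items():
            s.chains[cid] = [r.copy() for r in residues]
        s._reindex()
        return s

    # -- access -----------------------------------------------------------
    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains.keys())

    def residues(self, chain_id: str | None = None) -> list[Residue]:
        if chain_id is None:
            return [r for residues in self.chains.values() for r in residues]
        if chain_id not in self.chains:
            raise SpanLookupError(f"no chain {chain_id!r}")
        return self.chains[chain_id]

    def residue(self, key: ResidueKey) -> Residue:
        try:
            return self._index[key]
        except KeyError:
            raise SpanLookupError(
                f"no residue {key[0]}{key[1]}{key[2]}") from None

    def has_residue(self, key: ResidueKey) -> bool:
        return key in self._index

    def atoms(self) -> Iterator[tuple[Residue, Atom]]:
        for r in self.residues():
            for a in r.atoms:
                yield r, a

    def coords(self) -> np.ndarray:
        return np.array([a.position for _, a in self.atoms()])

    def chain_index(self, key: ResidueKey) -> int:
        """Position of a residue within its chain (file order)."""
        try:
            return self._chain_pos[key]
        except KeyError:
            raise SpanLookupError(f"no residue {key}") from None

    def neighbor_key(self, key: ResidueKey, offset: int) -> ResidueKey | None:
        """Chain-order neighbor (``offset`` = +-1 ...), or None at termini."""
        chain = self.chains[key[0]]
        i = self.chain_index(key) + offset
        if 0 <= i < len(chain):
            return chain[i].key
        return None


def select_span(structure: Structure, span: ResidueSpan) -> list[Residue]:
    """All residues between the span endpoints inclusive, in chain order.

    Insertion-code residues between the endpoints count, so a span like
    36-40 can contain more than ``stop - start + 1`` residues.
    """
    chain = structure.residues(span.chain_id)
    start_key = (span.chain_id, *span.start)
    stop_key = (span.chain_id, *span.stop)
    i0 = i1 = None
    for i, r in enumerate(chain):
        if r.key == start_key:
            i0 = i
        if r.key == stop_key:
            i1 = i
    if i0 is None or i1 is None:
        missing = span.start if i0 is None else span.stop
        raise SpanLookupError(
            f"span endpoint {span.chain_id}{missing[0]}{missing[1]} not found")
    if i1 < i0:
        raise ValidationError(
            f"span endpoints reversed: {span.start} after {span.stop}")
    return chain[i0:i1 + 1]


def span_keys(structure: Structure, span: ResidueSpan) -> list[ResidueKey]:
    return [r.key for r in select_span(structure, span)]


# -- PDB I/O ---------------------------------------------------------------

def read_pdb(path, keep_hetero: bool = False) -> Structure:
    """Parse a PDB file into a :class:`Structure`.

    HETATM records are skipped unless ``keep_hetero``; altlocs other than
    blank/'A' are dropped; every polymer residue must carry a complete
    N/CA/C backbone.
    """
    path = Path(path)
    if not path.exists():
        raise PDBParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise PDBParseError(f"{path}: no models / ATOM records found")
    st.setup_entities()
    model = st[0]
    out = Structure()
    for chain in model:
        for res in chain:
            if res.het_flag == "H" and not keep_hetero:
                continue
            icode = res.seqid.icode.strip()
            residue = Residue(chain.name, res.seqid.num, icode, res.name)
            for atom in res:
                if atom.altloc not in ("", "A", "\x00"):
                    continue
                residue.atoms.append(Atom(
                    atom.name,
                    atom.element.name.upper() or atom.name[0],
                    np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                    atom.occ,
                    atom.b_iso,
                ))
            if residue.atoms:
                out.add_residue(residue)
    if not out.chains:
        raise PDBParseError(f"{path}: no protein ATOM records")
    for cid, residues in out.chains.items():
        if not any(r.has_backbone() for r in residues):
            raise StructureError(
                f"chain {cid} has no backbone-complete residue")
        for r in residues:
            if not r.has_backbone():
                raise StructureError(
                    f"residue {r.label} is missing backbone atoms")
    return out


def format_atom_record(serial: int, residue: Residue, atom: Atom) -> str:
    name = atom.name
    # PDB column rules: 1-3 character names start in column 14
    if len(name) < 4:
        name = f" {name:<3s}"
    x, y, z = atom.position
    return (
        f"ATOM  {serial:>5d} {name:<4s}{' '}{residue.aa_type:<3s} "
        f"{residue.chain_id:1s}{residue.number:>4d}{residue.insertion_code or ' ':1s}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.b_factor:6.2f}"
        f"          {atom.element:>2s}"
    )


def write_pdb(structure: Structure, path, footer: Iterable[str] = ()) -> None:
    """Write fixed-width ATOM/TER/END records, appending optional analysis
    footer lines (score table, loop and interface analysis blocks) after
    END."""
    lines = []
    serial = 1
    for cid in structure.chain_ids:
        residues = structure.residues(cid)
        for r in residues:
            for a in r.atoms:
                lines.append(format_atom_record(serial, r, a))
                serial += 1
        last = residues[-1]
        lines.append(
            f"TER   {serial:>5d}      {last.aa_type:<3s} "
            f"{cid:1s}{last.number:>4d}{last.insertion_code or ' ':1s}")
        serial += 1
    lines.append("END")
    lines.extend(footer)
    Path(path).write_text("\n".join(lines) + "\n")
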