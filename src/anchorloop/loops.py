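"""Mobile-loop definitions.

A :class:`LoopSpec` names a flexible surface loop, the anchor span held
rigid against the binding target inside it (optional for plain, non-anchored
loops), and the chainbreak (cutpoint) position used during loop closure.
Spans are quoted in author numbering; insertion-code residues count as loop
positions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .errors import ValidationError
from .structure import ResidueKey, ResidueSpan, Structure, span_keys


@dataclass(frozen=True)
class LoopSpec:
    """One mobile loop: span, optional anchor span, optional cutpoint.

    ``cutpoint`` is the ``(number, insertion_code)`` of the loop residue on
    the N-terminal side of the break.  When omitted it defaults to the loop
    residue immediately C-terminal of the anchor (anchored loops) or the
    middle loop residue (plain loops).
    """

    loop: ResidueSpan
    anchor: ResidueSpan | None = None
    cutpoint: tuple[int, str] | None = None

    @staticmethod
    def of(chain_id, loop_start, loop_stop, anchor_start=None,
           anchor_stop=None, cutpoint=None) -> "LoopSpec":
        loop = ResidueSpan.of(chain_id, loop_start, loop_stop)
        anchor = None
        if anchor_start is not None:
            anchor = ResidueSpan.of(
                chain_id, anchor_start,
                anchor_stop if anchor_stop is not None else anchor_start)
        if isinstance(cutpoint, int):
            cutpoint = (cutpoint, "")
        return LoopSpec(loop, anchor, cutpoint)

    @property
    def chain_id(self) -> str:
        return self.loop.chain_id

    def resolve(self, structure: Structure) -> "ResolvedLoop":
        """Validate against a structure and resolve all spans to residue keys."""
        loop_keys = span_keys(structure, self.loop)
        anchor_keys: list[ResidueKey] = []
        if self.anchor is not None:
            if self.anchor.chain_id != self.loop.chain_id:
                raise ValidationError("anchor span must be on the loop chain")
            anchor_keys = span_keys(structure, self.anchor)
            if not set(anchor_keys) <= set(loop_keys):
                raise ValidationError("anchor span must lie inside the loop span")
        mobile = [k for k in loop_keys if k not in set(anchor_keys)]
        if len(mobile) < 3:
            raise ValidationError(
                f"loop {self.loop} has {len(mobile)} mobile residues; "
                "an absolute minimum of three mobile positions is required")
        # resolve cutpoint
        if self.cutpoint is not None:
            cut_key = (self.chain_id, *self.cutpoint)
            if cut_key not in loop_keys:
                raise ValidationError(f"cutpoint {cut_key} not in loop span")
            if cut_key in anchor_keys:
                raise ValidationError("cutpoint may not lie inside the anchor")
            if anchor_keys and loop_keys.index(cut_key) < loop_keys.index(anchor_keys[-1]):
                raise ValidationError(
                    "cutpoint must lie C-terminal of the anchor span")
        elif anchor_keys:
            i = loop_keys.index(anchor_keys[-1])
            if i + 1 >= len(loop_keys):
                raise ValidationError(
                    "anchor at the loop C-terminus leaves no room for a cutpoint")
            cut_key = loop_keys[i + 1]
        else:
            cut_key = loop_keys[(len(loop_keys) - 1) // 2]
        return ResolvedLoop(self, tuple(loop_keys), tuple(anchor_keys), cut_key)


@dataclass(frozen=True)
class ResolvedLoop:
    spec: LoopSpec
    loop_keys: tuple[ResidueKey, ...]
    anchor_keys: tuple[ResidueKey, ...]
    cut_key: ResidueKey

    @property
    def chain_id(self) -> str:
        return self.spec.chain_id

    @property
    def mobile_keys(self) -> tuple[ResidueKey, ...]:
        return tuple(k for k in self.loop_keys if k not in set(self.anchor_keys))


def read_loops_file(path) -> list[LoopSpec]:
    """Parse a loops file: one loop per line,
    ``chain loop_start loop_stop [anchor_start anchor_stop [cutpoint]]``.

    Residue identifiers may carry insertion codes (e.g. ``36A``).
    """

    def parse_resid(tok: str) -> tuple[int, str]:
        if tok[-1].isalpha():
            return int(tok[:-1]), tok[-1]
        return int(tok), ""

    specs = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#")[0].strip()
        if not line:
            continue
        toks = line.split()
        if len(toks) not in (3, 5, 6):
            raise ValidationError(
                f"loops file line {ln}: expected 3, 5 or 6 fields, got {len(toks)}")
        chain = toks[0]
        start, stop = parse_resid(toks[1]), parse_resid(toks[2])
        anchor_start = anchor_stop = cut = None
        if len(toks) >= 5:
            anchor_start, anchor_stop = parse_resid(toks[3]), parse_resid(toks[4])
        if len(toks) == 6:
            cut = parse_resid(toks[5])
        loop = ResidueSpan.of(chain, start, stop)
        anchor = (ResidueSpan.of(chain, anchor_start, anchor_stop)
                  if anchor_start is not None else None)
        specs.append(LoopSpec(loop, anchor, cut))
    return specs
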