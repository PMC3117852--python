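"""Graft an anchor residue from a donor complex into a fresh scaffold.

The anchor's identity and conformation are copied into the scaffold loop,
the loop is re-closed around the rigid anchor by CCD, and the whole
scaffold is superposed so the grafted anchor sits exactly on the donor's
binding pose against the target -- a ready starting structure for the
design protocol.
"""

import numpy as np

from anchorloop import (GraftSpec, ResidueSpan, anchor_backbone_rmsd,
                        extract_anchor, graft_anchor,
                        make_toy_anchored_complex)
from anchorloop.structure import Structure

donor, _ = make_toy_anchored_complex(12, 20, 9, seed=1)
target = Structure({"A": [r.copy() for r in donor.residues("A")]})
anchor = extract_anchor(donor, ResidueSpan.of("B", 10, 10))
print("anchor residue:", anchor.residues()[0].aa_type)

other, _ = make_toy_anchored_complex(12, 20, 9, seed=9)
scaffold = Structure()
for r in other.residues("B"):
    rc = r.copy()
    rc.chain_id = "S"
    scaffold.add_residue(rc)

spec = GraftSpec(scaffold_loop=ResidueSpan.of("S", 6, 14),
                 occupy=ResidueSpan.of("S", 10, 10))
result = graft_anchor(target, anchor, scaffold, spec,
                      rng=np.random.default_rng(3))

fid = anchor_backbone_rmsd(result, anchor, ResidueSpan.of("S", 10, 10))
print(f"grafted-anchor backbone RMSD to donor pose: {fid:.2e} A "
      "(no superposition -- the graft is exact)")
print("output chains:", result.chain_ids,
      "- target plus modified scaffold, ready for the protocol")
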