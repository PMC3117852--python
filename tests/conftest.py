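import numpy as np
import pytest

from anchorloop import (LoopSpec, ScoreWeights, build_anchored_fold_tree,
                        make_toy_anchored_complex)


@pytest.fixture(scope="session")
def toy():
    """Shared deterministic toy anchored complex (target helix + scaffold
    with a 9-residue anchored loop)."""
    structure, spec = make_toy_anchored_complex(12, 20, 9, seed=1)
    return structure, spec


@pytest.fixture(scope="session")
def toy_tree(toy):
    structure, spec = toy
    return build_anchored_fold_tree(structure, spec)


@pytest.fixture(scope="session")
def fullatom_weights():
    return ScoreWeights.preset("fullatom")


@pytest.fixture(scope="session")
def centroid_weights():
    return ScoreWeights.preset("centroid")


def atom_coords(structure, keys=None, atom_names=None):
    """All coordinates for the requested residues/atom names."""
    out = []
    residues = (structure.residues() if keys is None
                else [structure.residue(k) for k in keys])
    for res in residues:
        for atom in res.atoms:
            if atom_names is None or atom.name in atom_names:
                out.append(atom.position)
    return np.array(out)
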