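"""Exception hierarchy.

Everything raised on purpose by this package derives from
:class:`AnchorLoopError` so callers can catch the whole family at once.
"""


class AnchorLoopError(Exception):
    """Base class for all anchorloop errors."""


class PDBParseError(AnchorLoopError):
    """A coordinate file could not be parsed; the message names the line."""


class StructureError(AnchorLoopError):
    """A structure violates a structural precondition (e.g. missing backbone)."""


class SpanLookupError(AnchorLoopError):
    """A residue-span endpoint does not exist in the named chain."""


class ValidationError(AnchorLoopError):
    """Invalid user-supplied specification (loop spec, design spec, config)."""


class RigidityError(AnchorLoopError):
    """A torsion change was requested at a rigid (anchor / core) position."""


class ClosureError(AnchorLoopError):
    """Loop closure cannot run (no mobile torsions that move the break)."""


class KICNoSolution(AnchorLoopError):
    """Retry signal: no real closure solution for the sampled non-pivot
    torsions.  Callers are expected to resample and try again."""


class ConfigurationError(AnchorLoopError):
    """Missing or inconsistent configuration (fragment store, repack interval)."""


class ScoringError(AnchorLoopError):
    """A score term could not be evaluated; the message names the residue."""


class InterfaceError(AnchorLoopError):
    """Interface analysis requested on a structure without two chains."""


class GraftError(AnchorLoopError):
    """Anchor grafting failed (loop would not re-close)."""


class ProtocolError(AnchorLoopError):
    """Monte Carlo protocol failure (non-finite scores, aborted trajectory)."""
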