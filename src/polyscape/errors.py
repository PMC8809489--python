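"""Exception hierarchy."""


class PolyscapeError(Exception):
    """Base class for all package errors."""


class CifFormatError(PolyscapeError):
    """Malformed or incomplete CIF content."""


class SymmetryError(PolyscapeError):
    """Symmetry operations missing, unresolvable, or inconsistent."""


class ElementError(PolyscapeError):
    """Unknown chemical element symbol."""


class ConnectivityError(PolyscapeError):
    """Bond graph inconsistent with the declared molecular content."""


class DihedralError(PolyscapeError):
    """Dihedral specification unresolvable or geometrically degenerate."""


class CorrectionError(PolyscapeError):
    """Invalid monomer-correction bookkeeping (multiplicities, re-application)."""


class CoverageError(PolyscapeError):
    """Requested pressures outside the sampled range of a PV series."""


class EosError(PolyscapeError):
    """Degenerate or non-convergent equation-of-state fit."""


class MatchError(PolyscapeError):
    """Packing-similarity comparison cannot be set up (isomorphism, cluster size)."""


class PlacementError(PolyscapeError):
    """Synthetic crystal packing failed to find a non-overlapping placement."""
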