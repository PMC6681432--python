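"""Exception hierarchy for TWN analysis."""


class TWNError(Exception):
    """Base class for all package errors."""


class FormatError(TWNError):
    """A structure file could not be parsed."""


class EmptyStructureError(FormatError):
    """A structure file parsed but contained no atoms."""


class CriterionUnavailableError(TWNError):
    """The energy hydrogen-bond criterion was requested for waters
    without explicit hydrogens (crystal waters carry only oxygens)."""


class SingularGeometryError(TWNError):
    """Degenerate geometry, e.g. coincident oxygen positions."""


class ClassificationError(TWNError):
    """An atom cannot be classified (e.g. hydrogens have no
    backbone/side-chain region)."""


class ConfigurationError(TWNError):
    """A configuration is internally inconsistent or inapplicable
    to the given input (e.g. no reference atoms in the frame)."""


class AssignmentError(TWNError):
    """A ring cannot be assigned to any residue heavy atom."""


class PlacementError(TWNError):
    """The synthetic-scene generator could not place an object under
    its geometric constraints within the retry budget."""


class GeometryCertificationError(TWNError):
    """A generated water ring failed its own hydrogen-bond
    certification against the pair-energy / distance criteria."""
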