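"""Exception hierarchy.

Every stage raises a subclass of :class:`PtfluctError` so callers can catch
pipeline failures without masking programming errors.
"""


class PtfluctError(Exception):
    """Base class for all ptfluct errors."""


class FormatError(PtfluctError):
    """A file could not be parsed in the requested format."""


class TopologyError(PtfluctError):
    """Topology is unusable (e.g. a hydrogen with no covalent heavy partner)."""


class ShapeError(PtfluctError):
    """Array shapes disagree (e.g. trajectory atom count vs topology)."""


class GeometryError(PtfluctError):
    """Degenerate periodic cell or other geometric impossibility."""


class CoverageError(PtfluctError):
    """Trajectory or series too short for the requested analysis."""


class SelectionError(PtfluctError):
    """An atom selection came up empty (no protein heavy atoms, no waters...)."""


class SamplingError(PtfluctError):
    """Requested sampling grid incompatible with the frame interval."""


class MissingBoxError(PtfluctError):
    """Per-frame periodic boxes required but absent."""


class ConditionMismatchError(PtfluctError):
    """A reference (e.g. pure-solvent volume) is for a different (T, P) state."""


class PairingError(PtfluctError):
    """Endpoint conditions for a comparison are missing."""


class ParseError(PtfluctError):
    """A tabular input row could not be parsed."""


class ConstructionError(PtfluctError):
    """A synthetic scene could not be built within the retry budget."""


class DegenerateSummaryError(PtfluctError):
    """Summary undefined (e.g. every hydrogen-bond pair excluded)."""
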