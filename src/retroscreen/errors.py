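"""Exception hierarchy shared across modules."""


class RetroscreenError(ValueError):
    """Base class for all package-specific errors."""


class CurationError(RetroscreenError):
    """Malformed compound tables, duplicate identifiers, missing thresholds."""


class StructureParseError(RetroscreenError):
    """A molecular structure (SMILES or coordinate file) could not be parsed."""


class DecoySelectionError(RetroscreenError):
    """Decoy selection could not satisfy the requested criteria."""


class ScoreTableError(RetroscreenError):
    """Pose-score table inconsistencies or lookups of absent entries."""


class MetricError(RetroscreenError):
    """Invalid inputs to screening metrics (e.g. single-class labels)."""


class GeometryError(RetroscreenError):
    """Structure annotation, superposition, or fragment-spec failures."""
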