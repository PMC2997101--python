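"""Exception hierarchy for ahcut."""


class AHCutError(Exception):
    """Base class for all ahcut errors."""


class GraphValidationError(AHCutError, ValueError):
    """Raised when a distance matrix or graph fails validation."""


class PartitionError(AHCutError, ValueError):
    """Raised for invalid side-maps (unknown labels, empty sides, ...)."""


class DegenerateMoveError(PartitionError):
    """Raised when a vertex move would empty one side of the bipartition."""


class InstanceTooLargeError(AHCutError, ValueError):
    """Raised when an exact method is asked to enumerate beyond its hard cap."""


class ExpressionDataError(AHCutError, ValueError):
    """Raised for invalid expression matrices (missing values, zero variance)."""
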