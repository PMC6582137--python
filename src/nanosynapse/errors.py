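"""Exception hierarchy shared across the pipeline."""


class NanoSynapseError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(NanoSynapseError, ValueError):
    """A parameter is outside its valid domain."""


class SchemaError(NanoSynapseError):
    """A localization table is missing required columns."""


class ParseError(NanoSynapseError):
    """A file could not be parsed; carries the offending row where known."""


class DegenerateGeometryError(NanoSynapseError):
    """Point configuration too degenerate for the requested fit (collinear, too few)."""


class InsufficientDataError(NanoSynapseError):
    """Not enough observations for the requested estimate or test."""


class InsufficientFiducialsError(InsufficientDataError):
    """Too few trackable beads to estimate drift."""


class ROIRejectedError(NanoSynapseError):
    """A synapse ROI failed its acceptance preconditions; carries a reason."""

    def __init__(self, reason: str):
        super().__init__(reason)
        self.reason = reason


class EmptyImageError(NanoSynapseError):
    """Rendering was asked for an empty localization table."""


class PipelineStageError(NanoSynapseError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
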