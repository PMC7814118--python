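"""Exception hierarchy shared across the package."""


class MBSError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MBSError):
    """A delimited input file could not be parsed (names the offending cell)."""


class ValidationError(MBSError):
    """A record or value violates a domain invariant."""


class ConfigError(MBSError):
    """A configuration (file, column map, CLI option set) is unusable."""


class AlignmentError(MBSError):
    """Expression samples and clinical patients cannot be matched as requested."""


class ModelFormatError(MBSError):
    """A serialized score model is missing fields or fails validation."""


class ConvergenceError(MBSError):
    """An iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message, last_beta=None):
        super().__init__(message)
        self.last_beta = last_beta


class UninformativeMarkerError(MBSError):
    """Every admissible cutpoint yields the same metric value."""


class StageError(MBSError):
    """A pipeline stage failed; names the stage for the run manifest."""

    def __init__(self, stage, cause):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
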