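"""Exception hierarchy. All errors raised by this package derive from DDIMinerError."""


class DDIMinerError(Exception):
    """Base class for all ddiminer errors."""


class ParseError(DDIMinerError):
    """A malformed input file line; message names the file and line number."""


class ValidationError(DDIMinerError):
    """An argument violated a precondition (empty identifier, bad counts, ...)."""


class EmptySourceError(DDIMinerError):
    """A PPI source retained zero interactions after filtering."""


class CalibrationError(DDIMinerError):
    """Threshold calibration cannot proceed (degenerate learning set or shuffle)."""


class ConfigurationError(DDIMinerError):
    """Invalid run configuration (unknown strategy, missing file, bad combination)."""


class ClassificationError(DDIMinerError):
    """Category assignment received an invalid per-source score pattern."""


class EvaluationError(DDIMinerError):
    """An evaluation routine received a degenerate input (empty set, no positives)."""


class GenerationError(DDIMinerError):
    """The synthetic-world generator could not satisfy its configuration."""
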