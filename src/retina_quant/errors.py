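"""Exception hierarchy.

Exit-code contract for the CLI: 0 ok, 2 validation, 3 config, 4 I/O.
Each exception class carries the exit code the CLI maps it to.
"""


class RetinaQuantError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(RetinaQuantError):
    """Invalid measurement or record content."""

    exit_code = 2


class InvalidMeasurementError(ValidationError):
    """A width, length or thickness outside its physical sanity range."""


class InsufficientVesselsError(ValidationError):
    """No branch widths supplied where at least one is required."""


class IncompleteEyeError(ValidationError):
    """An eye missing artery or vein measurements; excluded from vessel analysis."""


class CalibrationError(ValidationError):
    """Non-positive known distance in the pixel-to-mm scale."""


class InvalidROIError(ValidationError):
    """Degenerate or self-intersecting region-of-interest polygon."""


class AnatomicalConsistencyError(ValidationError):
    """Cup/disc measurements violating cup <= disc or ratio bounds."""


class InsufficientDataError(ValidationError):
    """Too few non-missing values for a statistical comparison."""


class UndefinedCorrelationError(ValidationError):
    """Zero variance makes the Pearson correlation undefined."""


class ConfigError(RetinaQuantError):
    """Invalid scenario or run configuration."""

    exit_code = 3


class FormatError(ValidationError):
    """Malformed input file (header, dialect, required columns)."""


class OutputError(RetinaQuantError):
    """Unwritable output location or other I/O failure."""

    exit_code = 4
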