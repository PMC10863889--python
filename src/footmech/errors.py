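"""Exception hierarchy for the footmech pipeline.

Validation errors (bad user input, schema problems) and data errors
(inconsistent or degenerate measurements) are kept distinct so the CLI can
map them onto separate exit codes.
"""


class FootmechError(Exception):
    """Base class for all footmech errors."""


class ValidationError(FootmechError):
    """Invalid parameters, configuration, or metadata."""


class DataError(FootmechError):
    """Inconsistent, degenerate, or unusable input data."""


class SchemaError(ValidationError):
    """Required marker labels missing or mismatched."""


class FormatError(DataError):
    """A file could not be parsed under its declared format."""


class ParameterError(ValidationError):
    """A numeric parameter is out of its valid range."""


class MetadataError(ValidationError):
    """Subject metadata missing or non-physical."""


class TableError(ValidationError):
    """Anthropometry table incomplete or non-physical."""


class AlignmentError(DataError):
    """Time bases or series lengths that should match do not."""


class DegenerateGeometryError(DataError):
    """Collinear marker cluster or degenerate frame recipe."""


class NoContactError(DataError):
    """Vertical force never crosses the contact threshold."""


class PairingError(ValidationError):
    """Subjects cannot be paired across conditions."""


class SpecError(ValidationError):
    """A synthetic trial specification violates its invariants."""


class DiagnosticError(DataError):
    """An adaptive procedure failed; carries diagnostic payload."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


class StageError(FootmechError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage, original):
        super().__init__(f"stage '{stage}': {original}")
        self.stage = stage
        self.original = original
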