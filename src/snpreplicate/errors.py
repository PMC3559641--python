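"""Exception hierarchy.

All package errors derive from :class:`SnpReplicateError` so callers can
catch one base class; the CLI maps validation errors to exit code 1 and
I/O errors to exit code 2.
"""


class SnpReplicateError(Exception):
    """Base class for all snpreplicate errors."""


class ValidationError(SnpReplicateError):
    """Input data violates a documented invariant."""


class SchemaError(ValidationError):
    """A table is missing required columns or has a malformed header."""


class DegenerateTableError(SnpReplicateError):
    """A contingency table has too few non-empty rows/columns to test."""


class InsufficientDataError(SnpReplicateError):
    """Too few complete observations for the requested statistic."""
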