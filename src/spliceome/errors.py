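"""Named exception types raised across the pipeline.

Every validation failure maps to a distinct class so callers (and the CLI)
can translate them into precise error messages and exit codes.
"""


class SpliceomeError(Exception):
    """Base class for all package errors."""


class ValidationError(SpliceomeError):
    """Input failed a structural or value-range check."""


class GctFormatError(ValidationError):
    """Malformed GCT version or dimension line."""


class DimensionMismatchError(ValidationError):
    """GCT dimension line disagrees with the data block."""


class NegativeValueError(ValidationError):
    """Expression values must be non-negative finite TPM."""


class NonNumericValueError(ValidationError):
    """Expression block contains a non-numeric entry."""


class DuplicateIdError(ValidationError):
    """Duplicate transcript or sample identifier."""


class MissingColumnError(ValidationError):
    """A required column or GTF attribute is absent."""


class EmptyTableError(ValidationError):
    """A table that must contain at least one row is empty."""


class NoOverlapError(ValidationError):
    """Zero transcripts shared between expression and annotation.

    Signals an identifier-scheme mismatch (for example versioned against
    unversioned transcript ids)."""


class UnknownIdError(SpliceomeError):
    """A transcript, gene, sample or variant id is not present."""


class InsufficientDataError(SpliceomeError):
    """Too few samples/groups/values for the requested statistic."""


class NotTrimodalError(SpliceomeError):
    """Genotype calling requested on a fit without trimodal support."""


class NoisyTruthError(SpliceomeError):
    """Analytic truth summaries requested for a noisy/biased simulation."""
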