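"""Exception hierarchy for dta-meta.

All data-dependent failures derive from :class:`DtaMetaError` so the CLI can
map them to a single non-zero exit code.
"""


class DtaMetaError(Exception):
    """Base class for all package errors."""


class SchemaError(DtaMetaError):
    """Input file does not match the expected column schema."""


class ValidationError(DtaMetaError):
    """A record or configuration value violates an invariant."""


class ZeroCellError(DtaMetaError):
    """A log/logit transform was requested on a table with a zero cell."""


class InsufficientStudiesError(DtaMetaError):
    """An operation needs more studies than were supplied."""


class SingularDesignError(DtaMetaError):
    """The regression design matrix is singular (e.g. all S values equal)."""


class DegenerateSlopeError(DtaMetaError):
    """The SROC slope magnitude is >= 1; the curve is not monotone-valid."""
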