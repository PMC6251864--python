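"""Exception hierarchy shared across the package.

Every error raised on a user-facing code path derives from :class:`M5cError`
so callers (and the CLI) can catch one base class.
"""


class M5cError(Exception):
    """Base class for all package errors."""


class FastaParseError(M5cError):
    """Malformed FASTA input (e.g. sequence data before any header)."""


class DuplicateIdError(M5cError):
    """Two records in one file share an identifier."""


class SchemaError(M5cError):
    """A tabular input is missing required columns."""


class SiteValidationError(M5cError):
    """A site-table row violates the coordinate or label contract."""


class NotACandidateError(M5cError):
    """The base at a requested position is not a cytosine."""


class BoundsError(M5cError):
    """A 1-based position falls outside its transcript."""


class EncodingError(M5cError):
    """A window contains a character no encoding scheme knows."""


class ShapeMismatchError(M5cError):
    """Windows of differing width (or wrong width for a model) were mixed."""


class SingleClassError(M5cError):
    """An operation requiring both classes received only one."""


class EmptyNegativesError(M5cError):
    """No negative candidates are available where at least one is required."""


class UndefinedMetricError(M5cError):
    """A ratio metric was requested with a zero denominator."""


class BundleError(M5cError):
    """A saved model bundle is unreadable or internally inconsistent."""


class BundleVersionError(BundleError):
    """A saved model bundle was written by an incompatible version."""


class SyntheticSpecError(M5cError):
    """A synthetic-data specification is invalid or degenerate."""
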