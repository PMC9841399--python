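"""Exception hierarchy.

All errors raised by this package derive from :class:`VarzipError` so the CLI
can turn any of them into a one-line diagnostic and a nonzero exit code.
"""


class VarzipError(Exception):
    """Base class for all varzip errors."""


class ConfigError(VarzipError):
    """Invalid field configuration (missing keys, duplicate aliases, bad types)."""


class InvalidPositionError(VarzipError):
    """A VCF POS below 1 or an in-bin offset outside [0, 2^20)."""


class EncodingDomainError(VarzipError):
    """Alleles that cannot be packed into a 32-bit code were passed to the encoder."""


class PlaceholderDecodeError(VarzipError):
    """Attempt to decode a placeholder code (zero allele-length bits)."""


class NotSortedError(VarzipError):
    """Delta encoding requires a non-decreasing input sequence."""


class IntegerOverflowError(VarzipError):
    """A value left the 32-bit unsigned (or signed, for fields) domain."""


class CorruptArchiveError(VarzipError):
    """An archive entry failed structural validation; message names the entry."""


class SortOrderError(VarzipError):
    """Input VCF records out of coordinate order, or a chromosome revisited."""


class DecompositionError(VarzipError):
    """A multi-allelic record was seen where decomposed input is required."""


class FieldOverflowError(VarzipError):
    """A quantized or integer field value does not fit in a signed 32-bit integer."""


class ExpressionError(VarzipError):
    """Filter expression syntax or type error, reported before any record is read."""


class EvaluationError(VarzipError):
    """Record-level filter evaluation failure (e.g. division by zero)."""


class ArchiveError(VarzipError):
    """Archive unreadable or structurally unusable."""
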