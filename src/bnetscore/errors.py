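"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI:
  2 -> validation / schema errors
  3 -> I/O errors
  4 -> degenerate-statistics errors
"""


class BnetscoreError(Exception):
    """Base class for all package-specific errors."""

    exit_code = 1


class SchemaError(BnetscoreError):
    """The input file header does not match the documented CSV schema."""

    exit_code = 2


class ValidationError(BnetscoreError):
    """A record violates a domain invariant (bad value, duplicate, conflict)."""

    exit_code = 2


class IncompleteRecordError(ValidationError):
    """A drug record lacks data required by the requested computation."""

    exit_code = 2


class DegenerateStatisticsError(BnetscoreError):
    """A statistic is undefined for the given data (single class, constant input)."""

    exit_code = 4
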