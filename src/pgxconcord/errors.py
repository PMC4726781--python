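"""Exception hierarchy for pgxconcord.

All data-level failures derive from :class:`PgxError` so callers (and the
CLI) can distinguish bad input from programming errors.
"""


class PgxError(Exception):
    """Base class for all data-validation errors raised by pgxconcord."""


class MalformedAlleleError(PgxError):
    """An allele string contains characters other than A/C/G/T."""


class NoVariantError(PgxError):
    """A variant record carries no alternate allele."""


class PloidyError(PgxError):
    """A genotype is not diploid; only ploidy-2 calls are supported."""


class AmbiguousSiteError(PgxError):
    """One rsID maps to conflicting coordinates during site matching."""


class DuplicateCallError(PgxError):
    """Two calls were registered for the same (sample, site) pair."""


class ForeignAlleleError(PgxError):
    """A genotype letter matches neither the declared ref nor alt allele."""


class MalformedIntervalError(PgxError):
    """A BED interval has start >= end (0-based half-open convention)."""


class ParseError(PgxError):
    """A file could not be parsed; the message carries file/line context."""


class ConfigError(PgxError):
    """A simulation or threshold configuration failed validation."""
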