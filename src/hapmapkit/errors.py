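"""Exception hierarchy.

Every error raised by the toolkit derives from :class:`HapmapkitError`, so
callers (and the CLI) can catch one base class.  ``ArgumentError`` doubles as
a ``ValueError`` for ergonomic use in plain-Python call sites.
"""


class HapmapkitError(Exception):
    """Base class for all toolkit errors."""


class ParseError(HapmapkitError):
    """A flat file does not conform to its dialect."""


class UnsupportedDialectError(ParseError):
    """A recognisable but unsupported file dialect (e.g. 3-digit Genepop)."""


class IntegrityError(HapmapkitError):
    """Internally inconsistent data (counts, cross-references, checksums)."""


class AvailabilityError(HapmapkitError):
    """Requested data is not present in the store and cannot be fetched."""


class TransportError(HapmapkitError):
    """A configured remote fetch failed; retrying may help."""


class BuildMismatchError(HapmapkitError):
    """Two datasets use different genome reference builds."""


class NotFoundError(HapmapkitError):
    """A lookup (gene symbol, key) matched nothing."""


class AlignmentError(HapmapkitError):
    """Tables that must share a SNP list do not."""


class AmbiguityError(HapmapkitError):
    """An operation needs a single answer but the inputs span several."""


class UndefinedResultError(HapmapkitError):
    """The requested statistic is undefined on these inputs."""


class ArgumentError(HapmapkitError, ValueError):
    """A caller-supplied argument is invalid."""
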