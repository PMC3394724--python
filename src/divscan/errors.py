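"""Exception hierarchy shared across the package."""


class DivscanError(Exception):
    """Base class for all package errors."""


class FormatError(DivscanError):
    """A file does not conform to its expected layout (names the offending row)."""


class DataError(DivscanError):
    """Well-formed input with impossible content (e.g. a triallelic SNP)."""


class DomainError(DivscanError, ValueError):
    """An argument outside the operation's mathematical domain."""


class EmptyResultError(DivscanError):
    """A filter or query removed everything."""


class ConfigError(DivscanError):
    """An invalid simulation or pipeline configuration."""
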