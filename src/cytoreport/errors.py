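"""Exception hierarchy shared across the package."""


class CytoreportError(Exception):
    """Base class for all package errors."""


class SchemaError(CytoreportError):
    """A panel schema is malformed, or a panel does not conform to it."""


class DomainError(CytoreportError, ValueError):
    """A numeric input is outside its mathematical domain (e.g. negative count)."""


class ConfigError(CytoreportError):
    """A configuration file or identifier is invalid."""


class UsageError(CytoreportError):
    """An operation was called with inconsistent or missing arguments."""


class ConsistencyError(CytoreportError):
    """Two objects that must refer to the same specimen do not."""
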