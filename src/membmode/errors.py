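"""Exception hierarchy.

``UsageError`` maps to CLI exit code 2, ``DataError`` (and subclasses) to 3.
"""


class MembmodeError(Exception):
    """Base class for all package errors."""


class UsageError(MembmodeError):
    """Caller violated a precondition (bad argument, empty range, ...)."""


class ConfigurationError(UsageError):
    """Inconsistent configuration (e.g. periodic contacts without a box)."""


class DataError(MembmodeError):
    """Input data is structurally invalid."""


class ParseError(DataError):
    """A file could not be parsed in the declared dialect."""


class SelectionError(DataError):
    """A required particle selection came up empty."""


class PairingError(DataError):
    """Two particle sets could not be paired one-to-one."""


class CapacityError(DataError):
    """A stochastic placement could not satisfy its constraints."""


class FitError(DataError):
    """A numerical fit failed to produce a usable result."""
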