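"""Exception taxonomy shared across the package.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
``DomainError`` marks physically or mathematically invalid inputs to the
model layer and is a ``ValueError`` so callers can catch it generically.
"""


class TrisoscapeError(Exception):
    """Base class for package errors."""


class DomainError(TrisoscapeError, ValueError):
    """Input outside the physical/mathematical domain of an operation."""


class ConfigError(TrisoscapeError):
    """Invalid configuration (bad paths, malformed region file, bad params)."""


class DataError(TrisoscapeError):
    """Malformed or inconsistent data (bad CSV rows, missing variables)."""
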