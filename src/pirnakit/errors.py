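"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class PirnakitError(Exception):
    """Base class for all package errors."""


class ConfigError(PirnakitError):
    """Invalid configuration or parameters."""


class DataError(PirnakitError):
    """Invalid, inconsistent, or degenerate input data."""


class ParseError(DataError):
    """A file failed to parse; message carries the line number when known."""


class SchemaError(DataError):
    """A table was read with an unexpected header/schema."""
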