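"""Exception hierarchy.

ConfigError maps to CLI exit code 2, DataError to exit code 3.
"""


class GimapError(Exception):
    """Base class for package errors."""


class ConfigError(GimapError):
    """Invalid configuration or parameters."""


class DataError(GimapError):
    """Invalid, unreadable, or empty input data."""
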