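"""Exception hierarchy shared across the package."""


class TrajganError(Exception):
    """Base class for all package errors."""


class ConfigError(TrajganError):
    """Invalid configuration value or inconsistent config blocks."""


class InputError(TrajganError):
    """Well-formed call with data that violates a precondition."""


class FormatError(TrajganError):
    """On-disk artifact does not follow the documented layout."""


class NumericsError(TrajganError):
    """A computation produced non-finite or otherwise unusable numbers."""
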