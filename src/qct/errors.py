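"""Exception hierarchy shared across the package.

The CLI maps these onto process exit codes (validation errors -> 2,
insufficient data -> 3); library users catch them as ordinary exceptions.
"""


class QCTError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(QCTError):
    """Malformed, inconsistent, or out-of-contract input data."""


class ConfigError(ValidationError):
    """Invalid configuration value (non-finite calibration, unknown key, ...)."""


class InsufficientDataError(QCTError):
    """Too few usable beats/samples to run the requested computation."""
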