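"""Exception hierarchy.

ConfigError covers invalid parameters and impossible simulation requests;
DataError covers malformed or inconsistent input data. The CLI maps these
to distinct exit codes (2 and 3 respectively).
"""


class HetprofileError(Exception):
    """Base class for all package errors."""


class ConfigError(HetprofileError):
    """Invalid configuration or parameters."""


class CapacityError(ConfigError):
    """A simulated genome cannot accommodate the requested features."""


class DataError(HetprofileError):
    """Malformed, inconsistent, or out-of-bounds input data."""


class FailedCurveError(DataError):
    """A qPCR standard curve fit is unusable (e.g. non-negative slope)."""
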