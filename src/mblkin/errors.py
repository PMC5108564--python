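"""Exception taxonomy shared across the package."""


class MblkinError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(MblkinError, ValueError):
    """A scheme, rate set, chromophore map or run config is internally inconsistent."""


class IntegrationError(MblkinError, RuntimeError):
    """The ODE solver failed; carries the solver's diagnostic message."""


class RangeError(MblkinError, ValueError):
    """A requested wavelength or time lies outside the data grid."""


class InsufficientDataError(MblkinError, ValueError):
    """Too few data points for the requested analysis window."""
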