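"""Exception hierarchy shared across the package."""


class RepcountError(Exception):
    """Base class for all package-specific errors."""


class MalformedTraceError(RepcountError, ValueError):
    """Input file cannot be interpreted as a valid accelerometer trace."""


class ParameterError(RepcountError, ValueError):
    """A configuration or call parameter is out of its valid range."""


class BoundsError(RepcountError, ValueError):
    """A requested time interval selects no samples."""


class DegenerateSignalError(RepcountError, ValueError):
    """The signal has (near-)zero range; no threshold can be placed."""


class EvaluationError(RepcountError, RuntimeError):
    """No session could be evaluated."""


class ConfigError(RepcountError, ValueError):
    """A run-configuration file contains an unknown or invalid key."""
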