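"""Exception types raised across the package."""


class BlanketSimError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(BlanketSimError, ValueError):
    """An argument violated a documented precondition."""


class NumericalBlowupError(BlanketSimError, RuntimeError):
    """An integration step produced non-finite state.

    The message names the offending cell index and the state component
    (position, secretion or belief) that first went non-finite.
    """


class ConfigError(BlanketSimError, ValueError):
    """A configuration file failed validation (unknown key, bad type)."""


class MetricUndefinedError(BlanketSimError, RuntimeError):
    """A blanket metric could not be evaluated (e.g. a cell type is absent)."""
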