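"""Exception hierarchy shared across the package."""


class BioHekfError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BioHekfError, ValueError):
    """A model, filter or pipeline object was built from inconsistent pieces."""


class InputError(BioHekfError, ValueError):
    """User-supplied data (measurements, windows, confidence levels) is invalid."""


class DomainError(BioHekfError, ValueError):
    """A model function was evaluated outside its domain of definition."""


class IntegrationError(BioHekfError, RuntimeError):
    """ODE integration failed.  ``t_last`` is the last time reached."""

    def __init__(self, message, t_last=None):
        super().__init__(message)
        self.t_last = t_last


class FilterDivergenceError(BioHekfError, RuntimeError):
    """The filter diverged at step ``k`` (non-finite values or singular innovation)."""

    def __init__(self, message, k=None):
        super().__init__(message)
        self.k = k
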