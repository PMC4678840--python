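"""Exception hierarchy shared across the package."""


class McmflowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(McmflowError, ValueError):
    """A scenario, optics, or pipeline configuration is invalid."""


class InputError(McmflowError, ValueError):
    """Input data violates a documented precondition."""


class AnalysisError(McmflowError, RuntimeError):
    """An analysis step cannot produce a result on this input."""
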