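"""Exception hierarchy shared across the package."""


class QuantgapError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(QuantgapError, ValueError):
    """Invalid analysis configuration (missing column, bad bounds, ...)."""


class ParseError(QuantgapError, ValueError):
    """A cell in the input file could not be parsed as a number."""


class InsufficientDataError(QuantgapError, ValueError):
    """A group has too few complete rows to fit the model."""


class SingularDesignError(QuantgapError, ValueError):
    """Design matrix is rank deficient."""


class SolverError(QuantgapError, RuntimeError):
    """The quantile-regression solver failed."""


class InferenceError(QuantgapError, RuntimeError):
    """Bootstrap inference could not be completed."""


class DGPValidityError(QuantgapError, ValueError):
    """A synthetic data-generating process violates its own constraints."""
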