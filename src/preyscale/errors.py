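"""Exception hierarchy shared across the package."""


class PreyscaleError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PreyscaleError):
    """Bad configuration: missing columns, malformed mappings, bad paths."""


class ValidationError(PreyscaleError):
    """Input data violates a documented invariant.

    Carries a ``problems`` list of human-readable row/record level messages.
    """

    def __init__(self, message, problems=None):
        super().__init__(message)
        self.problems = list(problems) if problems else []


class ParameterError(PreyscaleError):
    """A parameter is outside its documented domain."""


class NumericalError(PreyscaleError):
    """Linear-algebra failure (singular design, non-PD covariance, ...).

    ``diagnostics`` holds e.g. condition numbers for post-mortem use.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = dict(diagnostics) if diagnostics else {}


class ConvergenceError(PreyscaleError):
    """Optimizer failed to converge; carries the evaluation trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class UsageError(PreyscaleError):
    """An operation was called on an object of the wrong kind."""
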