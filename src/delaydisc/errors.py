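"""Exception types shared across the package."""


class DelayDiscError(Exception):
    """Base class for package errors."""


class ConfigurationError(DelayDiscError, ValueError):
    """Invalid task, battery, or pipeline configuration."""


class ValidationError(DelayDiscError, ValueError):
    """Input data violate a schema or a contract precondition."""


class StaircaseStateError(DelayDiscError, RuntimeError):
    """Illegal operation on a titration state (e.g. updating after termination)."""


class FitError(DelayDiscError, RuntimeError):
    """An estimation routine could not produce a usable fit."""


class AnchoringError(ValidationError):
    """Time judgments cannot be normalized (no usable one-week anchor)."""


class ConvergenceWarning(UserWarning):
    """MCMC diagnostics exceed the convergence threshold."""
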