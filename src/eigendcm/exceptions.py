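"""Exception hierarchy for eigendcm."""


class EigenDCMError(Exception):
    """Base class for all eigendcm errors."""


class ValidationError(EigenDCMError, ValueError):
    """An input violates a structural requirement (shape, orthonormality, grid)."""


class StabilityError(EigenDCMError, ValueError):
    """A connectivity matrix is not stable (negative definite) where required."""


class ConditioningError(EigenDCMError, ValueError):
    """A matrix is singular or too ill-conditioned for the requested operation."""


class ConvergenceError(EigenDCMError, RuntimeError):
    """Model inversion diverged (non-finite objective)."""


class ConfigError(EigenDCMError, ValueError):
    """A configuration file violates the schema."""
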