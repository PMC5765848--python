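"""Exception and warning hierarchy."""


class GradsenseError(Exception):
    """Base class for all package-specific errors."""


class DomainError(GradsenseError, ValueError):
    """A point lies outside the domain where a kernel is defined."""


class SingularInputError(GradsenseError, ValueError):
    """Evaluation requested too close to a logarithmic singularity."""


class RegimeViolationError(GradsenseError, ValueError):
    """Configuration outside the validity of the asymptotic regime
    (e.g. window size >= window separation)."""


class DegenerateConfigurationError(GradsenseError, ValueError):
    """Window layout leads to a singular / ill-conditioned linear system."""


class ConfigurationError(GradsenseError, ValueError):
    """Invalid simulation or scenario configuration."""


class ReinjectionCapError(GradsenseError, RuntimeError):
    """A trajectory exceeded the re-injection safety cap; usually a sign of
    mis-sized inner/outer artificial boundaries."""


class NoSolutionError(GradsenseError, RuntimeError):
    """Source recovery found no root inside the search domain."""


class RegimeWarning(UserWarning):
    """Asymptotic formulas evaluated close to the edge of their validity."""


class AmbiguityWarning(UserWarning):
    """Source recovery found more than one candidate position."""
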