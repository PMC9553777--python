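"""Exception hierarchy shared by all modules."""


class DgmocoError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(DgmocoError, ValueError):
    """Invalid user-supplied parameter."""


class GatingError(DgmocoError):
    """Gating could not be performed on the given signals."""


class ReconError(DgmocoError):
    """Projection / reconstruction failure."""


class RegistrationError(DgmocoError):
    """Registration failure (grid mismatch, divergent field, ...)."""


class MetricsError(DgmocoError):
    """Quantification failure (empty VOI, degenerate profile, ...)."""
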