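"""Exception types shared across the package."""


class GermError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(GermError, ValueError):
    """Invalid input data or configuration."""


class DomainError(GermError, ValueError):
    """Evaluation point or observation outside the spline domain."""


class FormatError(GermError, ValueError):
    """Malformed tabular input file."""


class NumericalError(GermError, RuntimeError):
    """Numerical failure (rank deficiency, solver breakdown)."""
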