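"""Exception hierarchy.

Validation/parameter problems and numerical non-convergence are kept
distinct so the CLI can map them to different exit codes (2 and 3).
"""


class MitolineageError(Exception):
    """Base class for all package errors."""


class ValidationError(MitolineageError, ValueError):
    """Malformed distribution, table, or result object."""


class ParameterError(MitolineageError, ValueError):
    """Out-of-range or inconsistent user-supplied parameter."""


class ConvergenceError(MitolineageError, RuntimeError):
    """An iterative computation failed to converge within its budget."""


class QuantileUnreachableError(MitolineageError, ValueError):
    """Requested quantile exceeds the attained extinction probability."""


class LineageOverflowError(MitolineageError, OverflowError):
    """Simulated population exceeded the configured overflow bound."""


class ComparisonError(MitolineageError, ValueError):
    """Attempt to compare results that came from different distributions."""
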