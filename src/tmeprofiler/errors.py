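"""Exception hierarchy shared across the package."""


class TMEProfilerError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TMEProfilerError):
    """An input table is missing a required column or has a malformed header."""


class LinkageError(TMEProfilerError):
    """A sample referenced in one table is absent from a companion table."""


class DataError(TMEProfilerError):
    """Values are structurally valid but inconsistent (e.g. cells on zero area)."""


class ConfigError(TMEProfilerError):
    """A configuration object violates its own invariants."""


class NoValleyError(TMEProfilerError):
    """kde_valley found fewer than two modes; caller must fall back."""


class DegenerateInputError(TMEProfilerError):
    """Input carries no usable information (constant vector, empty set...)."""


class CombinationGuardError(TMEProfilerError):
    """Combination enumeration over too many markers was refused."""


class ConvergenceFailure(TMEProfilerError):
    """An iterative fit did not converge or the likelihood is monotone."""
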