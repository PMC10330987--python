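"""Exception hierarchy for the ssgblup pipeline."""


class SsgblupError(Exception):
    """Base class for all pipeline errors."""


class ConfigError(SsgblupError, ValueError):
    """Invalid configuration (bad proportion, negative variance, ...)."""


class PedigreeError(SsgblupError, ValueError):
    """Structural pedigree problem: cycle, unknown parent id, duplicate id."""


class DataError(SsgblupError, ValueError):
    """Inconsistent or malformed data (conflicting calls, bad id, parse error)."""


class PipelineOrderError(SsgblupError, RuntimeError):
    """An operation was called before its prerequisite stage (e.g. imputation
    before allele-frequency estimation)."""


class EmptyResultError(SsgblupError, ValueError):
    """A filter removed everything there was to analyze."""


class SingularSystemError(SsgblupError, ValueError):
    """The blending system Avg(diag(G))β+α, Avg(G)β+α is singular."""


class NumericalError(SsgblupError, RuntimeError):
    """Numerical failure (singular matrix after jitter, non-finite values)."""
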