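"""Exception hierarchy shared across the package."""


class GGMNetError(Exception):
    """Base class for all ggmnet errors."""


class InvalidSpecError(GGMNetError):
    """A cohort/run specification violates its invariants."""


class SchemaError(GGMNetError):
    """Mismatched node labels, dimensions, or unknown identifiers."""


class DegenerateDataError(GGMNetError):
    """Data with no usable variation (constant column, zero residual variance)."""


class FitError(GGMNetError):
    """A model fit could not be carried out (e.g. too few control subjects)."""


class DataError(GGMNetError):
    """Invalid input data (non-finite values, groups too small)."""


class SamplerStallError(GGMNetError):
    """All birth/death rates vanished numerically; the chain cannot move."""


class EmptyChainError(GGMNetError):
    """Chain summary requested before any post-burn-in state was recorded."""


class ConvergenceError(GGMNetError):
    """Iterative estimation failed to reach its tolerance within the cap."""


class DomainError(GGMNetError):
    """A numeric argument is outside the mathematically valid domain."""


class PipelineError(GGMNetError):
    """A pipeline stage failed; the message names the stage."""
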