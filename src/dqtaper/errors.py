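"""Exception hierarchy for cohort validation and pipeline stages."""


class DqTaperError(Exception):
    """Base class for all package errors."""


class ValidationError(DqTaperError):
    """A cohort table violates its schema or a typed invariant.

    The message names the offending table, record and field so a failing
    row can be located in the source file.
    """


class UnknownRegimenError(DqTaperError):
    """A dose observation names a drug absent from the regimen registry."""


class IncompleteTimelineError(DqTaperError):
    """A patient lacks a dose observation at a canonical grid month."""


class ImputationError(DqTaperError):
    """Linear interpolation cannot proceed (leading/trailing gap)."""


class ClassificationError(DqTaperError):
    """Response/relapse status cannot be computed (missing endpoint)."""


class WeightError(DqTaperError):
    """Stabilized weight is non-finite (numerically zero denominator)."""


class SingularDesignError(DqTaperError):
    """The treatment-model design matrix is rank deficient."""


class ConvergenceError(DqTaperError):
    """Iterative fitting (exchangeable GEE) failed to converge."""


class DegenerateLabelsError(DqTaperError):
    """ROC analysis received labels with only one class present."""
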