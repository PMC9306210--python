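"""Exception hierarchy.

Estimation failures during bootstrap resampling must be machine-readable so
that replicates can be skipped and counted rather than aborting a run; every
condition that legitimately invalidates a single replicate derives from
:class:`EstimationError`.
"""


class CausalRDError(Exception):
    """Base class for all package errors."""


class SchemaError(CausalRDError):
    """A required column or variable is missing from the input."""


class CodingError(CausalRDError):
    """A value does not match any declared codebook level."""


class DomainError(CausalRDError):
    """An input value lies outside the admissible domain."""


class DimensionError(CausalRDError):
    """Shapes of inputs do not line up (empty cohort, mismatched lengths)."""


class AlignmentError(CausalRDError):
    """Design-matrix columns do not match a fit's coefficient vector."""


class ContractError(CausalRDError):
    """A caller violated an interface contract (e.g. missing m0/m1)."""


class EstimationError(CausalRDError):
    """Base class for failures of a single estimation attempt.

    The bootstrap treats any subclass as a skippable replicate failure.
    """


class DegenerateResponseError(EstimationError):
    """The response takes a single value; the logistic MLE does not exist."""


class SeparationError(EstimationError):
    """Perfect or quasi-complete separation: the MLE diverges.

    Attributes
    ----------
    column : str or None
        Label of the column most implicated in the separation direction.
    """

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column


class SingularError(EstimationError):
    """The information matrix is singular (collinear or constant columns)."""


class DivisionGuardError(EstimationError):
    """A propensity score reached 0/1, making an inverse weight undefined."""


class ConvergenceError(EstimationError):
    """Iteration limit reached without meeting the convergence criteria."""


class ProfilingError(CausalRDError):
    """A profile-likelihood refit failed to converge."""


class ReliabilityError(CausalRDError):
    """Too few successful bootstrap replicates to report an interval."""
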