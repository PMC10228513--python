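"""Exception hierarchy.

All package-specific failures derive from :class:`HypoestimandError` so callers
can catch one base class; subclasses distinguish data-format problems from
statistical failure modes (positivity, separation, singular designs).
"""


class HypoestimandError(Exception):
    """Base class for all errors raised by hypoestimand."""


class FormatError(HypoestimandError):
    """A file does not conform to the documented wide CSV layout."""


class ValidationError(HypoestimandError):
    """A dataset violates a structural invariant (non-binary arm/ICE column,
    non-absorbing ICE pattern, ...)."""


class ScenarioError(HypoestimandError):
    """A simulation scenario configuration is internally inconsistent."""


class PositivityError(HypoestimandError):
    """An estimation subset required by the method is empty — typically a sign
    that the positivity assumption fails in the sample."""


class SingularDesignError(HypoestimandError):
    """The design matrix for a regression fit is rank deficient."""

    def __init__(self, message: str, collinear_terms=()):
        super().__init__(message)
        self.collinear_terms = tuple(collinear_terms)


class SeparationError(HypoestimandError):
    """A logistic ICE model is perfectly separated; its fitted probabilities
    degenerate to 0/1.  If the mechanism really is deterministic, supply it as
    a known mechanism instead of estimating it."""


class InfiniteWeightError(HypoestimandError):
    """A required inverse-probability weight is infinite (a fitted probability
    of exactly zero for an observed history)."""

    def __init__(self, message: str, patient_ids=()):
        super().__init__(message)
        self.patient_ids = tuple(patient_ids)


class PairingError(HypoestimandError):
    """An equivalence certification was requested for an estimator pairing that
    the underlying identity does not cover."""


class EstimationError(HypoestimandError):
    """Generic estimation failure (e.g. no eligible patients in an arm)."""
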