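"""Estimator specification and result containers."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .data import EstimandSpec
from .errors import ValidationError

METHODS = ("gformula", "gformula_mc", "ipw", "mle_mar", "mi", "naive")
SCOPES = ("ice_free_only", "all_data")
POOLINGS = ("per_arm", "pooled")
ICE_MECHANISMS = ("fitted", "known")


@dataclass(frozen=True)
class EstimatorSpec:
    """Which estimator to run, and with which model-fitting variant.

    ``model_scope`` selects the data used to fit the outcome (and L2) models:
    ``ice_free_only`` fits only among patients still ICE-free at the modeled
    stage (fewest assumptions), ``all_data`` fits on everyone with the ICE
    indicators as covariates (potentially more precise, more assumptions).
    ``arm_pooling`` selects separate models per randomized arm or a single
    pooled model with the arm indicator as a covariate.

    Formula fields are patsy right-hand sides over the covariate columns
    (e.g. ``"L0 * L1"`` for a saturated binary-covariate model); treatment and
    ICE indicator columns are appended automatically as main effects according
    to scope and pooling.  ``None`` means main effects of all covariates.
    """

    method: str = "gformula"
    model_scope: str = "ice_free_only"
    arm_pooling: str = "per_arm"
    outcome_formula: str | None = None
    l2_formula: str | None = None
    ice_formula: str | None = None
    ice_mechanism: str = "fitted"
    rand_prob: float = 0.5
    n_mc: int = 1000
    n_imputations: int = 50
    seed: int | None = None

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValidationError(f"unknown method {self.method!r}; one of {METHODS}")
        if self.model_scope not in SCOPES:
            raise ValidationError(f"unknown model_scope {self.model_scope!r}; one of {SCOPES}")
        if self.arm_pooling not in POOLINGS:
            raise ValidationError(f"unknown arm_pooling {self.arm_pooling!r}; one of {POOLINGS}")
        if self.ice_mechanism not in ICE_MECHANISMS:
            raise ValidationError(
                f"unknown ice_mechanism {self.ice_mechanism!r}; one of {ICE_MECHANISMS}"
            )
        if not 0 < self.rand_prob < 1:
            raise ValidationError("rand_prob must lie strictly inside (0, 1)")
        if self.n_mc < 1:
            raise ValidationError("n_mc must be >= 1")
        if self.n_imputations < 2:
            raise ValidationError("n_imputations must be >= 2")

    def with_seed(self, seed: int) -> "EstimatorSpec":
        return replace(self, seed=int(seed))


@dataclass
class EstimateResult:
    """Point estimate with optional bootstrap/Rubin inference and provenance."""

    estimand: EstimandSpec
    point: float
    spec: EstimatorSpec
    n_used: int
    se: float | None = None
    ci: tuple[float, float] | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        import math

        if not math.isfinite(self.point):
            raise ValidationError("estimate is not finite")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        bits = [f"point={self.point:.4f}"]
        if self.se is not None:
            bits.append(f"se={self.se:.4f}")
        if self.ci is not None:
            bits.append(f"ci=({self.ci[0]:.4f}, {self.ci[1]:.4f})")
        return f"EstimateResult({', '.join(bits)}, method={self.spec.method})"
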