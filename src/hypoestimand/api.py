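"""High-level estimation entry points.

``estimate_arm`` dispatches an :class:`EstimatorSpec` to the matching
estimator; ``estimate_contrast`` forms the between-arm difference
E(Y^{1,0,...}) − E(Y^{0,0,...}).  The naive comparator — the unadjusted mean
difference among ICE-free patients, i.e. what one gets by discarding patients
after the ICE without any adjustment — is included as the foil the adjusted
methods are measured against.
"""

from __future__ import annotations

import numpy as np

from .data import EstimandSpec, TrialDataset
from .errors import EstimationError, ValidationError
from .gformula import gformula_monte_carlo, gformula_single, gformula_two_timepoint
from .ipw import KnownIceMechanism, compute_weights, fit_ice_models, ipw_estimate
from .specs import EstimateResult, EstimatorSpec

__all__ = ["estimate_arm", "estimate_contrast", "naive_ice_free_estimate"]


def naive_ice_free_estimate(data: TrialDataset, arm: int, spec: EstimatorSpec | None = None) -> EstimateResult:
    """Unadjusted mean of Y among ICE-free patients in the arm.

    This estimator conditions on remaining ICE-free without adjusting for the
    covariates that drive the ICE, so it is biased for the hypothetical mean
    whenever those covariates also affect the outcome.
    """
    spec = spec or EstimatorSpec(method="naive")
    af = data.analysis_frame()
    mask = (af["A0"] == arm) & data.ice_free() & af["Y"].notna()
    if not mask.any():
        raise EstimationError(f"no ICE-free patients with observed outcome in arm {arm}")
    return EstimateResult(
        estimand=EstimandSpec(regime=(arm,) + (0,) * data.k),
        point=float(af.loc[mask, "Y"].mean()),
        spec=spec,
        n_used=int(mask.sum()),
    )


def estimate_arm(
    data: TrialDataset,
    arm: int,
    spec: EstimatorSpec,
    ice_mechanism: KnownIceMechanism | tuple | None = None,
) -> EstimateResult:
    """Estimate E(Y^{a0, 0[, 0]}) for one arm with the requested estimator.

    ``ice_mechanism`` supplies the known ICE mechanism for IPW when
    ``spec.ice_mechanism == "known"`` (e.g. a deterministic protocol rule).
    """
    from .mar import mi_estimate, mle_mar_estimate

    if spec.method == "gformula":
        fn = gformula_single if data.k == 1 else gformula_two_timepoint
        return fn(data, arm, spec)
    if spec.method == "gformula_mc":
        return gformula_monte_carlo(data, arm, spec)
    if spec.method == "mle_mar":
        return mle_mar_estimate(data, arm, spec)
    if spec.method == "mi":
        return mi_estimate(data, arm, spec)
    if spec.method == "naive":
        return naive_ice_free_estimate(data, arm, spec)
    if spec.method == "ipw":
        if spec.ice_mechanism == "known":
            if ice_mechanism is None:
                raise ValidationError(
                    "spec.ice_mechanism='known' requires passing the mechanism "
                    "(a KnownIceMechanism or tuple of mechanisms)"
                )
            models = ice_mechanism
        else:
            models = fit_ice_models(data, spec)
        weights = compute_weights(data, models, rand_prob=spec.rand_prob)
        res = ipw_estimate(data, weights, arm)
        res.spec = spec
        return res
    raise ValidationError(f"unknown method {spec.method!r}")


def estimate_contrast(
    data: TrialDataset,
    spec: EstimatorSpec,
    ice_mechanism: KnownIceMechanism | tuple | None = None,
) -> EstimateResult:
    """Estimate the hypothetical treatment effect E(Y^{1,0..}) − E(Y^{0,0..})."""
    r1 = estimate_arm(data, 1, spec, ice_mechanism)
    r0 = estimate_arm(data, 0, spec, ice_mechanism)
    return EstimateResult(
        estimand=EstimandSpec(regime=(1,) + (0,) * data.k, contrast=True),
        point=r1.point - r0.point,
        spec=spec,
        n_used=r1.n_used + r0.n_used,
        diagnostics={"arm1": r1.point, "arm0": r0.point},
    )
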