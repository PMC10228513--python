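"""G-formula (G-computation) plug-in estimators of the hypothetical no-ICE mean.

The estimand is E(Y^{a0, 0[, 0]}): the mean outcome had everyone been
randomized to arm ``a0`` and the intercurrent event been prevented.  The
G-formula standardizes an outcome regression over the empirical distribution
of the pre-ICE covariates among patients randomized to the arm:

* one ICE timepoint: fit E(Y | A0, A1, L0, L1) (or, restricting to ICE-free
  patients, E(Y | A0, A1=0, L0, L1)), predict for every patient in the arm
  with the ICE indicator set to 0, and average the predictions;
* two ICE timepoints: additionally fit E(L2 | A0, A1=0, L0, L1), predict each
  patient's L2 under no ICE, feed the prediction into the outcome model, and
  average.  For linear models this sequential-regression composition is exact;
  a Monte-Carlo variant that simulates L2 from its fitted residual
  distribution is provided as the generalizable alternative.

Model-scope and arm-pooling variants trade modeling assumptions against
precision: ``ice_free_only`` uses no post-ICE data at all, ``all_data`` uses
every observed outcome with the ICE indicators as covariates; ``per_arm``
fits separate models by randomized arm, ``pooled`` one model with the arm
indicator as covariate.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from ._lm import Design, OlsFit, fit_ols
from .data import EstimandSpec, TrialDataset
from .errors import EstimationError, PositivityError, ValidationError
from .specs import EstimateResult, EstimatorSpec

__all__ = [
    "gformula_single",
    "gformula_two_timepoint",
    "gformula_monte_carlo",
]


def _outcome_fit_frame(af: pd.DataFrame, data: TrialDataset, arm: int, spec: EstimatorSpec):
    """Rows and indicator columns for the outcome-model fit."""
    if spec.model_scope == "ice_free_only":
        mask = af["A1"] == 0
        if data.k == 2:
            mask &= af["A2"] == 0
        extra: tuple[str, ...] = ()
    else:
        mask = pd.Series(True, index=af.index)
        extra = ("A1", "A2") if data.k == 2 else ("A1",)
    if spec.arm_pooling == "per_arm":
        mask &= af["A0"] == arm
    else:
        extra = ("A0", *extra)

    observed = af["Y"].notna()
    n_dropped = int((mask & ~observed).sum())
    if spec.model_scope == "all_data" and n_dropped:
        warnings.warn(
            f"all_data scope: {n_dropped} row(s) with missing post-ICE Y dropped from "
            "the outcome-model fit",
            stacklevel=3,
        )
    return af[mask & observed], extra, n_dropped


def _predict_overrides(arm: int, extra: tuple[str, ...]) -> dict[str, float]:
    """Set every appended indicator to the regime value (arm for A0, 0 for ICEs)."""
    ov = {c: 0.0 for c in extra if c != "A0"}
    if "A0" in extra:
        ov["A0"] = float(arm)
    return ov


def _fit_l2_models(af: pd.DataFrame, data: TrialDataset, arm: int, spec: EstimatorSpec):
    """Per-component OLS fits for E(L2 | history) on the scope-implied subset."""
    if spec.model_scope == "ice_free_only":
        mask = af["A1"] == 0
        extra: tuple[str, ...] = ()
    else:
        mask = pd.Series(True, index=af.index)
        extra = ("A1",)
    if spec.arm_pooling == "per_arm":
        mask &= af["A0"] == arm
    else:
        extra = ("A0", *extra)

    fits: list[OlsFit] = []
    covars = tuple(data.l0_cols + data.l1_cols)
    for col in data.l2_cols:
        sub = af[mask & af[col].notna()]
        if sub.empty:
            raise PositivityError(
                f"no patients available to fit the {col} model "
                f"(scope={spec.model_scope}, pooling={spec.arm_pooling}, arm={arm})"
            )
        design = Design(l_cols=covars, formula=spec.l2_formula, extra_cols=extra)
        fits.append(fit_ols(sub, col, design))
    return fits, extra


def _result(point, arm, spec, n_used, **diag) -> EstimateResult:
    return EstimateResult(
        estimand=EstimandSpec(regime=(arm,) + (0,) * diag.pop("k")),
        point=float(point),
        spec=spec,
        n_used=int(n_used),
        diagnostics=diag,
    )


def gformula_single(data: TrialDataset, arm: int, spec: EstimatorSpec) -> EstimateResult:
    """G-formula estimate of E(Y^{a0, 0}) for a one-timepoint design."""
    if data.k != 1:
        raise ValidationError("gformula_single requires a one-ICE-timepoint dataset")
    af = data.analysis_frame()
    fit_df, extra, n_dropped = _outcome_fit_frame(af, data, arm, spec)
    if fit_df.empty:
        raise PositivityError(
            "no ICE-free patients with observed outcome to fit the outcome model on "
            f"(scope={spec.model_scope}, pooling={spec.arm_pooling}, arm={arm}); "
            "positivity fails in this sample"
        )
    covars = tuple(data.l0_cols + data.l1_cols)
    design = Design(l_cols=covars, formula=spec.outcome_formula, extra_cols=extra)
    fit = fit_ols(fit_df, "Y", design)

    pred_df = af[af["A0"] == arm]
    if pred_df.empty:
        raise EstimationError(f"no patients randomized to arm {arm}")
    preds = fit.predict(pred_df, overrides={"A1": 0.0, **_predict_overrides(arm, extra)})
    return _result(
        preds.mean(), arm, spec, len(fit_df), k=1,
        n_arm=len(pred_df), n_dropped_missing_y=n_dropped,
    )


def gformula_two_timepoint(data: TrialDataset, arm: int, spec: EstimatorSpec) -> EstimateResult:
    """Sequential-regression G-formula estimate of E(Y^{a0, 0, 0}) at K=2.

    The L2 model's prediction under no ICE is substituted into the outcome
    model (exact coefficient composition for linear models), then predictions
    are averaged over the arm's empirical (L0, L1) distribution.
    """
    if data.k != 2:
        raise ValidationError("gformula_two_timepoint requires a two-ICE-timepoint dataset")
    af = data.analysis_frame()
    y_df, y_extra, n_dropped = _outcome_fit_frame(af, data, arm, spec)
    if y_df.empty:
        raise PositivityError(
            "no fully ICE-free patients with observed outcome for the outcome model "
            f"(arm={arm}); positivity fails in this sample"
        )
    covars = tuple(data.l0_cols + data.l1_cols + data.l2_cols)
    y_design = Design(l_cols=covars, formula=spec.outcome_formula, extra_cols=y_extra)
    y_fit = fit_ols(y_df, "Y", y_design)

    l2_fits, l2_extra = _fit_l2_models(af, data, arm, spec)

    pred_df = af[af["A0"] == arm]
    if pred_df.empty:
        raise EstimationError(f"no patients randomized to arm {arm}")
    pred_df = pred_df.copy()
    l2_ov = _predict_overrides(arm, l2_extra)
    l2_ov["A1"] = 0.0
    for col, fit in zip(data.l2_cols, l2_fits):
        pred_df[col] = fit.predict(pred_df, overrides=l2_ov)
    y_ov = _predict_overrides(arm, y_extra)
    y_ov.update({"A1": 0.0, "A2": 0.0})
    preds = y_fit.predict(pred_df, overrides=y_ov)
    return _result(
        preds.mean(), arm, spec, len(y_df), k=2,
        n_arm=len(pred_df), n_l2_fit=l2_fits[0].n, n_dropped_missing_y=n_dropped,
    )


def gformula_monte_carlo(data: TrialDataset, arm: int, spec: EstimatorSpec) -> EstimateResult:
    """Monte-Carlo-integration G-computation at K=2.

    Instead of plugging the L2 conditional mean into the outcome model, L2 is
    simulated ``n_mc`` times per patient from its fitted Gaussian residual
    distribution and the outcome predictions are averaged over the draws.  For
    outcome models linear in L2 this converges to the plug-in composition as
    ``n_mc`` grows; it remains valid for outcome models nonlinear in L2.
    """
    if data.k != 2:
        raise ValidationError("gformula_monte_carlo requires a two-ICE-timepoint dataset")
    if spec.seed is None:
        raise ValidationError("gformula_monte_carlo requires an explicit seed in the spec")
    af = data.analysis_frame()
    y_df, y_extra, _ = _outcome_fit_frame(af, data, arm, spec)
    if y_df.empty:
        raise PositivityError("no patients to fit the outcome model on")
    covars = tuple(data.l0_cols + data.l1_cols + data.l2_cols)
    y_design = Design(l_cols=covars, formula=spec.outcome_formula, extra_cols=y_extra)
    y_fit = fit_ols(y_df, "Y", y_design)
    l2_fits, l2_extra = _fit_l2_models(af, data, arm, spec)

    pred_df = af[af["A0"] == arm].copy()
    if pred_df.empty:
        raise EstimationError(f"no patients randomized to arm {arm}")
    l2_ov = _predict_overrides(arm, l2_extra)
    l2_ov["A1"] = 0.0
    l2_mean = [fit.predict(pred_df, overrides=l2_ov) for fit in l2_fits]
    l2_sd = [np.sqrt(fit.sigma2) for fit in l2_fits]

    rng = np.random.default_rng(spec.seed)
    y_ov = _predict_overrides(arm, y_extra)
    y_ov.update({"A1": 0.0, "A2": 0.0})
    total = np.zeros(len(pred_df))
    for _ in range(spec.n_mc):
        for col, mu, sd in zip(data.l2_cols, l2_mean, l2_sd):
            pred_df[col] = mu + rng.normal(0.0, sd, size=len(pred_df)) if sd > 0 else mu
        total += y_fit.predict(pred_df, overrides=y_ov)
    preds = total / spec.n_mc
    return _result(
        preds.mean(), arm, spec, len(y_df), k=2,
        n_arm=len(pred_df), n_mc=spec.n_mc,
    )
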