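"""Inverse-probability weighting for the hypothetical no-ICE estimand.

Treating the intercurrent event as a time-varying "treatment" to be set to 0,
each patient's unstabilized weight is the product of reciprocal probabilities
of the treatment/ICE values they actually had:

    W_i = 1 / P(A0 = a0_i)  ×  Π_k 1 / P(A_k = a_{k,i} | history)

Under 1:1 randomization the first factor is 1/0.5 = 2 for everyone.  The
estimate of E(Y^{a0, 0[, 0]}) is the normalized (Hajek) weighted mean of Y
over patients whose history matches the regime — randomized to the arm and
ICE-free throughout.

Because "remaining ICE-free" is exactly "having the hypothetical outcome
observed", the same computation is the classical inverse-probability-of-
missingness estimator; :func:`ipw_missingness_estimate` is literally the same
code path under that name.

ICE-probability models are logistic regressions on the history (fitted pooled
or per arm; the timepoint-2 model is fitted among patients still ICE-free at
timepoint 1), or the investigator may supply the known mechanism — relevant
when the protocol triggers the ICE deterministically, in which case every
probability is 0 or 1 and every weight collapses to the randomization factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from patsy import dmatrix
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .data import EstimandSpec, TrialDataset
from .errors import (
    EstimationError,
    InfiniteWeightError,
    PositivityError,
    SeparationError,
)
from .simulate import IceMechanism
from .specs import EstimateResult, EstimatorSpec

__all__ = [
    "IceModelSet",
    "KnownIceMechanism",
    "WeightSet",
    "fit_ice_models",
    "compute_weights",
    "ipw_estimate",
    "ipw_missingness_estimate",
    "positivity_diagnostics",
]


# --------------------------------------------------------------------------
# ICE-probability models
# --------------------------------------------------------------------------


@dataclass
class _LogitFit:
    """One fitted logistic regression for P(A_k = 1 | history)."""

    result: object
    covars: tuple[str, ...]
    formula: str | None
    separated: bool

    def _exog(self, df: pd.DataFrame) -> np.ndarray:
        if self.formula is not None:
            block = np.asarray(dmatrix(self.formula, df), dtype=float)
            extra = [df[c].to_numpy(dtype=float) for c in self.covars if c == "A0"]
            return np.column_stack([block, *extra]) if extra else block
        return np.column_stack(
            [np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in self.covars]
        )

    def prob_ice(self, df: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.result.predict(self._exog(df)), dtype=float)

    @property
    def params(self) -> np.ndarray:
        return np.asarray(self.result.params, dtype=float)

    @property
    def bse(self) -> np.ndarray:
        return np.asarray(self.result.bse, dtype=float)


@dataclass
class IceModelSet:
    """Fitted per-timepoint logistic ICE models (pooled, or one per arm)."""

    k: int
    arm_pooling: str
    fits: dict[tuple[int, int | None], _LogitFit] = field(default_factory=dict)
    # keys: (timepoint, arm) with arm=None for pooled fits

    @property
    def any_separated(self) -> bool:
        return any(f.separated for f in self.fits.values())

    def prob_ice(self, df: pd.DataFrame, timepoint: int) -> np.ndarray:
        """P(A_k = 1 | history) for each row of ``df``."""
        if self.arm_pooling == "pooled":
            return self.fits[(timepoint, None)].prob_ice(df)
        out = np.full(len(df), np.nan)
        a0 = df["A0"].to_numpy()
        for arm in (0, 1):
            m = a0 == arm
            if m.any():
                out[m] = self.fits[(timepoint, arm)].prob_ice(df[m])
        return out


@dataclass
class KnownIceMechanism:
    """The true ICE mechanism, supplied instead of being estimated.

    Wraps the simulator's mechanism objects (logistic or deterministic
    threshold), one per timepoint.
    """

    mechanisms: tuple[IceMechanism, ...]

    def prob_ice(self, df: pd.DataFrame, timepoint: int) -> np.ndarray:
        mech = self.mechanisms[timepoint - 1]
        cols = {c: df[c].to_numpy(dtype=float) for c in df.columns if c != "id"}
        return np.asarray(mech.prob(cols), dtype=float)

    @property
    def any_separated(self) -> bool:
        return False


def _fit_one_logit(df: pd.DataFrame, endog_col: str, covars, formula, separation: str) -> _LogitFit:
    if df.empty:
        raise PositivityError(f"empty fitting subset for the {endog_col} model")
    y = df[endog_col].to_numpy(dtype=float)
    if y.min() == y.max():
        raise SeparationError(
            f"no variation in {endog_col} on its fitting subset (all values {y[0]:g}); "
            "if the ICE mechanism is deterministic, supply it as a known mechanism "
            "instead of estimating it"
        )
    fit_obj = _LogitFit(result=None, covars=tuple(covars), formula=formula, separated=False)
    X = fit_obj._exog(df)
    separated = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            if separation == "error":
                raise SeparationError(
                    f"perfect separation while fitting the {endog_col} model; "
                    "if the ICE mechanism is deterministic, supply it as a known mechanism"
                ) from exc
            # flag mode: fall back to IRLS with a pseudo-inverse so the
            # degenerate fit is still inspectable by the diagnostics
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            separated = True
        for w in caught:
            if issubclass(w.category, (PerfectSeparationWarning, ConvergenceWarning)):
                separated = True
    if separated and separation == "error":
        raise SeparationError(
            f"perfect separation detected while fitting the {endog_col} model; "
            "if the ICE mechanism is deterministic, supply it as a known mechanism"
        )
    fit_obj.result = res
    fit_obj.separated = separated
    return fit_obj


def fit_ice_models(
    data: TrialDataset, spec: EstimatorSpec, separation: str = "error"
) -> IceModelSet:
    """Fit logistic models for the ICE probability at each timepoint.

    The timepoint-1 model uses (A0 if pooled,) L0, L1 as covariates on all
    patients; the timepoint-2 model additionally uses L2 and is fitted only
    among patients ICE-free at timepoint 1.  ``separation`` is ``"error"``
    (default: raise :class:`SeparationError`) or ``"flag"`` (keep the fit and
    record the flag, for diagnostics).
    """
    af = data.analysis_frame()
    out = IceModelSet(k=data.k, arm_pooling=spec.arm_pooling)

    def covars_for(timepoint: int) -> list[str]:
        cols = data.l0_cols + data.l1_cols
        if timepoint == 2:
            cols = cols + data.l2_cols
        if spec.arm_pooling == "pooled":
            cols = ["A0"] + cols
        return cols

    for timepoint in range(1, data.k + 1):
        endog = f"A{timepoint}"
        sub = af if timepoint == 1 else af[af["A1"] == 0]
        if spec.arm_pooling == "pooled":
            out.fits[(timepoint, None)] = _fit_one_logit(
                sub, endog, covars_for(timepoint), spec.ice_formula, separation
            )
        else:
            for arm in (0, 1):
                out.fits[(timepoint, arm)] = _fit_one_logit(
                    sub[sub["A0"] == arm], endog, covars_for(timepoint),
                    spec.ice_formula, separation,
                )
    return out


# --------------------------------------------------------------------------
# weights
# --------------------------------------------------------------------------


@dataclass
class WeightSet:
    """Unstabilized weights plus the fitted probabilities that produced them.

    ``table`` has one row per patient: ``id``, ``weight``, ``included``
    (treatment/ICE history matches the no-ICE regime), and the per-timepoint
    probability of the patient's *observed* ICE value.  Weights are finite for
    every included patient; a non-included patient may carry an infinite
    weight if an estimated probability degenerates, which never enters the
    estimate.
    """

    table: pd.DataFrame
    models: IceModelSet | KnownIceMechanism
    rand_prob_used: float


def compute_weights(
    data: TrialDataset,
    models: IceModelSet | KnownIceMechanism | IceMechanism | tuple,
    rand_prob: float = 0.5,
    truncate_at: float | None = None,
) -> WeightSet:
    """Unstabilized inverse-probability weights for every patient.

    ``models`` is a fitted :class:`IceModelSet`, a :class:`KnownIceMechanism`,
    or (for convenience) one simulator mechanism / tuple of mechanisms.  The
    factor at timepoint k is 1 / P(A_k = a_{k,i} | history); for patients with
    an earlier ICE the later factor is 1 because the ICE pattern is absorbing.

    ``truncate_at`` caps weights at the given value, keeping the untruncated
    weight in a ``weight_untruncated`` column.  Truncation departs from the
    definition of the unstabilized weight and changes what is being estimated;
    it is offered as a diagnostic aid only and is off by default.
    """
    if not 0 < rand_prob < 1:
        raise EstimationError("rand_prob must lie strictly inside (0, 1)")
    if isinstance(models, IceMechanism):
        models = KnownIceMechanism((models,))
    elif isinstance(models, tuple):
        models = KnownIceMechanism(models)

    af = data.analysis_frame()
    a0 = af["A0"].to_numpy()
    p_assigned = np.where(a0 == 1, rand_prob, 1.0 - rand_prob)
    weight = 1.0 / p_assigned

    included = data.ice_free().to_numpy()
    probs: dict[str, np.ndarray] = {}
    for timepoint in range(1, data.k + 1):
        ak = af[f"A{timepoint}"].to_numpy()
        p_ice = models.prob_ice(af, timepoint)
        p_obs = np.where(ak == 1, p_ice, 1.0 - p_ice)
        if timepoint == 2:
            # absorbing pattern: P(A2=1 | A1=1) = 1 by construction
            p_obs = np.where(af["A1"].to_numpy() == 1, 1.0, p_obs)
        probs[f"p_obs_a{timepoint}"] = p_obs
        with np.errstate(divide="ignore"):
            weight = weight / p_obs

    bad = included & ~np.isfinite(weight)
    if bad.any():
        ids = af.loc[bad, "id"].tolist()
        raise InfiniteWeightError(
            "fitted probability of the observed ICE-free history is 0 for patients: "
            + ", ".join(map(str, ids)),
            patient_ids=ids,
        )

    table = pd.DataFrame({"id": af["id"], "weight": weight, "included": included, **probs})
    if truncate_at is not None:
        if truncate_at <= 0:
            raise EstimationError("truncate_at must be positive")
        table["weight_untruncated"] = table["weight"]
        table["weight"] = np.minimum(table["weight"], truncate_at)
    return WeightSet(table=table, models=models, rand_prob_used=float(rand_prob))


def ipw_estimate(data: TrialDataset, weights: WeightSet, arm: int) -> EstimateResult:
    """Hajek (normalized) weighted mean of Y over regime-compatible patients."""
    af = data.analysis_frame()
    mask = weights.table["included"].to_numpy() & (af["A0"].to_numpy() == arm)
    mask &= af["Y"].notna().to_numpy()
    if not mask.any():
        raise EstimationError(
            f"no ICE-free patients with observed outcome in arm {arm}; "
            "the Hajek denominator is zero"
        )
    w = weights.table.loc[mask, "weight"].to_numpy()
    y = af.loc[mask, "Y"].to_numpy(dtype=float)
    point = float(np.sum(w * y) / np.sum(w))
    spec = EstimatorSpec(method="ipw", rand_prob=weights.rand_prob_used)
    return EstimateResult(
        estimand=EstimandSpec(regime=(arm,) + (0,) * data.k),
        point=point,
        spec=spec,
        n_used=int(mask.sum()),
        diagnostics={"sum_weights": float(np.sum(w))},
    )


def ipw_missingness_estimate(data: TrialDataset, weights: WeightSet, arm: int) -> EstimateResult:
    """Inverse-probability-of-missingness estimate of the hypothetical mean.

    The hypothetical outcome is observed exactly for ICE-free patients, so the
    missing-data weighting estimator *is* the treatment-weighting estimator;
    this entry point simply calls :func:`ipw_estimate` (same code path, hence
    bit-identical results).
    """
    return ipw_estimate(data, weights, arm)


def positivity_diagnostics(weights: WeightSet, prob_floor: float = 1e-3) -> dict:
    """Weight and fitted-probability diagnostics for the positivity assumption.

    Returns min/max/mean weight among included patients, the effective sample
    size (ΣW)²/ΣW², the smallest fitted probability of remaining ICE-free, a
    count of probabilities below ``prob_floor`` with the corresponding flag,
    and whether any ICE model showed separation.
    """
    t = weights.table
    inc = t[t["included"]]
    w = inc["weight"].to_numpy()
    prob_cols = [c for c in t.columns if c.startswith("p_obs_a")]
    # probability of remaining ICE-free at each timepoint, among the included
    min_prob = float(min(inc[c].min() for c in prob_cols)) if len(inc) and prob_cols else np.nan
    n_below = int(sum((inc[c] < prob_floor).sum() for c in prob_cols)) if len(inc) else 0
    return {
        "n_included": int(len(inc)),
        "min_weight": float(w.min()) if len(w) else np.nan,
        "max_weight": float(w.max()) if len(w) else np.nan,
        "mean_weight": float(w.mean()) if len(w) else np.nan,
        "ess": float(w.sum() ** 2 / np.sum(w**2)) if len(w) else 0.0,
        "min_no_ice_prob": min_prob,
        "n_prob_below_floor": n_below,
        "prob_floor": float(prob_floor),
        "low_probability_flag": bool(n_below > 0),
        "separation_flag": bool(weights.models.any_separated),
    }
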