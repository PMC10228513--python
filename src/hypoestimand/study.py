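"""Bootstrap inference and desk-scale replication studies.

``bootstrap_ci`` resamples whole patients (nonparametric bootstrap across the
trial, not within arm/ICE strata) and refits every nuisance model in each
resample.  ``run_simulation_study`` replays a set of scenarios × estimators
over many simulated trials and reports bias against the simulator's exact
truth, empirical SD, mean bootstrap SE, and 95% CI coverage — coverage is
evaluated against the true estimand, so a misspecified estimator shows up as
under-coverage rather than being graded against its own limit.

Seed partitioning: the dataset of replicate ``r`` of scenario ``s`` depends
only on ``(study seed, s, r)`` and the estimator's internal seed only on
``(study seed, s, e, r)``, so any single cell can be recomputed in isolation
and reproduces its numbers exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .api import estimate_arm, estimate_contrast
from .data import EstimandSpec, TrialDataset
from .errors import EstimationError, HypoestimandError, ValidationError
from .ipw import KnownIceMechanism
from .simulate import ScenarioConfig, simulate_trial, true_estimand
from .specs import EstimatorSpec

__all__ = [
    "StudyConfig",
    "bootstrap_ci",
    "BootstrapResult",
    "run_simulation_study",
    "run_study_cell",
    "format_results_table",
]


def _derive_seed(*entropy: int) -> int:
    """Stable sub-stream seed below 2**31 from a tuple of integers."""
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] % (2**31))


@dataclass
class BootstrapResult:
    se: float
    ci: tuple[float, float]
    n_failed: int
    estimates: np.ndarray | None = None


def bootstrap_ci(
    data: TrialDataset,
    spec: EstimatorSpec,
    B: int,
    seed: int,
    contrast: bool = True,
    arm: int = 1,
    ice_mechanism: KnownIceMechanism | tuple | None = None,
    max_failure_frac: float = 0.10,
) -> BootstrapResult:
    """Nonparametric patient-level bootstrap SE and percentile 95% CI.

    Every resample refits all nuisance models from scratch.  Resamples in
    which estimation fails (e.g. an empty ICE-free stratum) are dropped and
    counted; more than ``max_failure_frac`` failures is an error.
    """
    if B < 50:
        raise ValidationError("bootstrap requires B >= 50")
    rng = np.random.default_rng(seed)
    n = data.n
    ests = []
    n_failed = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        boot = TrialDataset(data.df.iloc[idx].reset_index(drop=True), data.k, validate=False)
        bspec = spec if spec.seed is None else spec.with_seed(_derive_seed(spec.seed, b))
        try:
            if contrast:
                ests.append(estimate_contrast(boot, bspec, ice_mechanism).point)
            else:
                ests.append(estimate_arm(boot, arm, bspec, ice_mechanism).point)
        except HypoestimandError:
            n_failed += 1
    if n_failed > max_failure_frac * B:
        raise EstimationError(
            f"bootstrap failed in {n_failed}/{B} resamples (> {max_failure_frac:.0%})"
        )
    arr = np.asarray(ests)
    se = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    lo, hi = np.percentile(arr, [2.5, 97.5])
    return BootstrapResult(se=se, ci=(float(lo), float(hi)), n_failed=n_failed, estimates=arr)


@dataclass(frozen=True)
class StudyConfig:
    """A replication study: scenarios × estimators × replicates."""

    scenarios: tuple[ScenarioConfig, ...]
    estimators: tuple[tuple[str, EstimatorSpec], ...]  # (label, spec)
    n_reps: int = 500
    bootstrap_B: int = 0  # 0 disables bootstrap SE / coverage
    seed: int = 0
    contrast: bool = True
    arm: int = 1

    def __post_init__(self):
        if self.n_reps < 2:
            raise ValidationError("n_reps must be >= 2")
        labels = [lab for lab, _ in self.estimators]
        if len(set(labels)) != len(labels):
            raise ValidationError("estimator labels must be unique")


def _scenario_mechanisms(scenario: ScenarioConfig) -> KnownIceMechanism:
    mechs = (scenario.ice1,) if scenario.k_ice_times == 1 else (scenario.ice1, scenario.ice2)
    return KnownIceMechanism(mechs)


def run_study_cell(config: StudyConfig, scenario_index: int, estimator_index: int) -> pd.DataFrame:
    """All replicates of one (scenario, estimator) cell, one row per replicate."""
    scenario = config.scenarios[scenario_index]
    label, spec = config.estimators[estimator_index]
    estimand = EstimandSpec(
        regime=(config.arm,) + (0,) * scenario.k_ice_times, contrast=config.contrast
    )
    truth = true_estimand(scenario, estimand)
    known = _scenario_mechanisms(scenario) if spec.ice_mechanism == "known" else None

    rows = []
    for rep in range(config.n_reps):
        data_seed = _derive_seed(config.seed, scenario_index, rep)
        est_seed = _derive_seed(config.seed, scenario_index, estimator_index, rep)
        rspec = spec.with_seed(est_seed) if spec.method in ("gformula_mc", "mi") else spec
        rec = {"scenario": scenario.name or f"s{scenario_index}", "estimator": label,
               "rep": rep, "true_value": truth}
        try:
            data = simulate_trial(scenario, seed=data_seed)
            if config.contrast:
                rec["estimate"] = estimate_contrast(data, rspec, known).point
            else:
                rec["estimate"] = estimate_arm(data, config.arm, rspec, known).point
            if config.bootstrap_B:
                boot = bootstrap_ci(
                    data, rspec, config.bootstrap_B, seed=_derive_seed(est_seed, 1),
                    contrast=config.contrast, arm=config.arm, ice_mechanism=known,
                )
                rec["boot_se"] = boot.se
                rec["ci_lo"], rec["ci_hi"] = boot.ci
                rec["covered"] = boot.ci[0] <= truth <= boot.ci[1]
            rec["failed"] = False
        except HypoestimandError as exc:
            rec["failed"] = True
            rec["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(rec)
    return pd.DataFrame(rows)


def run_simulation_study(config: StudyConfig) -> pd.DataFrame:
    """Summary table over all cells.

    Columns: mean estimate, bias vs the exact truth, Monte-Carlo SE of the
    bias, empirical SD, mean bootstrap SE, 95% coverage, failure count.
    """
    summaries = []
    for si in range(len(config.scenarios)):
        for ei in range(len(config.estimators)):
            reps = run_study_cell(config, si, ei)
            ok = reps[~reps["failed"]]
            est = ok["estimate"].to_numpy(dtype=float) if len(ok) else np.array([])
            truth = reps["true_value"].iloc[0]
            row = {
                "scenario": reps["scenario"].iloc[0],
                "estimator": reps["estimator"].iloc[0],
                "n_reps": len(reps),
                "n_failed": int(reps["failed"].sum()),
                "true_value": truth,
                "mean_estimate": est.mean() if len(est) else np.nan,
                "bias": est.mean() - truth if len(est) else np.nan,
                "empirical_sd": est.std(ddof=1) if len(est) > 1 else np.nan,
            }
            row["mc_se_bias"] = (
                row["empirical_sd"] / np.sqrt(len(est)) if len(est) > 1 else np.nan
            )
            if config.bootstrap_B and len(ok):
                row["mean_boot_se"] = float(ok["boot_se"].mean())
                row["coverage"] = float(ok["covered"].mean())
            else:
                row["mean_boot_se"] = np.nan
                row["coverage"] = np.nan
            summaries.append(row)
    return pd.DataFrame(summaries)


def format_results_table(results: pd.DataFrame) -> str:
    """Aligned text rendering of a study summary table."""
    return results.to_string(
        index=False,
        float_format=lambda v: f"{v:10.4f}",
    )
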