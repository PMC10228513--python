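"""Trial simulator with counterfactual ground truth.

The data-generating process follows the causal graph of a randomized trial in
which an intercurrent event (ICE) such as rescue medication can occur at one
or two post-baseline timepoints:

    L0 -> A0(randomized) -> L1 -> A1 [-> L2 -> A2] -> Y

All structural models are linear with Gaussian noise; the ICE mechanism is
either logistic in the history or a deterministic threshold rule (the ICE is
triggered if and only if a marker exceeds a protocol threshold, which violates
positivity by design).

Counterfactual outcomes under the no-ICE regime of each arm are drawn in the
same pass, sharing every exogenous noise draw with the factual world
(single-world coupling).  Consequently consistency holds *exactly*: a patient
whose factual history equals the regime (randomized to the arm, no ICE) has a
factual outcome identical to the counterfactual one.  Counterfactual columns
exist only to provide ground truth for simulation studies; estimators never
see them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import EstimandSpec, TrialDataset
from .errors import ScenarioError

# --------------------------------------------------------------------------
# scenario configuration
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class GaussianSpec:
    """Marginal normal law of one baseline covariate component."""

    mean: float
    sd: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ScenarioError("baseline covariate SD must be > 0")


@dataclass(frozen=True)
class LinearModel:
    """Linear-Gaussian structural equation: value = intercept + coef·parents + N(0, sd)."""

    intercept: float
    coef: dict[str, float] = field(default_factory=dict)
    sd: float = 1.0

    def __post_init__(self):
        if self.sd < 0:
            raise ScenarioError("residual SD must be >= 0")

    def mean(self, cols: dict[str, np.ndarray]) -> np.ndarray:
        out = np.full(_any_len(cols), self.intercept, dtype=float)
        for name, c in self.coef.items():
            out += c * cols[name]
        return out


@dataclass(frozen=True)
class LogisticIce:
    """Stochastic ICE mechanism: P(ICE | history) = expit(intercept + coef·history)."""

    intercept: float
    coef: dict[str, float] = field(default_factory=dict)

    def prob(self, cols: dict[str, np.ndarray]) -> np.ndarray:
        lin = np.full(_any_len(cols), self.intercept, dtype=float)
        for name, c in self.coef.items():
            lin += c * cols[name]
        with np.errstate(over="ignore"):
            return 1.0 / (1.0 + np.exp(-lin))


@dataclass(frozen=True)
class ThresholdIce:
    """Deterministic ICE rule: the ICE occurs iff ``var`` strictly exceeds ``threshold``.

    Ties go to no ICE (strict inequality).  This mechanism violates positivity:
    given the triggering marker, the ICE probability is exactly 0 or 1.
    """

    var: str
    threshold: float

    def prob(self, cols: dict[str, np.ndarray]) -> np.ndarray:
        return (cols[self.var] > self.threshold).astype(float)


IceMechanism = LogisticIce | ThresholdIce


@dataclass(frozen=True)
class ScenarioConfig:
    """Full specification of the data-generating process.

    ``l0`` gives the marginal law of each baseline covariate component; ``l1``
    (and ``l2`` for two-timepoint designs) give one linear-Gaussian structural
    model per component, whose ``coef`` keys name any previously generated
    column (``L0``, ``A0``, ``L1``, ``A1``, ...).  ``ice1``/``ice2`` are the
    ICE mechanisms and ``y`` the outcome model.
    """

    n: int
    k_ice_times: int
    l0: tuple[GaussianSpec, ...]
    l1: tuple[LinearModel, ...]
    ice1: IceMechanism
    y: LinearModel
    l2: tuple[LinearModel, ...] = ()
    ice2: IceMechanism | None = None
    rand_prob: float = 0.5
    seed: int | None = None
    name: str = ""

    def __post_init__(self):
        if self.k_ice_times not in (1, 2):
            raise ScenarioError("k_ice_times must be 1 or 2")
        if not 0 < self.rand_prob < 1:
            raise ScenarioError("rand_prob must lie strictly inside (0, 1)")
        if self.k_ice_times == 2:
            if not self.l2:
                raise ScenarioError("two-timepoint scenario requires l2 models")
            if self.ice2 is None:
                if isinstance(self.ice1, ThresholdIce):
                    raise ScenarioError(
                        "deterministic scenario with K=2 needs a second threshold rule"
                    )
                raise ScenarioError("two-timepoint scenario requires an ice2 mechanism")

    @property
    def ice_mode(self) -> str:
        return "deterministic" if isinstance(self.ice1, ThresholdIce) else "stochastic"


def _any_len(cols: dict[str, np.ndarray]) -> int:
    return len(next(iter(cols.values())))


def _block_names(prefix: str, k: int) -> list[str]:
    return [prefix] if k == 1 else [f"{prefix}_{j + 1}" for j in range(k)]


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------


def simulate_trial(scenario: ScenarioConfig, seed: int | None = None) -> TrialDataset:
    """Draw one trial from the scenario's structural models.

    The factual world is generated in topological order; the two
    counterfactual worlds (arm 0 and arm 1, ICE forced off) reuse the same
    exogenous noise.  The returned dataset carries ``cf_Y_0`` and ``cf_Y_1``.
    """
    seed = scenario.seed if seed is None else seed
    if seed is None:
        raise ScenarioError("a seed is required (either in the scenario or as an argument)")
    rng = np.random.default_rng(seed)
    n = scenario.n

    # exogenous draws, shared between factual and counterfactual worlds
    l0_draws = [rng.normal(g.mean, g.sd, size=n) for g in scenario.l0]
    a0 = (rng.uniform(size=n) < scenario.rand_prob).astype(int)
    eps_l1 = [rng.normal(0.0, m.sd, size=n) for m in scenario.l1]
    u1 = rng.uniform(size=n)
    if scenario.k_ice_times == 2:
        eps_l2 = [rng.normal(0.0, m.sd, size=n) for m in scenario.l2]
        u2 = rng.uniform(size=n)
    eps_y = rng.normal(0.0, scenario.y.sd, size=n)

    l0_names = _block_names("L0", len(scenario.l0))
    l1_names = _block_names("L1", len(scenario.l1))
    l2_names = _block_names("L2", len(scenario.l2))

    def world(forced_arm: int | None):
        """Generate one world; ``forced_arm=None`` is the factual world."""
        cols: dict[str, np.ndarray] = dict(zip(l0_names, l0_draws))
        cols["A0"] = a0 if forced_arm is None else np.full(n, forced_arm)
        for name, model, eps in zip(l1_names, scenario.l1, eps_l1):
            cols[name] = model.mean(cols) + eps
        if forced_arm is None:
            p1 = scenario.ice1.prob(cols)
            cols["A1"] = (u1 < p1).astype(int)
        else:
            cols["A1"] = np.zeros(n, dtype=int)
        if scenario.k_ice_times == 2:
            for name, model, eps in zip(l2_names, scenario.l2, eps_l2):
                cols[name] = model.mean(cols) + eps
            if forced_arm is None:
                p2 = scenario.ice2.prob(cols)
                # absorbing: an ICE by time 1 stays an ICE at time 2
                cols["A2"] = np.where(cols["A1"] == 1, 1, (u2 < p2).astype(int))
            else:
                cols["A2"] = np.zeros(n, dtype=int)
        cols["Y"] = scenario.y.mean(cols) + eps_y
        return cols

    factual = world(None)
    cf0 = world(0)
    cf1 = world(1)

    ordered = (
        ["id", *l0_names, "A0", *l1_names, "A1"]
        + (l2_names + ["A2"] if scenario.k_ice_times == 2 else [])
        + ["Y", "cf_Y_0", "cf_Y_1"]
    )
    frame = pd.DataFrame({"id": [f"p{i + 1}" for i in range(n)]})
    for c in ordered[1:-3]:
        frame[c] = factual[c]
    frame["Y"] = factual["Y"]
    frame["cf_Y_0"] = cf0["Y"]
    frame["cf_Y_1"] = cf1["Y"]
    return TrialDataset(frame[ordered], k_ice_times=scenario.k_ice_times)


# --------------------------------------------------------------------------
# closed-form truth
# --------------------------------------------------------------------------


def true_estimand(scenario: ScenarioConfig, spec: EstimandSpec) -> float:
    """Exact E(Y^{a0, 0[, 0]}) for a linear-Gaussian scenario.

    Because every structural equation is linear, expectations compose: the
    regime fixes the treatment/ICE columns, and the expectation of each
    covariate under the regime is obtained by propagating means through the
    structural models in topological order.  No simulation is involved.
    """
    if spec.contrast:
        return _arm_truth(scenario, 1) - _arm_truth(scenario, 0)
    return _arm_truth(scenario, spec.arm)


def _arm_truth(scenario: ScenarioConfig, arm: int) -> float:
    mean: dict[str, float] = {}
    for name, g in zip(_block_names("L0", len(scenario.l0)), scenario.l0):
        mean[name] = g.mean
    mean["A0"] = float(arm)
    for name, model in zip(_block_names("L1", len(scenario.l1)), scenario.l1):
        mean[name] = model.intercept + sum(c * mean[k] for k, c in model.coef.items())
    mean["A1"] = 0.0
    if scenario.k_ice_times == 2:
        for name, model in zip(_block_names("L2", len(scenario.l2)), scenario.l2):
            mean[name] = model.intercept + sum(c * mean[k] for k, c in model.coef.items())
        mean["A2"] = 0.0
    y = scenario.y
    return y.intercept + sum(c * mean[k] for k, c in y.coef.items())


# --------------------------------------------------------------------------
# YAML (de)serialization and packaged default scenarios
# --------------------------------------------------------------------------


def _model_to_dict(m):
    if isinstance(m, LinearModel):
        return {"intercept": m.intercept, "coef": dict(m.coef), "sd": m.sd}
    if isinstance(m, LogisticIce):
        return {"kind": "logistic", "intercept": m.intercept, "coef": dict(m.coef)}
    if isinstance(m, ThresholdIce):
        return {"kind": "threshold", "var": m.var, "threshold": m.threshold}
    raise TypeError(type(m))


def _ice_from_dict(d) -> IceMechanism:
    kind = d.get("kind", "logistic")
    if kind == "logistic":
        return LogisticIce(intercept=d["intercept"], coef=dict(d.get("coef", {})))
    if kind == "threshold":
        return ThresholdIce(var=d["var"], threshold=d["threshold"])
    raise ScenarioError(f"unknown ICE mechanism kind: {kind}")


def scenario_to_dict(s: ScenarioConfig) -> dict:
    d = {
        "name": s.name,
        "n": s.n,
        "k_ice_times": s.k_ice_times,
        "rand_prob": s.rand_prob,
        "seed": s.seed,
        "l0": [{"mean": g.mean, "sd": g.sd} for g in s.l0],
        "l1": [_model_to_dict(m) for m in s.l1],
        "ice1": _model_to_dict(s.ice1),
        "y": _model_to_dict(s.y),
    }
    if s.k_ice_times == 2:
        d["l2"] = [_model_to_dict(m) for m in s.l2]
        d["ice2"] = _model_to_dict(s.ice2)
    return d


def scenario_from_dict(d: dict) -> ScenarioConfig:
    def lm(x):
        return LinearModel(intercept=x["intercept"], coef=dict(x.get("coef", {})), sd=x.get("sd", 1.0))

    return ScenarioConfig(
        name=d.get("name", ""),
        n=int(d["n"]),
        k_ice_times=int(d["k_ice_times"]),
        rand_prob=float(d.get("rand_prob", 0.5)),
        seed=d.get("seed"),
        l0=tuple(GaussianSpec(g["mean"], g["sd"]) for g in d["l0"]),
        l1=tuple(lm(x) for x in d["l1"]),
        ice1=_ice_from_dict(d["ice1"]),
        l2=tuple(lm(x) for x in d.get("l2", [])),
        ice2=_ice_from_dict(d["ice2"]) if "ice2" in d else None,
        y=lm(d["y"]),
    )


def scenario_from_yaml(path: str | Path) -> ScenarioConfig:
    with open(path) as fh:
        return scenario_from_dict(yaml.safe_load(fh))


def scenario_to_yaml(scenario: ScenarioConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(scenario), fh, sort_keys=False)
    return path


def _load_builtin_catalog() -> dict[str, dict]:
    from importlib.resources import files

    text = files("hypoestimand.scenarios").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def builtin_scenario(name: str, n: int | None = None, seed: int | None = None) -> ScenarioConfig:
    """A packaged default scenario, optionally overriding size and seed.

    Available names: ``rescue_k1`` (stochastic ICE, one timepoint, confounded
    by the interim marker), ``rescue_k2`` (two timepoints), ``threshold_k1``
    (deterministic protocol-triggered ICE, positivity violated), ``null_k1``
    (no treatment effect anywhere).
    """
    catalog = _load_builtin_catalog()
    if name not in catalog:
        raise ScenarioError(
            f"unknown builtin scenario {name!r}; available: {', '.join(sorted(catalog))}"
        )
    d = dict(catalog[name])
    d.setdefault("name", name)
    if n is not None:
        d["n"] = n
    if seed is not None:
        d["seed"] = seed
    return scenario_from_dict(d)
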