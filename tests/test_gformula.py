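"""G-formula estimators against collapse cases, a brute-force stratified
oracle, degenerate compositions, and the simulator's exact truth."""

import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest

import hypoestimand as he
from conftest import make_dataset


def _no_ice_dataset():
    rng = np.random.default_rng(4)
    n = 40
    return make_dataset(
        {
            "id": [f"p{i}" for i in range(n)],
            "L0": rng.normal(8, 1, n),
            "A0": rng.integers(0, 2, n),
            "L1": rng.normal(8, 1, n),
            "A1": np.zeros(n, dtype=int),
            "Y": rng.normal(8, 1, n),
        }
    )


def test_no_ice_collapses_to_arm_mean():
    d = _no_ice_dataset()
    for arm in (0, 1):
        expected = d.df.loc[d.df["A0"] == arm, "Y"].mean()
        got = he.gformula_single(d, arm, he.EstimatorSpec()).point
        assert got == pytest.approx(expected, abs=1e-10)


def test_identical_arms_give_zero_contrast():
    rng = np.random.default_rng(8)
    half = {
        "L0": rng.normal(8, 1, 20), "L1": rng.normal(8, 1, 20),
        "A1": rng.integers(0, 2, 20), "Y": rng.normal(8, 1, 20),
    }
    df = pd.DataFrame(
        {
            "id": [f"p{i}" for i in range(40)],
            "L0": np.concatenate([half["L0"]] * 2),
            "A0": np.repeat([0, 1], 20),
            "L1": np.concatenate([half["L1"]] * 2),
            "A1": np.concatenate([half["A1"]] * 2),
            "Y": np.concatenate([half["Y"]] * 2),
        }
    )
    d = he.TrialDataset(df, 1)
    res = he.estimate_contrast(d, he.EstimatorSpec())
    assert res.point == pytest.approx(0.0, abs=1e-12)


def _stratified_oracle(df: pd.DataFrame, arm: int) -> float:
    """Nonparametric G-formula for binary L0, L1 by explicit enumeration."""
    arm_df = df[df["A0"] == arm]
    total = 0.0
    for l0, l1 in itertools.product((0, 1), (0, 1)):
        stratum = arm_df[(arm_df["L0"] == l0) & (arm_df["L1"] == l1)]
        if stratum.empty:
            continue
        p_hat = len(stratum) / len(arm_df)
        ybar = stratum.loc[stratum["A1"] == 0, "Y"].mean()
        total += p_hat * ybar
    return total


def saturated_toy():
    # one arm, all four (L0, L1) strata populated with an ICE-free patient
    return make_dataset(
        {
            "id": [f"p{i}" for i in range(8)],
            "L0": [0, 0, 0, 0, 1, 1, 1, 1],
            "A0": [1] * 8,
            "L1": [0, 0, 1, 1, 0, 0, 1, 1],
            "A1": [0, 1, 0, 0, 0, 0, 0, 1],
            "Y": [5.0, 2.0, 7.0, 8.0, 4.0, 6.0, 9.0, 1.0],
        }
    )


def test_saturated_model_equals_stratified_oracle():
    d = saturated_toy()
    spec = he.EstimatorSpec(outcome_formula="L0 * L1")
    got = he.gformula_single(d, 1, spec).point
    assert got == pytest.approx(_stratified_oracle(d.df, 1), abs=1e-12)


def test_two_timepoint_no_ice_collapses_to_arm_mean():
    rng = np.random.default_rng(12)
    n = 60
    d = make_dataset(
        {
            "id": [f"p{i}" for i in range(n)],
            "L0": rng.normal(8, 1, n), "A0": rng.integers(0, 2, n),
            "L1": rng.normal(8, 1, n), "A1": np.zeros(n, dtype=int),
            "L2": rng.normal(8, 1, n), "A2": np.zeros(n, dtype=int),
            "Y": rng.normal(8, 1, n),
        },
        k=2,
    )
    for arm in (0, 1):
        expected = d.df.loc[d.df["A0"] == arm, "Y"].mean()
        assert he.gformula_two_timepoint(d, arm, he.EstimatorSpec()).point == pytest.approx(
            expected, abs=1e-10
        )


def _degenerate_l2_scenario(n):
    """Zero L2 residual noise, L2 untouched by the ICE, outcome driven by
    (L0, L2) only.  With sd(L2)=0 the full (L0, L1, L2) outcome design would
    be exactly collinear, so the outcome model must exclude L2's parents
    beyond L0 — the restricted formula keeps it identified and correct."""
    sc = he.builtin_scenario("rescue_k2", n=n)
    return dataclasses.replace(
        sc,
        l2=(he.LinearModel(0.8, {"L0": 0.35, "L1": 0.55, "A0": -0.35}, sd=0.0),),
        ice2=he.LogisticIce(-2.0, {"L1": 0.1}),
        y=he.LinearModel(0.5, {"L0": 0.25, "L2": 0.55, "A0": -0.35, "A1": -0.8, "A2": -0.7}, sd=0.5),
    )


def test_degenerate_l2_reduces_to_single_timepoint():
    """With zero L2 residual noise, the two-stage composition equals a
    one-stage fit treating L2 as an observed covariate."""
    sc = _degenerate_l2_scenario(1500)
    d2 = he.simulate_trial(sc, seed=44)
    spec2 = he.EstimatorSpec(outcome_formula="L0 + L2")
    # rebuild as K=1 with bivariate L1 = (L1, L2); factual L2 equals its
    # no-ICE value because nothing upstream of it was touched by the ICE
    df1 = d2.df.rename(columns={"L1": "L1_1", "L2": "L1_2"}).copy()
    df1["A1"] = ((d2.df["A1"] == 1) | (d2.df["A2"] == 1)).astype(int)
    df1 = df1.drop(columns=["A2"])
    d1 = he.TrialDataset(df1, 1)
    spec1 = he.EstimatorSpec(outcome_formula="L0 + L1_2")
    for arm in (0, 1):
        two = he.gformula_two_timepoint(d2, arm, spec2).point
        one = he.gformula_single(d1, arm, spec1).point
        assert two == pytest.approx(one, abs=1e-8)


def test_monte_carlo_degenerate_draw_equals_plugin():
    sc = _degenerate_l2_scenario(400)
    d = he.simulate_trial(sc, seed=19)
    spec = he.EstimatorSpec(outcome_formula="L0 + L2")
    plug = he.gformula_two_timepoint(d, 1, spec).point
    mc_spec = he.EstimatorSpec(
        method="gformula_mc", outcome_formula="L0 + L2", n_mc=1, seed=1
    )
    mc = he.gformula_monte_carlo(d, 1, mc_spec).point
    assert mc == plug


def test_monte_carlo_converges_to_plugin_for_linear_outcome(sim_k2):
    n_mc = 400
    spec = he.EstimatorSpec(method="gformula_mc", n_mc=n_mc, seed=6)
    mc = he.gformula_monte_carlo(sim_k2, 1, spec)
    plug = he.gformula_two_timepoint(sim_k2, 1, he.EstimatorSpec())
    # MC error of the average over patients and draws: |b_L2| * sd_L2 / sqrt(n_arm * n_mc)
    sd_l2 = 0.6
    b_l2 = 0.55
    mc_se = b_l2 * sd_l2 / np.sqrt(mc.diagnostics["n_arm"] * n_mc)
    assert abs(mc.point - plug.point) < 4 * mc_se


def test_monte_carlo_reproducible(sim_k2):
    spec = he.EstimatorSpec(method="gformula_mc", n_mc=50, seed=9)
    assert (
        he.gformula_monte_carlo(sim_k2, 0, spec).point
        == he.gformula_monte_carlo(sim_k2, 0, spec).point
    )


def test_estimate_within_bootstrap_error_of_truth():
    sc = he.builtin_scenario("rescue_k2", n=2000, seed=55)
    d = he.simulate_trial(sc)
    truth = he.true_estimand(sc, he.EstimandSpec(regime=(1, 0, 0), contrast=True))
    spec = he.EstimatorSpec()
    est = he.estimate_contrast(d, spec).point
    boot = he.bootstrap_ci(d, spec, B=120, seed=3)
    assert abs(est - truth) < 3 * boot.se


@pytest.mark.parametrize("scope", ["ice_free_only", "all_data"])
@pytest.mark.parametrize("pooling", ["per_arm", "pooled"])
def test_shuffle_invariance(sim_k1, scope, pooling):
    spec = he.EstimatorSpec(model_scope=scope, arm_pooling=pooling)
    base = he.estimate_contrast(sim_k1, spec).point
    rng = np.random.default_rng(0)
    perm = rng.permutation(sim_k1.n)
    shuffled = he.TrialDataset(sim_k1.df.iloc[perm].reset_index(drop=True), 1)
    assert he.estimate_contrast(shuffled, spec).point == pytest.approx(base, abs=1e-10)


def test_post_ice_corruption_irrelevant_for_ice_free_scope(sim_k2):
    spec = he.EstimatorSpec(model_scope="ice_free_only")
    base = [he.gformula_two_timepoint(sim_k2, a, spec).point for a in (0, 1)]
    df = sim_k2.df.copy()
    post1 = df["A1"] == 1
    df.loc[post1, "L2"] = 999.0
    df.loc[~he.TrialDataset(df, 2).ice_free(), "Y"] = np.nan
    corrupted = he.TrialDataset(df, 2)
    got = [he.gformula_two_timepoint(corrupted, a, spec).point for a in (0, 1)]
    np.testing.assert_array_equal(base, got)


def test_all_data_scope_drops_missing_post_ice_rows_from_fit_only(sim_k1):
    """Rows with missing post-ICE Y leave the all_data fit (with a warning)
    but stay in the standardization population; an explicit statsmodels OLS
    on the complete rows is the oracle."""
    import statsmodels.api as sm

    df = sim_k1.df.copy()
    df.loc[(df["A1"] == 1) & (df.index % 2 == 0), "Y"] = np.nan
    data = he.TrialDataset(df, 1)
    spec = he.EstimatorSpec(model_scope="all_data", arm_pooling="per_arm")
    with pytest.warns(UserWarning, match="missing post-ICE Y"):
        got = he.gformula_single(data, 1, spec).point

    fit_rows = df[(df["A0"] == 1) & df["Y"].notna()]
    X = sm.add_constant(fit_rows[["L0", "L1", "A1"]])
    beta = sm.OLS(fit_rows["Y"], X).fit().params
    arm_rows = df[df["A0"] == 1]
    oracle = (
        beta["const"] + beta["L0"] * arm_rows["L0"] + beta["L1"] * arm_rows["L1"]
    ).mean()  # A1 set to 0
    assert got == pytest.approx(oracle, abs=1e-10)


def test_positivity_error_when_everyone_has_ice():
    d = make_dataset(
        {"id": ["a", "b", "c", "d"], "L0": [1.0, 2.0, 3.0, 4.0], "A0": [1, 1, 0, 0],
         "L1": [1.0, 2.0, 3.0, 4.0], "A1": [1, 1, 0, 0], "Y": [1.0, 2.0, 3.0, 4.0]}
    )
    with pytest.raises(he.PositivityError):
        he.gformula_single(d, 1, he.EstimatorSpec())


def test_singular_design_names_collinear_terms():
    d = make_dataset(
        {"id": [f"p{i}" for i in range(10)],
         "L0": np.linspace(0, 1, 10), "A0": [1] * 10,
         "L1_1": np.linspace(0, 2, 10), "L1_2": np.linspace(0, 2, 10),  # duplicate
         "A1": [0] * 10, "Y": np.linspace(5, 6, 10)}
    )
    with pytest.raises(he.SingularDesignError) as exc:
        he.gformula_single(d, 1, he.EstimatorSpec())
    assert exc.value.collinear_terms
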