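"""Inverse-probability weighting: hand-computed weights, Hajek properties,
logistic model recovery, separation handling, and positivity diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest

import hypoestimand as he
from conftest import make_dataset
from hypoestimand.ipw import WeightSet


def _manual_weightset(ids, weights, included):
    table = pd.DataFrame({"id": ids, "weight": weights, "included": included})
    return WeightSet(table=table, models=he.KnownIceMechanism(()), rand_prob_used=0.5)


def _simple_data(y, a0=None, a1=None):
    n = len(y)
    return make_dataset(
        {
            "id": [f"p{i}" for i in range(n)],
            "L0": np.linspace(0, 1, n),
            "A0": a0 if a0 is not None else [1] * n,
            "L1": np.linspace(1, 2, n),
            "A1": a1 if a1 is not None else [0] * n,
            "Y": y,
        }
    )


def test_hajek_hand_arithmetic():
    d = _simple_data([1.0, 3.0])
    ws = _manual_weightset(["p0", "p1"], [2.0, 4.0], [True, True])
    assert he.ipw_estimate(d, ws, 1).point == pytest.approx(7 / 3, abs=1e-14)


def test_equal_weights_reduce_to_simple_mean():
    y = [2.0, 4.0, 9.0]
    d = _simple_data(y)
    ws = _manual_weightset([f"p{i}" for i in range(3)], [5.0] * 3, [True] * 3)
    assert he.ipw_estimate(d, ws, 1).point == pytest.approx(np.mean(y), abs=1e-14)


def test_estimate_is_convex_combination():
    rng = np.random.default_rng(2)
    y = rng.normal(size=12)
    w = rng.uniform(1, 10, size=12)
    d = _simple_data(y)
    ws = _manual_weightset([f"p{i}" for i in range(12)], w, [True] * 12)
    est = he.ipw_estimate(d, ws, 1).point
    assert y.min() <= est <= y.max()


def test_known_probability_weight_hand_value():
    """P(no ICE) = 0.8 under a known logistic, 1:1 arms -> weight 1/(0.5*0.8)."""
    d = _simple_data([1.0], a1=[0])
    mech = he.LogisticIce(intercept=math.log(0.25), coef={})  # expit = 1/5 exactly
    ws = he.compute_weights(d, (mech,), rand_prob=0.5)
    assert ws.table["weight"].iloc[0] == pytest.approx(2.5, abs=1e-12)


def test_probability_one_no_ice_gives_weight_two_and_arm_mean():
    y = [1.0, 5.0, 6.0]
    d = _simple_data(y)
    mech = he.LogisticIce(intercept=-800.0, coef={})  # P(ICE) underflows to exactly 0
    ws = he.compute_weights(d, (mech,), rand_prob=0.5)
    np.testing.assert_array_equal(ws.table["weight"].to_numpy(), 2.0)
    assert he.ipw_estimate(d, ws, 1).point == pytest.approx(np.mean(y), abs=1e-14)


def test_deterministic_known_mechanism_all_weights_two():
    sc = he.builtin_scenario("threshold_k1", n=200, seed=3)
    d = he.simulate_trial(sc)
    ws = he.compute_weights(d, (sc.ice1,), rand_prob=0.5)
    assert set(np.unique(ws.table["weight"])) == {2.0}
    # and the estimate collapses to the unadjusted ICE-free mean
    for arm in (0, 1):
        assert he.ipw_estimate(d, ws, arm).point == he.naive_ice_free_estimate(d, arm).point


def test_infinite_weight_error_names_patients():
    # mechanism says the ICE is certain, yet patient p0 is ICE-free
    d = _simple_data([1.0], a1=[0])
    mech = he.LogisticIce(intercept=800.0, coef={})
    with pytest.raises(he.InfiniteWeightError) as exc:
        he.compute_weights(d, (mech,), rand_prob=0.5)
    assert "p0" in exc.value.patient_ids


def test_null_ice_model_recovery():
    rng = np.random.default_rng(5)
    n = 20000
    d = make_dataset(
        {
            "id": [f"p{i}" for i in range(n)],
            "L0": rng.normal(size=n), "A0": rng.integers(0, 2, n),
            "L1": rng.normal(size=n), "A1": rng.integers(0, 2, n),
            "Y": rng.normal(size=n),
        }
    )
    models = he.fit_ice_models(d, he.EstimatorSpec(method="ipw", arm_pooling="pooled"))
    fit = models.fits[(1, None)]
    assert np.all(np.abs(fit.params) < 3 * fit.bse + 1e-9)
    assert abs(fit.params[0]) < 0.1  # intercept ~ logit(0.5) = 0


def test_logistic_coefficient_recovery_from_simulator():
    sc = he.builtin_scenario("rescue_k1", n=50_000, seed=8)
    d = he.simulate_trial(sc)
    models = he.fit_ice_models(d, he.EstimatorSpec(method="ipw", arm_pooling="pooled"))
    fit = models.fits[(1, None)]
    # pooled covariates: A0, L0, L1 — truth: intercept -14, A0 0, L0 0, L1 1.7
    truth = {"Intercept": -14.0, "A0": 0.0, "L0": 0.0, "L1": 1.7}
    names = ["Intercept", "A0", "L0", "L1"]
    for name, b, se in zip(names, fit.params, fit.bse):
        assert abs(b - truth[name]) < 3 * se, name


def test_per_arm_fit_equals_independent_subset_fits(sim_k1):
    import statsmodels.api as sm

    models = he.fit_ice_models(sim_k1, he.EstimatorSpec(method="ipw", arm_pooling="per_arm"))
    af = sim_k1.analysis_frame()
    for arm in (0, 1):
        sub = af[af["A0"] == arm]
        X = sm.add_constant(sub[["L0", "L1"]]).to_numpy(dtype=float)
        oracle = sm.Logit(sub["A1"].to_numpy(dtype=float), X).fit(disp=0)
        np.testing.assert_allclose(models.fits[(1, arm)].params, oracle.params, atol=1e-6)


def test_missingness_entry_point_bit_identical(sim_k1, sim_k2):
    for d in (sim_k1, sim_k2):
        models = he.fit_ice_models(d, he.EstimatorSpec(method="ipw"))
        ws = he.compute_weights(d, models, 0.5)
        for arm in (0, 1):
            assert (
                he.ipw_estimate(d, ws, arm).point
                == he.ipw_missingness_estimate(d, ws, arm).point
            )


def test_separation_raises_and_flag_mode_reports():
    sc = he.builtin_scenario("threshold_k1", n=500, seed=13)
    d = he.simulate_trial(sc)
    with pytest.raises(he.SeparationError):
        he.fit_ice_models(d, he.EstimatorSpec(method="ipw"))
    models = he.fit_ice_models(d, he.EstimatorSpec(method="ipw"), separation="flag")
    ws = he.compute_weights(d, models, 0.5)
    diag = he.positivity_diagnostics(ws)
    assert diag["separation_flag"]


def test_no_ice_variation_suggests_known_mechanism():
    d = _simple_data([1.0, 2.0, 3.0, 4.0], a0=[0, 0, 1, 1], a1=[0, 0, 0, 0])
    with pytest.raises(he.SeparationError, match="known mechanism"):
        he.fit_ice_models(d, he.EstimatorSpec(method="ipw"))


def test_positivity_error_for_empty_second_stage_subset():
    d = make_dataset(
        {
            "id": ["a", "b", "c", "d"], "L0": [1.0, 2.0, 3.0, 4.0],
            "A0": [0, 1, 0, 1], "L1": [1.0, 2.0, 3.0, 4.0], "A1": [1, 1, 1, 1],
            "L2": [1.0, 2.0, 3.0, 4.0], "A2": [1, 1, 1, 1], "Y": [1.0] * 4,
        },
        k=2,
    )
    with pytest.raises((he.PositivityError, he.SeparationError)):
        he.fit_ice_models(d, he.EstimatorSpec(method="ipw", arm_pooling="pooled"))


def test_diagnostics_equal_weights_ess():
    ws = _manual_weightset(["a", "b", "c"], [2.0, 2.0, 2.0], [True, True, True])
    diag = he.positivity_diagnostics(ws)
    assert diag["ess"] == pytest.approx(3.0)
    assert diag["min_weight"] == diag["max_weight"] == 2.0


def test_diagnostics_low_probability_flag():
    d = _simple_data([1.0, 2.0], a1=[0, 0])
    p_ice = 1 - 1e-4  # no-ICE probability 1e-4, below the default floor
    mech = he.LogisticIce(intercept=math.log(p_ice / (1 - p_ice)), coef={})
    ws = he.compute_weights(d, (mech,), rand_prob=0.5)
    diag = he.positivity_diagnostics(ws)
    assert diag["low_probability_flag"] and diag["n_prob_below_floor"] == 2


def test_hajek_denominator_zero_is_error():
    d = _simple_data([1.0, 2.0], a0=[0, 0])
    ws = _manual_weightset(["p0", "p1"], [2.0, 2.0], [True, True])
    with pytest.raises(he.EstimationError):
        he.ipw_estimate(d, ws, 1)


def test_weight_truncation_is_opt_in_and_labeled(sim_k1):
    models = he.fit_ice_models(sim_k1, he.EstimatorSpec(method="ipw"))
    plain = he.compute_weights(sim_k1, models, 0.5)
    assert "weight_untruncated" not in plain.table.columns
    cap = float(np.percentile(plain.table["weight"], 60))
    trunc = he.compute_weights(sim_k1, models, 0.5, truncate_at=cap)
    assert trunc.table["weight"].max() <= cap
    np.testing.assert_array_equal(
        trunc.table["weight_untruncated"].to_numpy(), plain.table["weight"].to_numpy()
    )
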