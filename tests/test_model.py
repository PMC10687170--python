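"""Behavioral model: weight fitting, prediction, grid search, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from motorstates.model import (
    InternalStateModel,
    alpha_grid,
    condition_design_rt,
    condition_design_se,
    fit_weights,
    predict_behavior,
)
from motorstates.simulate import GeneratorSpec, simulate_session
from motorstates.states import StateParams, evolve_states
from tests.conftest import make_trials


def test_alpha_grid_matches_search_specification():
    grid = alpha_grid(0.01)
    assert len(grid) == 99
    assert grid[0] == pytest.approx(0.01)
    assert grid[-1] == pytest.approx(0.99)
    np.testing.assert_allclose(np.diff(grid), 0.01)


def test_fit_weights_matches_normal_equations_oracle():
    rng = np.random.default_rng(3)
    X = np.column_stack([np.ones(300), rng.normal(size=(300, 4))])
    beta = np.array([0.5, -1.0, 2.0, 0.0, 0.3])
    y = X @ beta + rng.normal(0, 0.1, 300)
    w, var = fit_weights(X, y)
    oracle = np.linalg.solve(X.T @ X, X.T @ y)
    np.testing.assert_allclose(w, oracle, atol=1e-8)
    assert var == pytest.approx(np.mean((y - X @ oracle) ** 2))


def test_fit_weights_noiseless_and_constant_response():
    rng = np.random.default_rng(4)
    trials = make_trials(rng.uniform(-0.3, 0.3, 40))
    X = condition_design_rt(trials)  # rank deficient by construction
    w_true = rng.normal(size=X.shape[1])
    y = X @ w_true
    w, var = fit_weights(X, y)
    np.testing.assert_allclose(X @ w, y, atol=1e-8)  # fitted values exact
    assert var == pytest.approx(0.0, abs=1e-16)
    w_c, var_c = fit_weights(np.ones((30, 1)), np.full(30, 2.5))
    assert w_c[0] == pytest.approx(2.5) and var_c == pytest.approx(0.0)


def test_fit_weights_rejects_underdetermined():
    with pytest.raises(ValueError):
        fit_weights(np.eye(3), np.zeros(2))


def test_predict_behavior_hand_computed():
    rt_w = pd.Series(0.0, index=["const", "x_se", "x_p"] + [
        "speed[fast]", "speed[slow]", "dir[down]", "dir[right]", "dir[up]", "dir[left]"])
    se_w = pd.Series(0.0, index=["const", "x_se", "x_p", "rt_z"] + [
        f"cell[{s},{p}]" for s in ("fast", "slow") for p in ("unperturbed", "towards", "away")])
    # null model
    assert predict_behavior("fast", "up", "towards", 1.0, -1.0, rt_w, se_w) == (0.0, 0.0)
    # constant-only RT
    rt_w["const"] = 1.0
    assert predict_behavior("slow", "left", "unperturbed", 0.3, 0.7, rt_w, se_w)[0] == 1.0
    # full hand-built linear combination, RT feeding SE
    rt_w[:] = [0.1, -0.5, 0.2, -0.3, 0.3, 0.0, 0.0, 0.15, 0.0, 0.0][: len(rt_w)]
    se_w[["const", "x_se", "x_p", "rt_z", "cell[slow,away]"]] = [0.05, 0.4, -0.1, 0.2, 0.07]
    x_se, x_p = 0.8, 1.5
    rt_z, se = predict_behavior("slow", "up", "away", x_se, x_p, rt_w, se_w)
    rt_expect = 0.1 + (-0.5) * 0.8 + 0.2 * 1.5 + 0.3 + 0.15
    se_expect = 0.05 + 0.4 * 0.8 + (-0.1) * 1.5 + 0.2 * rt_expect + 0.07
    assert rt_z == pytest.approx(rt_expect)
    assert se == pytest.approx(se_expect)
    with pytest.raises(KeyError):
        predict_behavior("fast", "diagonal", "away", 0, 0, rt_w, se_w)


def test_noiseless_session_recovers_exact_grid_point(noiseless_session):
    res = InternalStateModel(noiseless_session.trials).fit()
    assert res.params.alpha_se == pytest.approx(0.5)
    assert res.params.alpha_p == pytest.approx(0.75)
    assert res.metrics.pearson_rt == pytest.approx(1.0, abs=1e-9)
    assert res.metrics.pearson_se == pytest.approx(1.0, abs=1e-9)
    assert res.metrics.r2_rt == pytest.approx(1.0, abs=1e-9)
    assert res.metrics.deviance_rt == pytest.approx(0.0, abs=1e-9)


def test_estimates_reproduce_observation_equations(default_session):
    """Fitted estimates are exactly the weighted design, no hidden terms."""
    res = InternalStateModel(default_session.trials).fit()
    m = res.model
    for i in [0, 5, 100]:
        row = m.completed.iloc[i]
        rt_hat, _ = predict_behavior(
            row["speed"], row["direction"], row["perturbation"],
            res.states.x_se_z[i], res.states.x_p_z[i], res.rt_weights, res.se_weights,
        )
        assert rt_hat == pytest.approx(res.rt_estimate[i], abs=1e-10)
        # SE estimate uses the *observed* z-scored RT as regressor
        se_hat = (
            res.se_weights["const"]
            + res.se_weights["x_se"] * res.states.x_se_z[i]
            + res.se_weights["x_p"] * res.states.x_p_z[i]
            + res.se_weights["rt_z"] * m.rt_z[i]
            + res.se_weights[f"cell[{row['speed']},{row['perturbation']}]"]
        )
        assert se_hat == pytest.approx(res.se_estimate[i], abs=1e-10)


def test_r2_matches_direct_formula_oracle(default_session):
    res = InternalStateModel(default_session.trials).fit()
    y, yhat = res.model.rt_z, res.rt_estimate
    r2_oracle = 1.0 - ((y - yhat) ** 2).sum() / ((y - y.mean()) ** 2).sum()
    assert res.metrics.r2_rt == pytest.approx(r2_oracle, abs=1e-10)
    assert res.metrics.deviance_rt == pytest.approx(((y - yhat) ** 2).sum(), abs=1e-8)


def test_perturbation_free_session_is_safe():
    spec = GeneratorSpec(p_perturb=0.0, n_trials=80, seed=5)
    sess = simulate_session(spec)
    res = InternalStateModel(sess.trials).fit()
    assert np.all(res.states.x_p_raw == 0.0)
    assert res.rt_weights["x_p"] == pytest.approx(0.0, abs=1e-12)  # dead column
    assert "x_p" in res.non_identifiable
    assert np.isfinite(res.rt_estimate).all() and np.isfinite(res.se_estimate).all()


def test_baseline_equals_full_model_when_states_are_zero():
    spec = GeneratorSpec(p_perturb=0.0, n_trials=60, seed=6)
    wr = dict(spec.true_rt_weights, x_se=0.0, x_p=0.0)
    ws = dict(spec.true_se_weights, x_se=0.0, x_p=0.0)
    spec = GeneratorSpec(
        p_perturb=0.0, n_trials=60, seed=6, true_rt_weights=wr, true_se_weights=ws
    )
    sess = simulate_session(spec)
    model = InternalStateModel(sess.trials)
    base = model.fit_baseline()
    # zero-state trace: the baseline regression sees the same design
    assert np.all(base.states.x_se_raw == 0.0)
    assert base.baseline
    full_zero = model._fit_at(StateParams(0.0, 0.0), baseline=True, cv_seed=0)
    np.testing.assert_allclose(base.rt_estimate, full_zero.rt_estimate)


def test_conf_int_state_weights_match_min_norm(default_session):
    """Continuous coefficients are identifiable: both codings agree."""
    res = InternalStateModel(default_session.trials).fit()
    for which, weights in (("rt", res.rt_weights), ("se", res.se_weights)):
        ci = res.conf_int(which)
        for name in ("x_se", "x_p"):
            assert ci.loc[name, "estimate"] == pytest.approx(weights[name], abs=1e-8)
            assert ci.loc[name, "lower"] < weights[name] < ci.loc[name, "upper"]


def test_model_requires_enough_trials():
    with pytest.raises(ValueError, match=">= 20"):
        InternalStateModel(make_trials(np.linspace(-0.1, 0.1, 10)))


def test_summary_mentions_key_quantities(default_session):
    res = InternalStateModel(default_session.trials).fit()
    text = res.summary()
    assert "alpha_SE" in text and "RT model" in text and "SE weights" in text
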