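"""Cox fit and the Grambsch-Therneau proportionality test."""

import numpy as np
import pandas as pd
import pytest

from lipidjm.cox import fit_cox, schoenfeld_test

TOY = pd.DataFrame({"event_time": [1.0, 2.0, 3.0, 4.0],
                    "event": [1, 1, 0, 1],
                    "x": [1.0, 0.0, 1.0, 0.0]})


def toy_partial_loglik(g):
    """Hand-written partial likelihood of the 4-row toy set (no ties).

    Events at t=1 (x=1, risk set {1,2,3,4}), t=2 (x=0, risk set {2,3,4})
    and t=4 (x=0, risk set {4}); the t=3 subject is censored.
    """
    g = np.asarray(g, float)
    ll = g - np.log(2 * np.exp(g) + 2)      # t=1
    ll = ll - np.log(np.exp(g) + 2)         # t=2
    return ll                               # t=4 contributes 0


def test_toy_gamma_matches_grid_maximization():
    fit = fit_cox(TOY, ["x"])
    grid = np.linspace(-3, 3, 600001)
    g_star = grid[np.argmax(toy_partial_loglik(grid))]
    assert fit.gamma[0] == pytest.approx(g_star, abs=1e-5)
    assert fit.partial_loglik == pytest.approx(float(toy_partial_loglik(fit.gamma[0])), abs=1e-8)


def test_constant_covariate_gives_zero_effect():
    df = TOY.assign(x=1.0)
    fit = fit_cox(df, ["x"])
    assert fit.gamma[0] == pytest.approx(0.0, abs=1e-6)
    assert fit.partial_loglik == pytest.approx(toy_partial_loglik(0.0), abs=1e-8)


def test_rescaling_covariate_halves_coefficient():
    f1 = fit_cox(TOY, ["x"])
    f2 = fit_cox(TOY.assign(x=TOY["x"] * 2.0), ["x"])
    assert f2.gamma[0] == pytest.approx(f1.gamma[0] / 2.0, rel=1e-6)


def test_breslow_baseline_cumhaz_is_step_nondecreasing():
    rng = np.random.default_rng(4)
    n = 300
    x = rng.normal(size=n)
    T = rng.exponential(np.exp(-0.7 * x))
    C = rng.uniform(0.1, 2.0, n)
    df = pd.DataFrame({"event_time": np.minimum(T, C), "event": (T <= C).astype(int), "x": x})
    fit = fit_cox(df, ["x"])
    H = fit.baseline_cumhaz
    assert (np.diff(H.to_numpy()) >= -1e-12).all()
    assert fit.n_events == df["event"].sum()


def test_schoenfeld_single_covariate_global_equals_percovariate():
    rng = np.random.default_rng(8)
    n = 250
    x = rng.binomial(1, 0.5, n).astype(float)
    T = rng.exponential(np.exp(-0.5 * x))
    C = rng.uniform(0.2, 2.5, n)
    df = pd.DataFrame({"event_time": np.minimum(T, C), "event": (T <= C).astype(int), "x": x})
    fit = fit_cox(df, ["x"])
    res = schoenfeld_test(fit, df, "km")
    assert res.global_statistic == pytest.approx(res.statistic[0], rel=1e-10)
    assert res.global_p_value == pytest.approx(res.p_value[0], rel=1e-10)
    assert 0 <= res.global_p_value <= 1


def test_schoenfeld_matches_lifelines_reference():
    """Identity/log transforms reproduce lifelines' proportional_hazard_test
    statistics exactly (same Grambsch-Therneau construction)."""
    from lifelines.statistics import proportional_hazard_test

    rng = np.random.default_rng(1)
    n = 400
    x1 = rng.normal(size=n)
    x2 = rng.binomial(1, 0.4, n).astype(float)
    T = rng.exponential(np.exp(-(0.5 * x1 - 0.3 * x2)))
    C = rng.uniform(0.2, 2.5, n)
    df = pd.DataFrame({"event_time": np.minimum(T, C), "event": (T <= C).astype(int),
                       "x1": x1, "x2": x2})
    fit = fit_cox(df, ["x1", "x2"])
    for tt in ("identity", "log"):
        ours = schoenfeld_test(fit, df, tt)
        ref = proportional_hazard_test(fit.model, df, time_transform=tt)
        assert np.allclose(np.sort(ours.statistic),
                           np.sort(ref.summary["test_statistic"].to_numpy()), rtol=1e-6)


def test_schoenfeld_detects_strong_nonproportionality():
    """A covariate whose effect reverses sign mid-follow-up must be flagged."""
    rng = np.random.default_rng(12)
    n = 2000
    x = rng.binomial(1, 0.5, n).astype(float)
    # piecewise hazard: strong positive effect before t=1, negative after
    lam1 = 0.5 * np.exp(1.2 * x)
    t1 = rng.exponential(1 / lam1)
    lam2 = 0.5 * np.exp(-1.2 * x)
    t = np.where(t1 < 1.0, t1, 1.0 + rng.exponential(1 / lam2))
    C = rng.uniform(0.5, 4.0, n)
    df = pd.DataFrame({"event_time": np.minimum(t, C), "event": (t <= C).astype(int), "x": x})
    fit = fit_cox(df, ["x"])
    res = schoenfeld_test(fit, df, "km")
    assert res.global_p_value < 0.01


def test_error_conditions():
    with pytest.raises(ValueError, match="at least one event"):
        fit_cox(TOY.assign(event=0), ["x"])
    fit = fit_cox(TOY, ["x"])
    single = TOY.copy()
    single.loc[1, "event"] = 0
    single.loc[3, "event"] = 0
    with pytest.raises(ValueError, match="2 events"):
        schoenfeld_test(fit, single, "km")
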