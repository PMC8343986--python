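"""Mixed-model estimation against independent references."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from lipidjm.lmm import (LMMSpec, SubjectStats, fit_lmm, marginal_loglik,
                         posterior_random_effects, predict_trajectory)
from lipidjm.simulate import generate_cohort, recovery_config

from conftest import intercept_only_config


@pytest.fixture(scope="module")
def fitted(medium_cohort):
    long, _, _ = medium_cohort
    spec = LMMSpec(["intercept", "time"], ["intercept", "time"])
    return long, spec, fit_lmm(long, spec)


def test_degenerate_D_recovers_ols():
    """With no between-subject variance the MLE collapses to OLS."""
    cfg = intercept_only_config(n=400, var_b=0.0, sigma=0.1, seed=5)
    cfg.markers["TC"].D = np.array([[0.0]])
    long, _, _ = generate_cohort(cfg)
    spec = LMMSpec(["intercept", "time"], ["intercept"])
    fit = fit_lmm(long, spec)
    X = np.column_stack([np.ones(len(long)), long["time"]])
    beta_ols = np.linalg.lstsq(X, long["log_marker"], rcond=None)[0]
    assert np.allclose(fit.beta, beta_ols, atol=1e-3)


def test_recovers_generating_parameters(fitted, medium_cohort):
    _, _, fit = fitted
    _, _, truth = medium_cohort
    mp = truth["params"]["markers"]["TC"]
    se = np.sqrt(np.diag(fit.vcov_beta))
    assert abs(fit.beta[0] - mp["beta"]["intercept"]) < 4 * se[0]
    assert abs(fit.beta[1] - mp["beta"]["time"]) < 4 * se[1]
    assert fit.sigma2 == pytest.approx(mp["sigma"] ** 2, rel=0.25)
    assert fit.D[0, 0] == pytest.approx(mp["D"][0][0], rel=0.35)


def test_loglik_dominates_truth(fitted, medium_cohort):
    long, spec, fit = fitted
    _, _, truth = medium_cohort
    mp = truth["params"]["markers"]["TC"]
    st = SubjectStats(long, spec)
    ll_truth = marginal_loglik(st, np.array([mp["beta"]["intercept"], mp["beta"]["time"]]),
                               np.array(mp["D"]), mp["sigma"] ** 2)
    assert fit.loglik >= ll_truth


def test_matches_statsmodels_ml(small_cohort):
    """statsmodels MixedLM (ML) as the independent oracle on a
    well-conditioned intercept-only problem."""
    import statsmodels.formula.api as smf

    cfg = intercept_only_config(n=250, var_b=0.05, sigma=0.12, seed=13)
    long, _, _ = generate_cohort(cfg)
    fit = fit_lmm(long, LMMSpec(["intercept", "time"], ["intercept"]))
    sm_fit = smf.mixedlm("log_marker ~ time", long, groups=long["subject_id"]).fit(reml=False)
    assert np.allclose(fit.beta, sm_fit.fe_params.values, atol=1e-4)
    assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-4)
    assert fit.sigma2 == pytest.approx(sm_fit.scale, rel=1e-3)
    assert fit.D[0, 0] == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), rel=2e-3)


def test_marginal_loglik_equals_dense_covariance_form(fitted):
    """Woodbury-based loglik equals the direct N(X beta, Z D Z' + s2 I)
    evaluation subject by subject."""
    long, spec, fit = fitted
    total = 0.0
    for _, grp in long.groupby("subject_id"):
        t = grp["time"].to_numpy()
        X = np.column_stack([np.ones(len(t)), t])
        Z = X.copy()
        V = Z @ fit.D @ Z.T + fit.sigma2 * np.eye(len(t))
        r = grp["log_marker"].to_numpy() - X @ fit.beta
        sign, logdet = np.linalg.slogdet(V)
        total += -0.5 * (len(t) * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(V, r))
    assert fit.loglik == pytest.approx(total, abs=1e-8)


def test_time_origin_shift_invariance(fitted):
    long, spec, fit = fitted
    shifted = long.copy()
    c = 4.0
    shifted["time"] = shifted["time"] - c
    # same model: intercept absorbs c * slope; slope-related D rotates, but
    # with intercept-only randomness the likelihood is unchanged exactly
    spec1 = LMMSpec(["intercept", "time"], ["intercept"])
    f0 = fit_lmm(long, spec1)
    f1 = fit_lmm(shifted, spec1)
    assert f0.loglik == pytest.approx(f1.loglik, abs=1e-5)
    assert f0.beta[1] == pytest.approx(f1.beta[1], abs=1e-6)
    assert f1.beta[0] == pytest.approx(f0.beta[0] + c * f0.beta[1], abs=1e-4)


def test_posterior_mean_matches_grid_integration(fitted):
    """Empirical-Bayes b against brute-force posterior integration for a
    2-observation subject."""
    long, spec, fit = fitted
    sid = long.groupby("subject_id").size().loc[lambda s: s == 2].index[0]
    sub = long[long["subject_id"] == sid]
    eb = posterior_random_effects(fit, sub)
    grid = np.linspace(-1.0, 1.0, 2001)
    d0, d1 = np.meshgrid(grid * 6 * np.sqrt(fit.D[0, 0]),
                         grid * 6 * np.sqrt(fit.D[1, 1]), indexing="ij")
    t = sub["time"].to_numpy()
    y = sub["log_marker"].to_numpy()
    lp = np.zeros_like(d0)
    for ti, yi in zip(t, y):
        lp += norm.logpdf(yi, fit.beta[0] + fit.beta[1] * ti + d0 + d1 * ti, np.sqrt(fit.sigma2))
    Dinv = np.linalg.inv(fit.D)
    lp += -0.5 * (Dinv[0, 0] * d0**2 + 2 * Dinv[0, 1] * d0 * d1 + Dinv[1, 1] * d1**2)
    w = np.exp(lp - lp.max())
    b0 = float((w * d0).sum() / w.sum())
    b1 = float((w * d1).sum() / w.sum())
    assert eb["b_intercept"].iloc[0] == pytest.approx(b0, abs=1e-6)
    assert eb["b_time"].iloc[0] == pytest.approx(b1, abs=1e-6)


def test_prediction_limits(fitted):
    long, spec, fit = fitted
    # a subject with as many observations as random effects: the sigma2 -> 0
    # limit interpolates the data exactly
    sid = long.groupby("subject_id").size().loc[lambda s: s == 2].index[0]
    sub = long[long["subject_id"] == sid]
    import dataclasses
    tiny = dataclasses.replace(fit, sigma2=1e-12)
    m = predict_trajectory(tiny, sub, sub["time"].to_numpy())
    assert np.allclose(m, sub["log_marker"], atol=1e-4)
    # zero observations: population-mean trajectory
    empty = sub.iloc[0:0]
    m0 = predict_trajectory(fit, empty, [0.0, 6.0])
    assert np.allclose(m0, fit.beta[0] + fit.beta[1] * np.array([0.0, 6.0]))
    with pytest.warns(UserWarning, match="extrapolation"):
        predict_trajectory(fit, sub, [40.0])


def test_design_errors():
    cfg = intercept_only_config(n=50, seed=2)
    long, _, _ = generate_cohort(cfg)
    long = long.assign(dup=long["time"] * 1.0)
    with pytest.raises(ValueError, match="rank deficient"):
        fit_lmm(long, LMMSpec(["intercept", "time", "dup"], ["intercept"]))
    singles = long.groupby("subject_id").sample(n=1, random_state=1)
    with pytest.raises(ValueError, match="single"):
        fit_lmm(singles, LMMSpec(["intercept", "time"], ["intercept", "time"]))
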