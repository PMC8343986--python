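"""Synthetic cohort generator: invariants, closed forms, decoupling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lipidjm.simulate import (MarkerParams, SimulationConfig, default_config,
                              generate_cohort, invert_cumulative_hazard,
                              recovery_config)

from conftest import intercept_only_config


def test_same_seed_reproduces_tables_bit_identically():
    cfg = recovery_config(200, seed=11)
    l1, s1, t1 = generate_cohort(cfg)
    l2, s2, t2 = generate_cohort(recovery_config(200, seed=11))
    pd.testing.assert_frame_equal(l1, l2)
    pd.testing.assert_frame_equal(s1, s2)
    assert t1["random_effects"] == t2["random_effects"]


def test_structural_invariants(medium_cohort):
    long, surv, _ = medium_cohort
    sizes = long.groupby(["subject_id", "marker"]).size()
    assert sizes.between(1, 5).all()
    assert (long["marker_value"] > 0).all()
    assert np.allclose(long["log_marker"], np.log(long["marker_value"]))
    # within-subject times strictly increasing
    assert long.groupby(["subject_id", "marker"])["time"].apply(
        lambda t: (np.diff(t) > 0).all()).all()
    # no record postdates the event/censoring time
    merged = long.merge(surv[["subject_id", "event_time"]], on="subject_id")
    assert (merged["time"] < merged["event_time"] + 1e-12).all()
    assert set(long["subject_id"]) == set(surv["subject_id"])
    assert (surv["event_time"] > 0).all()


def test_zero_association_decouples_marker_from_event_time():
    cfg = intercept_only_config(n=2000, assoc=0.0, seed=3)
    cfg.gamma = {}
    _, surv, truth = generate_cohort(cfg)
    b0 = np.asarray(truth["random_effects"]["TC"])[:, 0]
    rho = stats.spearmanr(b0, surv["event_time"]).statistic
    assert abs(rho) < 0.1


def test_constant_hazard_reduces_to_exponential_mean():
    lam = 0.2
    marker = MarkerParams(beta={"intercept": 5.0, "time": 0.0},
                          D=np.array([[0.02]]), sigma=0.05, assoc=0.0)
    cfg = SimulationConfig(n_subjects=5000, markers={"TC": marker}, gamma={},
                           baseline_knots=(0.0,), baseline_rates=(lam,),
                           admin_censor_time=1e9, seed=9)
    _, surv, _ = generate_cohort(cfg)
    t = surv["event_time"].to_numpy()
    assert surv["event"].all()
    mc_se = t.std() / np.sqrt(len(t))
    assert abs(t.mean() - 1 / lam) < 3 * mc_se


def test_inversion_exponential_closed_form():
    u = np.array([0.9, 0.5, 0.1, 1e-6])
    lam = 0.3
    t = invert_cumulative_hazard(u, np.zeros(4), np.zeros(4), [0.0], [lam])
    assert np.allclose(t, -np.log(u) / lam, rtol=1e-12)


def test_inversion_matches_numerical_integration_with_slope():
    # one hazard interval, nonzero association x slope
    level, slope, lam = 0.4, -0.15, 0.08
    for u in (0.9, 0.75, 0.6, 0.5):
        t = invert_cumulative_hazard(np.array([u]), np.array([level]),
                                     np.array([slope]), [0.0], [lam])[0]
        grid = np.linspace(0.0, t, 200001)
        H = np.trapezoid(lam * np.exp(level + slope * grid), grid)
        assert abs(H - (-np.log(u))) < 1e-8 * max(1.0, -np.log(u))
    # the decaying hazard has finite total mass: small u is never reached
    t = invert_cumulative_hazard(np.array([0.2]), np.array([level]),
                                 np.array([slope]), [0.0], [lam])[0]
    assert np.isinf(t)


def test_inversion_monotone_decreasing_in_u():
    us = np.linspace(1e-4, 1 - 1e-4, 50)
    t = invert_cumulative_hazard(us, np.zeros(50), np.full(50, 0.1), [0.0, 2.0], [0.1, 0.2])
    assert (np.diff(t) < 0).all()
    # u -> 1- gives t -> 0+
    t1 = invert_cumulative_hazard(np.array([1 - 1e-12]), [0.0], [0.1], [0.0], [0.5])
    assert 0 < t1[0] < 1e-9


def test_insufficient_total_hazard_returns_infinity():
    # decaying hazard with finite total mass
    t = invert_cumulative_hazard(np.array([1e-12]), np.array([0.0]),
                                 np.array([-2.0]), [0.0], [0.1])
    assert np.isinf(t[0])


def test_invalid_configs_rejected():
    bad_D = np.array([[1.0, 2.0], [2.0, 1.0]])  # indefinite
    with pytest.raises(ValueError, match="positive semi-definite"):
        MarkerParams(beta={"intercept": 5, "time": 0}, D=bad_D, sigma=0.1)
    cfg = recovery_config(10)
    cfg.visit_times = ()
    with pytest.raises(ValueError, match="empty"):
        generate_cohort(cfg)
    cfg = recovery_config(10)
    cfg.dropout_prob = 1.0
    with pytest.raises(ValueError, match="dropout"):
        generate_cohort(cfg)
    with pytest.raises(ValueError, match="rates must be >= 0"):
        invert_cumulative_hazard(np.array([0.5]), [0.0], [0.0], [0.0], [-1.0])


def test_km_curve_matches_baseline_survival_when_decoupled():
    """With a=0 and no covariate effects the model is a plain piecewise-
    exponential: the Kaplan-Meier estimate must track exp(-H0(t))."""
    from lifelines import KaplanMeierFitter

    marker = MarkerParams(beta={"intercept": 5.0, "time": -0.01},
                          D=np.array([[0.03]]), sigma=0.08, assoc=0.0)
    knots, rates = (0.0, 4.0, 8.0), (0.03, 0.05, 0.08)
    cfg = SimulationConfig(n_subjects=4000, markers={"TC": marker}, gamma={},
                           baseline_knots=knots, baseline_rates=rates,
                           admin_censor_time=14.0, seed=21)
    _, surv, _ = generate_cohort(cfg)
    km = KaplanMeierFitter().fit(surv["event_time"], surv["event"])
    for t0 in (2.0, 5.0, 9.0, 13.0):
        H0 = 0.03 * min(t0, 4) + 0.05 * max(min(t0, 8) - 4, 0) + 0.08 * max(t0 - 8, 0)
        km_s = float(km.survival_function_at_times(t0).iloc[0])
        assert abs(km_s - np.exp(-H0)) < 0.025


def test_default_cohort_matches_study_scale():
    long, surv, _ = generate_cohort(default_config(n_subjects=4507, seed=17))
    frac = surv["event"].mean()
    assert 0.034 <= frac <= 0.074
    assert set(long["marker"]) == {"TC", "LDL", "HDL"}
    per_subject = long.groupby(["subject_id", "marker"]).size()
    assert per_subject.between(1, 5).all()
    # baseline TC mean on the raw scale is in the observed cohort range
    base = long[(long["marker"] == "TC") & (long["time"] == 0)]
    assert 190 < base["marker_value"].mean() < 240
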