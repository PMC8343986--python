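"""Joint model: quadrature accuracy, structural identities, estimation."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

from lipidjm.joint import (JointModel, JointModelSpec, JointModelFit, fit_joint,
                           piecewise_ph_loglik, rr_per_fraction)
from lipidjm.lmm import LMMSpec, SubjectStats, fit_lmm, marginal_loglik
from lipidjm.simulate import generate_cohort, recovery_config

from _oracle import brute_force_joint_loglik
from conftest import intercept_only_config

BETA = np.array([5.37, -0.0105])
D2 = np.array([[0.0289, -0.000204], [-0.000204, 3.6e-05]])
SIG2 = 0.0081
RATES = np.array([0.03, 0.03, 0.03])
KNOTS = (0.0, 4.0, 8.0)


def _subset(long, surv, k):
    ids = surv["subject_id"].iloc[:k]
    return long[long["subject_id"].isin(ids)], surv[surv["subject_id"].isin(ids)].copy()


def test_gh_matches_dense_grid_2d(small_cohort, joint_spec_2d):
    long, surv, _ = small_cohort
    l5, s5 = _subset(long, surv, 5)
    jm = JointModel(l5, s5, joint_spec_2d)
    ll = jm.loglik(jm.pack(BETA, SIG2, D2, [-0.3], 1.5, RATES))
    oracle = brute_force_joint_loglik(
        l5, s5, {"intercept": BETA[0], "time": BETA[1]}, SIG2, D2,
        {"sex": -0.3}, 1.5, KNOTS, RATES, center=jm.m_center)
    assert abs(ll - oracle) / abs(oracle) < 1e-6


def test_gh_matches_dense_grid_1d(joint_spec_1d):
    long, surv, _ = generate_cohort(intercept_only_config(n=80, assoc=1.0, seed=31))
    l6, s6 = _subset(long, surv, 6)
    jm = JointModel(l6, s6, joint_spec_1d)
    D1 = np.array([[0.0289]])
    ll = jm.loglik(jm.pack(BETA, SIG2, D1, [-0.3], 1.0, RATES))
    oracle = brute_force_joint_loglik(
        l6, s6, {"intercept": BETA[0], "time": BETA[1]}, SIG2, D1,
        {"sex": -0.3}, 1.0, KNOTS, RATES, center=jm.m_center)
    assert abs(ll - oracle) / abs(oracle) < 1e-6


def test_zero_association_factorizes(small_cohort, joint_spec_2d):
    """With a=0 the joint likelihood is exactly (mixed model) + (piecewise
    exponential PH)."""
    long, surv, _ = small_cohort
    jm = JointModel(long, surv, joint_spec_2d)
    ll = jm.loglik(jm.pack(BETA, SIG2, D2, [-0.3], 0.0, RATES))
    ll_lmm = marginal_loglik(SubjectStats(long, joint_spec_2d.lmm_spec), BETA, D2, SIG2)
    ll_surv = piecewise_ph_loglik(surv, ["sex"], KNOTS, RATES, [-0.3])
    assert abs(ll - (ll_lmm + ll_surv)) < 1e-8


def test_subject_permutation_invariance(small_cohort, joint_spec_2d):
    long, surv, _ = small_cohort
    jm1 = JointModel(long, surv, joint_spec_2d)
    rng = np.random.default_rng(0)
    perm_long = long.sample(frac=1.0, random_state=3)
    perm_surv = surv.sample(frac=1.0, random_state=4)
    jm2 = JointModel(perm_long, perm_surv, joint_spec_2d)
    th = jm1.pack(BETA, SIG2, D2, [-0.3], 1.5, RATES)
    assert jm1.loglik(th) == pytest.approx(jm2.loglik(th), abs=1e-9)


def test_quadrature_saturation(small_cohort, joint_spec_2d):
    """9 -> 15 Gauss-Hermite points changes the loglik by < 1e-4."""
    long, surv, _ = small_cohort
    th_args = (BETA, SIG2, D2, [-0.3], 1.5, RATES)
    jm9 = JointModel(long, surv, joint_spec_2d)
    spec15 = dataclasses.replace(joint_spec_2d, quad_points=15)
    jm15 = JointModel(long, surv, spec15)
    assert abs(jm9.loglik(jm9.pack(*th_args)) - jm15.loglik(jm15.pack(*th_args))) < 1e-4


def test_fit_improves_on_initialization_and_on_null_model(small_cohort, joint_spec_2d):
    long, surv, _ = small_cohort
    jm = JointModel(long, surv, joint_spec_2d)
    init = jm.default_init(long)
    fit = jm.fit(init=init, compute_vcov=False)
    assert fit.loglik >= jm.loglik(init) - 1e-9

    # constrained maximum at a=0 factorizes: LMM MLE + piecewise-PH MLE
    lfit = fit_lmm(long, joint_spec_2d.lmm_spec)

    def neg_ph(x):
        return -piecewise_ph_loglik(surv, ["sex"], KNOTS, np.exp(x[1:]), x[:1])

    res = minimize(neg_ph, np.array([0.0, -3.0, -3.0, -3.0]), method="Nelder-Mead",
                   options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000})
    ll_constrained = lfit.loglik - res.fun
    lr = 2.0 * (fit.loglik - ll_constrained)
    assert lr >= -1e-6


def test_fit_recovers_association_on_one_dataset(medium_cohort, joint_spec_2d):
    long, surv, _ = medium_cohort
    fit = fit_joint(long, surv, joint_spec_2d)
    assert fit.converged
    assert fit.vcov is not None
    assert np.allclose(fit.vcov, fit.vcov.T, atol=1e-10)
    assert abs(fit.assoc - 1.5) < 3 * fit.assoc_se
    assert fit.sigma2 == pytest.approx(0.0081, rel=0.25)


def test_rr_per_fraction_transform():
    def fake_fit(a, se):
        names = ["assoc"]
        return JointModelFit(
            spec=None, knots=np.array([0.0]), beta=np.zeros(2), sigma2=1.0,
            D=np.eye(2), gamma=np.zeros(0), assoc=a, log_rates=np.zeros(1),
            loglik=0.0, vcov=np.array([[se**2]]), param_names=names,
            theta=np.array([a]), converged=True, n_subjects=1, n_events=1, n_iter=0)

    rr, lo, hi, p = rr_per_fraction(fake_fit(0.0, 0.5), 0.10)
    assert rr == 1.0
    assert lo == pytest.approx(1.0 / hi, rel=1e-12)   # symmetric on log scale
    assert p == pytest.approx(1.0)

    rr, *_ = rr_per_fraction(fake_fit(1.0, 0.5), 0.10)
    assert rr == pytest.approx(1.1, abs=1e-15)

    a_tc = np.log(1.28) / np.log(1.1)
    rr, *_ = rr_per_fraction(fake_fit(a_tc, 0.3), 0.10)
    assert rr == pytest.approx(1.28, abs=1e-12)

    with pytest.raises(ValueError):
        rr_per_fraction(fake_fit(1.0, 0.5), -1.0)


def test_input_validation(small_cohort, joint_spec_2d):
    long, surv, _ = small_cohort
    with pytest.raises(ValueError, match="do not match"):
        JointModel(long, surv.iloc[:-3], joint_spec_2d)
    spec_bad = dataclasses.replace(joint_spec_2d, knots=None, n_intervals=10_000)
    with pytest.raises(ValueError, match="fewer events"):
        JointModel(long, surv, spec_bad)
    with pytest.raises(ValueError):
        JointModelSpec(quad_points=4)
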