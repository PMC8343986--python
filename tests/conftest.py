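import numpy as np
import pytest

from lipidjm.lmm import LMMSpec
from lipidjm.joint import JointModelSpec
from lipidjm.simulate import MarkerParams, SimulationConfig, generate_cohort, recovery_config


@pytest.fixture(scope="session")
def small_cohort():
    """Single-marker cohort with intercept+slope random effects, ~30% events."""
    long, surv, truth = generate_cohort(recovery_config(150, assoc=1.5, seed=42))
    return long, surv, truth


@pytest.fixture(scope="session")
def medium_cohort():
    long, surv, truth = generate_cohort(recovery_config(600, assoc=1.5, seed=7))
    return long, surv, truth


@pytest.fixture()
def joint_spec_2d():
    return JointModelSpec(
        lmm_spec=LMMSpec(["intercept", "time"], ["intercept", "time"]),
        survival_covariates=["sex"], knots=(0.0, 4.0, 8.0))


@pytest.fixture()
def joint_spec_1d():
    return JointModelSpec(
        lmm_spec=LMMSpec(["intercept", "time"], ["intercept"]),
        survival_covariates=["sex"], knots=(0.0, 4.0, 8.0))


def intercept_only_config(n=300, sigma=0.09, var_b=0.0289, assoc=0.0, seed=0):
    """Helper: single-marker config with intercept-only random effect."""
    marker = MarkerParams(beta={"intercept": 5.37, "time": -0.0105},
                          D=np.array([[var_b]]), sigma=sigma, assoc=assoc, ref=5.37)
    return SimulationConfig(
        n_subjects=n, markers={"TC": marker}, gamma={"sex": -0.3},
        baseline_knots=(0.0, 4.0, 8.0), baseline_rates=(0.0243, 0.0243, 0.0243),
        dropout_prob=0.15, seed=seed)
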