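"""Linear mixed-effects sub-model for the log-marker trajectory.

The longitudinal marker (natural-log scale) is modeled as

    y_ij = x_ij' beta + z_ij' b_i + eps_ij,   b_i ~ N(0, D),  eps ~ N(0, sigma^2)

with z_ij = (1,) or (1, t_ij). Estimation is maximum likelihood: for given
variance components the fixed effects are profiled out by GLS, and the
profiled deviance is minimized by quasi-Newton on an unconstrained
parameterization (log-Cholesky factor of D, log sigma). ML rather than REML
because these estimates seed the joint likelihood, which is ML-based.

The per-subject marginal covariance V_i = Z_i D Z_i' + sigma^2 I is never
formed; everything runs on per-subject sufficient statistics via the
Woodbury identity, so evaluation cost is independent of the number of
observations per subject.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from ._design import build_design, check_full_rank

_LOG2PI = np.log(2.0 * np.pi)


@dataclass
class LMMSpec:
    fixed_terms: list[str] = field(default_factory=lambda: ["intercept", "time"])
    random_terms: list[str] = field(default_factory=lambda: ["intercept", "time"])
    response: str = "log_marker"

    def __post_init__(self):
        if not set(self.random_terms) <= {"intercept", "time"} or not self.random_terms:
            raise ValueError("random_terms must be a non-empty subset of {intercept, time}")
        if "intercept" not in self.fixed_terms or "time" not in self.fixed_terms:
            raise ValueError("fixed_terms must include intercept and time")


@dataclass
class LMMFit:
    spec: LMMSpec
    beta: np.ndarray
    D: np.ndarray
    sigma2: float
    loglik: float
    vcov_beta: np.ndarray
    n_subjects: int
    converged: bool
    time_range: tuple[float, float]

    @property
    def beta_named(self) -> dict[str, float]:
        return dict(zip(self.spec.fixed_terms, self.beta))

    def summary(self) -> dict:
        se = np.sqrt(np.diag(self.vcov_beta))
        return {
            "beta": {t: {"estimate": float(b), "se": float(s)}
                     for t, b, s in zip(self.spec.fixed_terms, self.beta, se)},
            "D": self.D.tolist(),
            "sigma2": float(self.sigma2),
            "loglik": float(self.loglik),
            "n_subjects": int(self.n_subjects),
            "converged": bool(self.converged),
        }


class SubjectStats:
    """Per-subject cross-product statistics for the marginal likelihood."""

    def __init__(self, data: pd.DataFrame, spec: LMMSpec, id_col: str = "subject_id"):
        data = data.sort_values([id_col, "time"], kind="stable")
        X = build_design(data, spec.fixed_terms)
        check_full_rank(X, spec.fixed_terms)
        Z = build_design(data, spec.random_terms)
        y = data[spec.response].to_numpy(float)
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise ValueError("non-finite values in the design or response")

        ids = data[id_col].to_numpy()
        _, starts, counts = np.unique(ids, return_index=True, return_counts=True)
        order = np.argsort(starts)
        starts, counts = starts[order], counts[order]
        self.subject_ids = ids[starts]
        self.n_i = counts.astype(float)
        if "time" in spec.random_terms and np.all(counts <= 1):
            raise ValueError("random slope requested but every subject has a single "
                             "observation (slope variance unidentifiable)")

        self.XtX = np.add.reduceat(X[:, :, None] * X[:, None, :], starts, axis=0)
        self.XtZ = np.add.reduceat(X[:, :, None] * Z[:, None, :], starts, axis=0)
        self.ZtZ = np.add.reduceat(Z[:, :, None] * Z[:, None, :], starts, axis=0)
        self.Xty = np.add.reduceat(X * y[:, None], starts, axis=0)
        self.Zty = np.add.reduceat(Z * y[:, None], starts, axis=0)
        self.yty = np.add.reduceat(y * y, starts, axis=0)
        self.p = X.shape[1]
        self.q = Z.shape[1]
        self.n_obs = len(y)
        self.time_range = (float(data["time"].min()), float(data["time"].max()))


def _theta_to_D(theta_D: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    L[np.diag_indices(q)] = np.exp(theta_D[:q])
    if q == 2:
        L[1, 0] = theta_D[2]
    return L @ L.T


def _D_to_theta(D: np.ndarray) -> np.ndarray:
    L = np.linalg.cholesky(D + 1e-12 * np.eye(len(D)))
    q = len(D)
    theta = list(np.log(np.diag(L)))
    if q == 2:
        theta.append(L[1, 0])
    return np.asarray(theta)


def _profile(stats: SubjectStats, D: np.ndarray, sigma2: float):
    """GLS fixed effects and profiled loglik pieces for given (D, sigma2)."""
    q = stats.q
    Dinv = np.linalg.inv(D)
    M = Dinv[None] + stats.ZtZ / sigma2                    # (n, q, q)
    Minv = np.linalg.inv(M)
    sign, logdet_M = np.linalg.slogdet(M)
    sign_D, logdet_D = np.linalg.slogdet(D)
    logdet_V = stats.n_i * np.log(sigma2) + logdet_D + logdet_M

    # X' V^-1 X = XtX/s2 - XtZ M^-1 ZtX / s4  (and analogous pieces)
    XtZM = np.einsum("npq,nqr->npr", stats.XtZ, Minv)
    A = (stats.XtX / sigma2 - np.einsum("npq,nrq->npr", XtZM, stats.XtZ) / sigma2**2).sum(0)
    rhs = (stats.Xty / sigma2 - np.einsum("npq,nq->np", XtZM, stats.Zty) / sigma2**2).sum(0)
    beta = np.linalg.solve(A, rhs)
    return beta, A, Minv, logdet_V


def marginal_loglik(stats: SubjectStats, beta: np.ndarray, D: np.ndarray, sigma2: float) -> float:
    """Exact marginal Gaussian log-likelihood at the supplied parameters."""
    Dinv = np.linalg.inv(D)
    M = Dinv[None] + stats.ZtZ / sigma2
    Minv = np.linalg.inv(M)
    _, logdet_M = np.linalg.slogdet(M)
    _, logdet_D = np.linalg.slogdet(D)
    logdet_V = stats.n_i * np.log(sigma2) + logdet_D + logdet_M
    rtr = stats.yty - 2.0 * stats.Xty @ beta + np.einsum("p,npq,q->n", beta, stats.XtX, beta)
    h = stats.Zty - np.einsum("npq,p->nq", stats.XtZ, beta)
    quad = rtr / sigma2 - np.einsum("nq,nqr,nr->n", h, Minv, h) / sigma2**2
    return float(-0.5 * np.sum(stats.n_i * _LOG2PI + logdet_V + quad))


def fit_lmm(data: pd.DataFrame, spec: LMMSpec | None = None, id_col: str = "subject_id",
            max_iter: int = 500) -> LMMFit:
    """Maximum-likelihood fit of the trajectory mixed model."""
    spec = spec or LMMSpec()
    stats = SubjectStats(data, spec, id_col=id_col)
    if len(stats.n_i) < 2:
        raise ValueError("need at least 2 subjects")
    q = stats.q

    # moment-based start: OLS residual variance split between levels
    XtX = stats.XtX.sum(0)
    beta0 = np.linalg.solve(XtX, stats.Xty.sum(0))
    rss = stats.yty.sum() - 2 * stats.Xty.sum(0) @ beta0 + beta0 @ XtX @ beta0
    s2 = max(rss / stats.n_obs, 1e-8)
    D0 = np.eye(q) * max(s2 / 2, 1e-6)
    if q == 2:
        D0[1, 1] = max(s2 / 200, 1e-8)
    x0 = np.concatenate([_D_to_theta(D0), [0.5 * np.log(s2 / 2)]])

    def negll(x):
        D = _theta_to_D(x[:-1], q)
        sigma2 = np.exp(2.0 * x[-1])
        try:
            beta, _, _, _ = _profile(stats, D, sigma2)
            return -marginal_loglik(stats, beta, D, sigma2)
        except np.linalg.LinAlgError:
            return 1e12

    bounds = [(-8.0, 5.0)] * q + ([(-30.0, 30.0)] if q == 2 else []) + [(-8.0, 5.0)]
    res = minimize(negll, x0, method="L-BFGS-B", bounds=bounds,
                   options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8})
    D = _theta_to_D(res.x[:-1], q)
    sigma2 = float(np.exp(2.0 * res.x[-1]))
    beta, A, _, _ = _profile(stats, D, sigma2)
    ll = marginal_loglik(stats, beta, D, sigma2)
    return LMMFit(spec=spec, beta=beta, D=D, sigma2=sigma2, loglik=ll,
                  vcov_beta=np.linalg.inv(A), n_subjects=len(stats.n_i),
                  converged=bool(res.success), time_range=stats.time_range)


def posterior_random_effects(fit: LMMFit, data: pd.DataFrame, id_col: str = "subject_id") -> pd.DataFrame:
    """Empirical-Bayes (posterior mean) random effects per subject."""
    stats = SubjectStats(data, fit.spec, id_col=id_col)
    Dinv = np.linalg.inv(fit.D)
    M = Dinv[None] + stats.ZtZ / fit.sigma2
    h = stats.Zty - np.einsum("npq,p->nq", stats.XtZ, fit.beta)
    b = np.linalg.solve(M, h[..., None])[..., 0] / fit.sigma2
    cols = [f"b_{t}" for t in fit.spec.random_terms]
    out = pd.DataFrame(b, columns=cols)
    out.insert(0, id_col, stats.subject_ids)
    return out


def predict_trajectory(fit: LMMFit, subject_data: pd.DataFrame, times) -> np.ndarray:
    """Latent trajectory m_i(t) at the requested times for one subject.

    ``subject_data`` holds the subject's observed rows (covariates are taken
    from the first row; they are baseline values and constant in time). A
    subject with zero observations gets the population-mean trajectory
    (posterior mean of b is the prior mean, zero).
    """
    times = np.atleast_1d(np.asarray(times, float))
    lo, hi = fit.time_range
    if np.any(times < lo - 1e-9) or np.any(times > hi + 3.0):
        warnings.warn("prediction time outside the fitted range plus one visit gap; "
                      "linear extrapolation may be unreliable", stacklevel=2)

    if len(subject_data) == 0:
        b = np.zeros(len(fit.spec.random_terms))
        grid = pd.DataFrame({"time": times})
        for t in fit.spec.fixed_terms:
            if t not in ("intercept", "time"):
                grid[t] = 0.0
        raise_if = [t for t in fit.spec.fixed_terms if t not in ("intercept", "time")]
        if raise_if:
            raise ValueError("population prediction with covariate fixed effects needs "
                             "a covariate row; supply subject_data with one row")
    else:
        y = subject_data[fit.spec.response].to_numpy(float)
        Z = build_design(subject_data, fit.spec.random_terms)
        X = build_design(subject_data, fit.spec.fixed_terms)
        r = y - X @ fit.beta
        M = np.linalg.inv(fit.D) + Z.T @ Z / fit.sigma2
        b = np.linalg.solve(M, Z.T @ r) / fit.sigma2
        grid = subject_data.iloc[[0] * len(times)].copy()
        grid["time"] = times

    Xg = build_design(grid, fit.spec.fixed_terms)
    Zg = build_design(grid, fit.spec.random_terms)
    return Xg @ fit.beta + Zg @ b
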