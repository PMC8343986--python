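"""Shared-parameter joint model of a longitudinal log-marker and survival.

The hazard depends on the *current value* of the latent trajectory:

    h_i(t) = h0(t) * exp( gamma' w_i + a * m_i(t) ),
    m_i(t) = x_i(t)' beta + z_i(t)' b_i,

with h0 piecewise constant on a knot grid. The marginal likelihood per
subject integrates the product of the longitudinal Gaussian density, the
survival density and the random-effects prior over b_i. Because m_i is
linear in t, the cumulative hazard has a closed form on every constant-
hazard interval (an integral of exp(linear)), so the only numerical
integral is over b_i, done by adaptive Gauss-Hermite quadrature centred at
each subject's posterior mode with Hessian scaling. The integrand is
log-concave in b_i, so the vectorized Newton mode search is safe.

Estimation maximizes the integrated likelihood directly (quasi-Newton on an
unconstrained parameterization: log-Cholesky D, log sigma, log baseline
rates); standard errors come from the numerically differentiated observed
information at the optimum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy import stats as sstats

from ._design import build_design
from ._kernels import HAVE_NUMBA, agq_loglik
from ._piecewise import exp_int0, exp_int1, exp_int2, interval_bounds, interval_index
from .lmm import LMMSpec, SubjectStats, fit_lmm
from .cox import fit_cox

_LOG2PI = np.log(2.0 * np.pi)
_EXP_CLIP = 600.0  # cap on exponents to keep exploratory optimizer steps finite


@dataclass
class JointModelSpec:
    lmm_spec: LMMSpec = field(default_factory=LMMSpec)
    survival_covariates: list[str] = field(default_factory=list)
    n_intervals: int = 6
    knots: tuple[float, ...] | None = None   # override for the event-quantile rule
    quad_points: int = 9
    adaptive: bool = True
    # reference log-marker level subtracted inside the hazard:
    # h_i(t) = h0(t) exp(gamma'w + a*(m_i(t) - center)). A pure
    # reparameterization of h0 that decorrelates a from the baseline rates
    # (much better conditioned optimization). None -> mean observed response.
    hazard_center: float | None = None

    def __post_init__(self):
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")
        if self.quad_points < 3 or self.quad_points % 2 == 0:
            raise ValueError("quad_points must be odd and >= 3")


@dataclass
class JointModelFit:
    spec: JointModelSpec
    knots: np.ndarray
    beta: np.ndarray
    sigma2: float
    D: np.ndarray
    gamma: np.ndarray
    assoc: float
    log_rates: np.ndarray
    loglik: float
    vcov: np.ndarray | None
    param_names: list[str]
    theta: np.ndarray
    converged: bool
    n_subjects: int
    n_events: int
    n_iter: int
    hazard_center: float = 0.0   # rates refer to a subject with m(t) at this log level

    @property
    def assoc_se(self) -> float:
        if self.vcov is None:
            return float("nan")
        return float(np.sqrt(self.vcov[self._assoc_idx, self._assoc_idx]))

    @property
    def _assoc_idx(self) -> int:
        return self.param_names.index("assoc")

    def summary(self) -> dict:
        se = np.sqrt(np.diag(self.vcov)) if self.vcov is not None else np.full(len(self.theta), np.nan)
        return {
            "params": {n: {"estimate": float(v), "se": float(s)}
                       for n, v, s in zip(self.param_names, self.theta, se)},
            "beta": dict(zip(self.spec.lmm_spec.fixed_terms, map(float, self.beta))),
            "sigma2": float(self.sigma2),
            "D": self.D.tolist(),
            "gamma": dict(zip(self.spec.survival_covariates, map(float, self.gamma))),
            "assoc": float(self.assoc),
            "assoc_se": self.assoc_se,
            "baseline_knots": self.knots.tolist(),
            "baseline_rates": np.exp(self.log_rates).tolist(),
            "hazard_center": float(self.hazard_center),
            "loglik": float(self.loglik),
            "n_subjects": int(self.n_subjects),
            "n_events": int(self.n_events),
            "converged": bool(self.converged),
        }


def choose_knots(event_times: np.ndarray, n_intervals: int) -> np.ndarray:
    """Piecewise-constant hazard knots at event-time quantiles (first knot 0)."""
    if n_intervals == 1:
        return np.array([0.0])
    qs = np.quantile(event_times, np.arange(1, n_intervals) / n_intervals)
    knots = np.concatenate([[0.0], np.unique(qs)])
    return knots


class JointModel:
    """Precomputed data structures + likelihood machinery for one dataset."""

    def __init__(self, long: pd.DataFrame, surv: pd.DataFrame, spec: JointModelSpec,
                 id_col: str = "subject_id"):
        self.spec = spec
        self.id_col = id_col
        surv = surv.sort_values(id_col).reset_index(drop=True)

        # Internally every covariate column is standardized ((x - mean)/sd):
        # raw scales (SBP ~ 130, BMI ~ 28) make the likelihood surface so
        # anisotropic in coefficient space that quasi-Newton line searches
        # fail. pack/unpack translate between the raw (reported) and
        # standardized (optimized) parameterizations exactly.
        covariate_cols = [c for c in dict.fromkeys(
            list(spec.lmm_spec.fixed_terms) + list(spec.survival_covariates))
            if c not in ("intercept", "time")]
        self._scalers: dict[str, tuple[float, float]] = {}
        for col in covariate_cols:
            src = surv[col] if col in surv.columns else long[col]
            mu, sd = float(src.mean()), float(src.std(ddof=0))
            self._scalers[col] = (mu, sd) if sd > 0 else (0.0, 1.0)
        long_std = long.copy()
        surv_std = surv.copy()
        for col, (mu, sd) in self._scalers.items():
            if col in long_std.columns:
                long_std[col] = (long_std[col] - mu) / sd
            surv_std[col] = (surv_std[col] - mu) / sd

        self.stats = SubjectStats(long_std, spec.lmm_spec, id_col=id_col)
        if not np.array_equal(np.asarray(surv[id_col]), np.asarray(self.stats.subject_ids)):
            raise ValueError("subject ids in the survival table do not match the longitudinal table")
        self.surv = surv
        self.q = self.stats.q
        self.p = self.stats.p
        self.T = surv["event_time"].to_numpy(float)
        self.delta = surv["event"].to_numpy(float)
        self.n = len(self.T)
        self.n_events = int(self.delta.sum())
        self.W = (build_design(surv_std, spec.survival_covariates)
                  if spec.survival_covariates else np.zeros((self.n, 0)))
        grid = surv_std.copy()
        grid["time"] = 0.0
        self.xb = build_design(grid, spec.lmm_spec.fixed_terms)   # trajectory design at t=0
        self.m_center = (float(long[spec.lmm_spec.response].mean())
                         if spec.hazard_center is None else float(spec.hazard_center))
        self._mu_x = np.array([self._scalers.get(t, (0.0, 1.0))[0]
                               for t in spec.lmm_spec.fixed_terms])
        self._s_x = np.array([self._scalers.get(t, (0.0, 1.0))[1]
                              for t in spec.lmm_spec.fixed_terms])
        self._mu_w = np.array([self._scalers.get(c, (0.0, 1.0))[0]
                               for c in spec.survival_covariates])
        self._s_w = np.array([self._scalers.get(c, (0.0, 1.0))[1]
                              for c in spec.survival_covariates])
        self._int_idx = spec.lmm_spec.fixed_terms.index("intercept")
        self.time_idx = spec.lmm_spec.fixed_terms.index("time")
        self.random_slope = "time" in spec.lmm_spec.random_terms
        if self.random_slope and spec.lmm_spec.random_terms != ["intercept", "time"]:
            raise ValueError("random_terms must be [intercept] or [intercept, time]")

        if spec.knots is not None:
            self.knots = np.asarray(spec.knots, float)
        else:
            ev = self.T[self.delta == 1]
            if len(ev) < spec.n_intervals:
                raise ValueError("fewer events than baseline-hazard intervals")
            self.knots = choose_knots(ev, spec.n_intervals)
        self.K = len(self.knots)
        self.u0, self.u1 = interval_bounds(self.knots, self.T)    # (n, K)
        self.k_event = interval_index(self.knots, self.T)

        # contiguous views for the fused node kernel
        st = self.stats
        self._A00 = np.ascontiguousarray(st.ZtZ[:, 0, 0])
        self._A01 = np.ascontiguousarray(st.ZtZ[:, 0, 1]) if self.q == 2 else np.zeros(self.n)
        self._A11 = np.ascontiguousarray(st.ZtZ[:, 1, 1]) if self.q == 2 else np.zeros(self.n)
        self._u0c = np.ascontiguousarray(self.u0)
        self._u1c = np.ascontiguousarray(self.u1)

        z, w = hermgauss(spec.quad_points)
        if self.q == 2:
            zz0, zz1 = np.meshgrid(z, z, indexing="ij")
            self.z_nodes = np.column_stack([zz0.ravel(), zz1.ravel()])
            self.logw = (np.log(w)[:, None] + np.log(w)[None, :]).ravel()
        else:
            self.z_nodes = z[:, None]
            self.logw = np.log(w)
        self.z_sq = np.sum(self.z_nodes**2, axis=1)
        self._mode_cache = np.zeros((self.n, 2))
        self._z2 = np.ascontiguousarray(
            np.column_stack([self.z_nodes, np.zeros(len(self.z_nodes))])[:, :2])
        self._logw_zsq = np.ascontiguousarray(self.logw + self.z_sq)

        # parameter layout
        names = [f"beta:{t}" for t in spec.lmm_spec.fixed_terms] + ["log_sigma"]
        names += ["D:log_l11"] + (["D:log_l22", "D:l21"] if self.q == 2 else [])
        names += [f"gamma:{c}" for c in spec.survival_covariates]
        names += ["assoc"] + [f"log_rate:{k}" for k in range(self.K)]
        self.param_names = names
        self.n_params = len(names)

    # -- parameter packing ---------------------------------------------------
    # raw <-> standardized translation: beta_std_j = beta_raw_j * s_j with the
    # intercept absorbing sum(beta_raw_j * mu_j); gamma likewise, with the log
    # baseline rates absorbing sum(gamma_raw_j * mu_j).
    def pack(self, beta, sigma2, D, gamma, assoc, rates) -> np.ndarray:
        """Pack raw-scale parameters into the internal optimization vector."""
        beta = np.asarray(beta, float)
        gamma = np.asarray(gamma, float)
        beta_std = beta * self._s_x
        beta_std[self._int_idx] += float(beta @ self._mu_x)
        gamma_std = gamma * self._s_w
        log_rates_std = np.log(np.asarray(rates, float)) + float(gamma @ self._mu_w)

        D = np.atleast_2d(D)
        try:
            L = np.linalg.cholesky(D)
        except np.linalg.LinAlgError:
            L = np.linalg.cholesky(D + 1e-12 * np.eye(self.q))
        th = [beta_std, [0.5 * np.log(sigma2)], [np.log(L[0, 0])]]
        if self.q == 2:
            th += [[np.log(L[1, 1]), L[1, 0]]]
        th += [gamma_std, [assoc], log_rates_std]
        return np.concatenate([np.atleast_1d(np.asarray(t, float)) for t in th])

    def _unpack_std(self, theta: np.ndarray):
        """Parameter blocks on the internal (standardized-design) scale."""
        i = 0
        beta = theta[i:i + self.p]; i += self.p
        sigma2 = np.exp(2.0 * theta[i]); i += 1
        if self.q == 2:
            l11, l22, l21 = np.exp(theta[i]), np.exp(theta[i + 1]), theta[i + 2]
            L = np.array([[l11, 0.0], [l21, l22]])
            i += 3
        else:
            L = np.array([[np.exp(theta[i])]]); i += 1
        D = L @ L.T
        r = len(self.spec.survival_covariates)
        gamma = theta[i:i + r]; i += r
        assoc = theta[i]; i += 1
        rates = np.exp(theta[i:i + self.K])
        return beta, float(sigma2), D, gamma, float(assoc), rates

    def unpack(self, theta: np.ndarray):
        """Parameter blocks on the raw (reported) scale."""
        beta_s, sigma2, D, gamma_s, assoc, rates_s = self._unpack_std(theta)
        beta = beta_s / self._s_x
        beta[self._int_idx] = beta_s[self._int_idx] - float((beta_s / self._s_x) @ self._mu_x)
        gamma = gamma_s / self._s_w if len(gamma_s) else gamma_s
        rates = rates_s * np.exp(-float(gamma @ self._mu_w)) if len(gamma_s) else rates_s
        return beta, sigma2, D, gamma, assoc, rates

    def _raw_jacobian(self) -> np.ndarray:
        """d(raw params)/d(internal params): constant linear map for vcov."""
        A = np.eye(self.n_params)
        for j in range(self.p):
            if j == self._int_idx:
                continue
            A[j, j] = 1.0 / self._s_x[j]
            A[self._int_idx, j] = -self._mu_x[j] / self._s_x[j]
        og = self.p + 1 + (3 if self.q == 2 else 1)
        r = len(self.spec.survival_covariates)
        ok = og + r + 1
        for j in range(r):
            A[og + j, og + j] = 1.0 / self._s_w[j]
            for k in range(self.K):
                A[ok + k, og + j] = -self._mu_w[j] / self._s_w[j]
        return A

    # -- survival pieces -----------------------------------------------------
    def _cumhaz_parts(self, rates, level, s, want=1):
        """H and optionally its u- and u^2-weighted variants.

        level: (n,) or (n,J); s: same shape; returns arrays matching shape.
        H = exp(level) * sum_k rates_k * Int_{I_k} u^m exp(s u) du.
        """
        u0 = self.u0[:, None, :] if level.ndim == 2 else self.u0
        u1 = self.u1[:, None, :] if level.ndim == 2 else self.u1
        sx = s[..., None]
        e = np.exp(np.clip(level, -_EXP_CLIP, _EXP_CLIP))
        I0 = exp_int0(sx, u0, u1)
        H = e * np.sum(rates * I0, axis=-1)
        if want == 1:
            return H
        I1 = exp_int1(sx, u0, u1)
        Hu = e * np.sum(rates * I1, axis=-1)
        if want == 2:
            return H, Hu
        I2 = exp_int2(sx, u0, u1)
        Huu = e * np.sum(rates * I2, axis=-1)
        return H, Hu, Huu

    # -- log integrand g(b) and derivatives ----------------------------------
    def _subject_constants(self, theta_parts):
        """Per-theta precomputations shared by mode search and node evaluation."""
        beta, sigma2, D, gamma, a, rates = theta_parts
        st = self.stats
        c0 = self.xb @ beta - self.m_center     # centered latent intercept part
        d0 = beta[self.time_idx]
        eta = self.W @ gamma if self.W.shape[1] else np.zeros(self.n)
        log_rate_T = np.log(rates)[self.k_event]
        h = st.Zty - np.einsum("npq,p->nq", st.XtZ, beta)
        rtr = st.yty - 2.0 * st.Xty @ beta + np.einsum("p,npq,q->n", beta, st.XtX, beta)
        Dinv = np.linalg.inv(D)
        _, logdet_D = np.linalg.slogdet(D)
        return c0, d0, eta, log_rate_T, h, rtr, Dinv, logdet_D

    def _g_at(self, b, theta_parts, const):
        """Log integrand at b: (n,) for b (n,q) or (n,J) for b (n,J,q)."""
        beta, sigma2, D, gamma, a, rates = theta_parts
        c0, d0, eta, log_rate_T, h, rtr, Dinv, logdet_D = const
        st = self.stats

        nodes = b.ndim == 3
        b0 = b[..., 0]
        b1 = b[..., 1] if self.q == 2 else np.zeros_like(b0)
        if nodes:
            hh, A = h[:, None, :], st.ZtZ[:, None, :, :]
            rtr_, n_i = rtr[:, None], st.n_i[:, None]
            c0_, eta_, T_, delta_, lrT = (x[:, None] for x in (c0, eta, self.T, self.delta, log_rate_T))
        else:
            hh, A, rtr_, n_i = h, st.ZtZ, rtr, st.n_i
            c0_, eta_, T_, delta_, lrT = c0, eta, self.T, self.delta, log_rate_T

        quad = np.einsum("...i,...ij,...j->...", b, A, b)
        lin = np.einsum("...i,...i->...", b, hh)
        g_long = -0.5 * (rtr_ - 2.0 * lin + quad) / sigma2 - 0.5 * n_i * (_LOG2PI + np.log(sigma2))

        level = eta_ + a * (c0_ + b0)
        s = a * (d0 + b1)
        H = self._cumhaz_parts(rates, level, s, want=1)
        g_surv = delta_ * (lrT + eta_ + a * (c0_ + b0 + T_ * (d0 + b1))) - H

        bq = np.einsum("...i,ij,...j->...", b, Dinv, b)
        g_prior = -0.5 * bq - 0.5 * (self.q * _LOG2PI + logdet_D)
        return g_long + g_surv + g_prior

    def _mode_and_hessian(self, theta_parts, const):
        """Vectorized Newton for the posterior mode of b per subject."""
        beta, sigma2, D, gamma, a, rates = theta_parts
        c0, d0, eta, log_rate_T, h, rtr, Dinv, logdet_D = const
        st = self.stats
        b = self._mode_cache[:, :self.q].copy()
        g = self._g_at(b, theta_parts, const)

        for _ in range(40):
            b0 = b[:, 0]
            b1 = b[:, 1] if self.q == 2 else np.zeros(self.n)
            level = eta + a * (c0 + b0)
            s = a * (d0 + b1)
            if self.q == 2:
                H, Hu, Huu = self._cumhaz_parts(rates, level, s, want=3)
            else:
                H = self._cumhaz_parts(rates, level, s, want=1)

            Ab = np.einsum("nij,nj->ni", st.ZtZ, b)
            Db = b @ Dinv.T
            grad = (h - Ab) / sigma2 - Db
            grad[:, 0] += self.delta * a - a * H
            hess = -st.ZtZ / sigma2 - Dinv[None]
            hess = hess.copy()
            hess[:, 0, 0] -= a * a * H
            if self.q == 2:
                grad[:, 1] += self.delta * a * self.T - a * Hu
                hess[:, 0, 1] -= a * a * Hu
                hess[:, 1, 0] -= a * a * Hu
                hess[:, 1, 1] -= a * a * Huu

            step = np.linalg.solve(-hess, grad[..., None])[..., 0]
            if np.max(np.abs(step)) < 1e-10:
                break
            # damped update: halve where the objective would decrease
            scale = np.ones(self.n)
            for _ in range(8):
                b_new = b + scale[:, None] * step
                g_new = self._g_at(b_new, theta_parts, const)
                bad = g_new < g - 1e-12
                if not np.any(bad):
                    break
                scale[bad] *= 0.5
            b, g = b_new, g_new
            if np.max(np.abs(scale[:, None] * step)) < 1e-9:
                break

        # final Hessian at the mode
        b0 = b[:, 0]
        b1 = b[:, 1] if self.q == 2 else np.zeros(self.n)
        level = eta + a * (c0 + b0)
        s = a * (d0 + b1)
        if self.q == 2:
            H, Hu, Huu = self._cumhaz_parts(rates, level, s, want=3)
        else:
            H = self._cumhaz_parts(rates, level, s, want=1)
        M = st.ZtZ / sigma2 + Dinv[None]
        M = M.copy()
        M[:, 0, 0] += a * a * H
        if self.q == 2:
            M[:, 0, 1] += a * a * Hu
            M[:, 1, 0] += a * a * Hu
            M[:, 1, 1] += a * a * Huu
        self._mode_cache[:, :self.q] = b
        return b, M

    def loglik(self, theta: np.ndarray) -> float:
        """Adaptive Gauss-Hermite marginal log-likelihood at packed theta."""
        theta_parts = self._unpack_std(theta)
        const = self._subject_constants(theta_parts)
        if HAVE_NUMBA:
            beta, sigma2, D, gamma, a, rates = theta_parts
            c0, d0, eta, log_rate_T, h, rtr, Dinv, logdet_D = const
            h1 = np.ascontiguousarray(h[:, 1]) if self.q == 2 else np.zeros(self.n)
            Di01 = float(Dinv[0, 1]) if self.q == 2 else 0.0
            Di11 = float(Dinv[1, 1]) if self.q == 2 else 0.0
            return float(agq_loglik(
                self._mode_cache, self._z2, self._logw_zsq, rtr,
                np.ascontiguousarray(h[:, 0]), h1,
                self._A00, self._A01, self._A11, self.stats.n_i, float(sigma2),
                c0, float(d0), eta, log_rate_T, self.T, self.delta,
                self._u0c, self._u1c, np.asarray(rates, float), float(a),
                float(Dinv[0, 0]), Di01, Di11, float(logdet_D), self.q))
        b_hat, M = self._mode_and_hessian(theta_parts, const)

        # scale: Sigma = M^{-1}, L = chol(Sigma)
        if self.q == 2:
            det = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] ** 2
            s00 = M[:, 1, 1] / det
            s01 = -M[:, 0, 1] / det
            s11 = M[:, 0, 0] / det
            l11 = np.sqrt(s00)
            l21 = s01 / l11
            l22 = np.sqrt(np.maximum(s11 - l21**2, 1e-300))
            logdet_L = np.log(l11) + np.log(l22)
            z = self.z_nodes
            db0 = np.sqrt(2.0) * l11[:, None] * z[None, :, 0]
            db1 = np.sqrt(2.0) * (l21[:, None] * z[None, :, 0] + l22[:, None] * z[None, :, 1])
            b_nodes = np.stack([b_hat[:, 0:1] + db0, b_hat[:, 1:2] + db1], axis=-1)
        else:
            sd = 1.0 / np.sqrt(M[:, 0, 0])
            logdet_L = np.log(sd)
            b_nodes = (b_hat[:, 0:1] + np.sqrt(2.0) * sd[:, None] * self.z_nodes[None, :, 0])[..., None]

        g = self._g_at(b_nodes, theta_parts, const)
        li = (0.5 * self.q * np.log(2.0) + logdet_L
              + logsumexp(self.logw[None, :] + self.z_sq[None, :] + g, axis=1))
        return float(np.sum(li))

    def negloglik(self, theta: np.ndarray) -> float:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            ll = self.loglik(theta)
        return -ll if np.isfinite(ll) else 1e12

    def _precondition_scale(self, theta: np.ndarray) -> np.ndarray:
        """Per-parameter scale from the diagonal observed curvature at the
        starting values, so the optimizer sees roughly unit curvature in
        every direction (the raw directions differ by ~7 orders)."""
        p = len(theta)
        f0 = self.negloglik(theta)
        diag = np.empty(p)
        step = 1e-3 * np.maximum(np.abs(theta), 1.0)
        for i in range(p):
            e = np.zeros(p)
            e[i] = step[i]
            diag[i] = (self.negloglik(theta + e) - 2.0 * f0 + self.negloglik(theta - e)) / step[i] ** 2
        pos = diag[diag > 0]
        floor = (np.median(pos) if pos.size else 1.0) * 1e-3
        return 1.0 / np.sqrt(np.clip(diag, floor, None))

    def fit(self, init: np.ndarray | None = None, long: pd.DataFrame | None = None,
            max_iter: int = 400, compute_vcov: bool = True) -> JointModelFit:
        if init is None:
            init = self.default_init(long)
        self._mode_cache[:] = 0.0
        scale = self._precondition_scale(init)
        res = minimize(lambda xi: self.negloglik(init + scale * xi), np.zeros(len(init)),
                       method="L-BFGS-B",
                       options={"maxiter": max_iter, "ftol": 1e-11, "gtol": 1e-6,
                                "maxcor": 25})
        theta = init + scale * res.x
        ll = self.loglik(theta)
        beta, sigma2, D, gamma, assoc, rates = self.unpack(theta)

        vcov = None
        if compute_vcov:
            Hn = observed_information(self.negloglik, theta)
            try:
                vcov = np.linalg.inv(Hn)
                if np.any(np.diag(vcov) <= 0):
                    raise np.linalg.LinAlgError
                A = self._raw_jacobian()
                vcov = A @ vcov @ A.T      # delta method back to the raw scale
            except np.linalg.LinAlgError:
                warnings.warn("observed information singular or indefinite; "
                              "standard errors unavailable", stacklevel=2)
                vcov = None

        return JointModelFit(
            spec=self.spec, knots=self.knots, beta=beta, sigma2=sigma2, D=D,
            gamma=gamma, assoc=assoc, log_rates=np.log(rates), loglik=ll,
            vcov=vcov, param_names=self.param_names, theta=theta,
            converged=bool(res.success), n_subjects=self.n, n_events=self.n_events,
            n_iter=int(res.nit), hazard_center=self.m_center)

    def default_init(self, long: pd.DataFrame | None = None) -> np.ndarray:
        """LMM + Cox starting values with a = 0 and crude piecewise rates."""
        lfit = fit_lmm(long, self.spec.lmm_spec, id_col=self.id_col) if long is not None else None
        if lfit is None:
            raise ValueError("default_init needs the longitudinal table")
        if self.spec.survival_covariates:
            cfit = fit_cox(self.surv, self.spec.survival_covariates)
            gamma0 = cfit.gamma
        else:
            gamma0 = np.zeros(0)
        eta = self.W @ gamma0 if self.W.shape[1] else np.zeros(self.n)
        exposure = (self.u1 - self.u0) * np.exp(eta)[:, None]
        d_k = np.array([self.delta[self.k_event == k].sum() for k in range(self.K)])
        rates0 = np.maximum(d_k, 0.5) / np.maximum(exposure.sum(0), 1e-12)
        return self.pack(lfit.beta, lfit.sigma2, lfit.D, gamma0, 0.0, rates0)


def observed_information(negloglik, theta: np.ndarray, rel_step: float = 1e-5) -> np.ndarray:
    """Numerical Hessian of the negative log-likelihood (central differences)."""
    p = len(theta)
    h = rel_step * np.maximum(np.abs(theta), 1.0)
    H = np.zeros((p, p))
    f0 = negloglik(theta)
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h[i]
            ej = np.zeros(p); ej[j] = h[j]
            if i == j:
                f1 = negloglik(theta + ei)
                f2 = negloglik(theta - ei)
                H[i, i] = (f1 - 2.0 * f0 + f2) / h[i] ** 2
            else:
                fpp = negloglik(theta + ei + ej)
                fpm = negloglik(theta + ei - ej)
                fmp = negloglik(theta - ei + ej)
                fmm = negloglik(theta - ei - ej)
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * h[i] * h[j])
    return H


def fit_joint(long: pd.DataFrame, surv: pd.DataFrame, spec: JointModelSpec,
              init: np.ndarray | None = None, compute_vcov: bool = True) -> JointModelFit:
    """Fit the joint model; initializes from the LMM and Cox sub-fits (a=0)."""
    jm = JointModel(long, surv, spec)
    if init is None:
        init = jm.default_init(long)
    return jm.fit(init=init, compute_vcov=compute_vcov)


def joint_loglik(long: pd.DataFrame, surv: pd.DataFrame, spec: JointModelSpec,
                 beta, sigma2, D, gamma, assoc, rates) -> float:
    """Adaptive-GH joint log-likelihood at explicitly supplied parameters."""
    jm = JointModel(long, surv, spec)
    return jm.loglik(jm.pack(beta, sigma2, D, gamma, assoc, rates))


def piecewise_ph_loglik(surv: pd.DataFrame, covariates: list[str],
                        knots, rates, gamma) -> float:
    """Log-likelihood of the piecewise-exponential PH model (no marker link)."""
    knots = np.asarray(knots, float)
    rates = np.asarray(rates, float)
    T = surv["event_time"].to_numpy(float)
    delta = surv["event"].to_numpy(float)
    W = build_design(surv, covariates) if covariates else np.zeros((len(T), 0))
    eta = W @ np.asarray(gamma, float) if covariates else np.zeros(len(T))
    u0, u1 = interval_bounds(knots, T)
    H = np.exp(eta) * ((u1 - u0) @ rates)
    k = interval_index(knots, T)
    return float(np.sum(delta * (np.log(rates)[k] + eta) - H))


def rr_per_fraction(fit: JointModelFit, fraction: float = 0.10):
    """Relative risk for a (100*fraction)% multiplicative increase of the raw
    marker. The marker enters the hazard on the natural-log scale, so the
    shift in m is ln(1+fraction): RR = exp(a * ln(1+fraction)), with a Wald
    CI on the log scale and a Wald p-value for a = 0."""
    if fraction <= -1:
        raise ValueError("fraction must be > -1")
    step = np.log1p(fraction)
    a, se = fit.assoc, fit.assoc_se
    rr = float(np.exp(a * step))
    if np.isnan(se):
        return rr, float("nan"), float("nan"), float("nan")
    lo = float(np.exp((a - 1.959963984540054 * se) * step))
    hi = float(np.exp((a + 1.959963984540054 * se) * step))
    if step < 0:
        lo, hi = hi, lo
    z = a / se
    p = float(2.0 * sstats.norm.sf(abs(z)))
    return rr, lo, hi, p
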