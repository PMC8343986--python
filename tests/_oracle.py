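"""Brute-force dense-grid evaluation of the joint likelihood.

Independent oracle: builds the integrand directly from the model formulas
(Gaussian longitudinal density x survival density x random-effects prior)
and integrates over the random effects on a dense grid. Shares no code with
the adaptive-quadrature implementation under test.
"""

import numpy as np
from scipy.special import logsumexp
from scipy.stats import multivariate_normal, norm


def _cumhaz(T, knots, rates, s, level):
    """integral_0^T rates(t)*exp(level + s*t) dt, elementary antiderivative
    per constant-rate interval ((e^{s u1} - e^{s u0})/s); s, level arrays.

    The piecewise-exponential quadrature in test_piecewise.py validates this
    textbook form against scipy.integrate.quad independently.
    """
    s = np.asarray(s, float)
    level = np.asarray(level, float)
    upper = np.concatenate([knots[1:], [np.inf]])
    H = np.zeros_like(s)
    for k in range(len(knots)):
        u0 = min(knots[k], T)
        u1 = min(upper[k], T)
        if u1 <= u0:
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            I = (np.exp(s * u1) - np.exp(s * u0)) / s
        tiny = np.abs(s * (u1 - u0)) < 1e-9
        if np.any(tiny):
            I = np.where(tiny, (u1 - u0) * np.exp(s * (u0 + u1) / 2.0), I)
        H = H + rates[k] * I
    return np.exp(level) * H


def brute_force_joint_loglik(long, surv, beta_map, sigma2, D, gamma_map, a,
                             knots, rates, center, n_grid=201, width=8.0):
    """Sum over subjects of log integral p(y|b) p(T,delta|b) phi(b) db.

    ``beta_map``/``gamma_map`` map design column names (with 'intercept',
    'time' conventions) to coefficients. 2-D random effects use an
    (n_grid x n_grid) trapezoid grid, 1-D a 10,001-point grid.
    """
    D = np.atleast_2d(np.asarray(D, float))
    q = D.shape[0]
    knots = np.asarray(knots, float)
    rates = np.asarray(rates, float)
    total = 0.0
    for sid, grp in long.groupby("subject_id", sort=True):
        row = surv.loc[surv["subject_id"] == sid].iloc[0]
        T, delta = float(row["event_time"]), int(row["event"])
        eta = sum(v * float(row[k]) for k, v in gamma_map.items())
        fixed0 = sum(v * (1.0 if k == "intercept" else float(row[k]))
                     for k, v in beta_map.items() if k != "time")
        slope0 = beta_map["time"]

        if q == 2:
            g0 = np.linspace(-width * np.sqrt(D[0, 0]), width * np.sqrt(D[0, 0]), n_grid)
            g1 = np.linspace(-width * np.sqrt(D[1, 1]), width * np.sqrt(D[1, 1]), n_grid)
            B0, B1 = np.meshgrid(g0, g1, indexing="ij")
            steps = (g0[1] - g0[0]) * (g1[1] - g1[0])
            prior = multivariate_normal.logpdf(np.dstack([B0, B1]), np.zeros(2), D)
        else:
            g0 = np.linspace(-width * np.sqrt(D[0, 0]), width * np.sqrt(D[0, 0]), 10001)
            B0, B1 = g0, np.zeros_like(g0)
            steps = g0[1] - g0[0]
            prior = norm.logpdf(g0, 0.0, np.sqrt(D[0, 0]))

        lp = prior.astype(float)
        for _, obs in grp.iterrows():
            m = fixed0 + slope0 * obs["time"] + B0 + B1 * obs["time"]
            lp = lp + norm.logpdf(obs["log_marker"], m, np.sqrt(sigma2))

        c = fixed0 - center + B0
        d = slope0 + B1
        H = _cumhaz(T, knots, rates, a * d, eta + a * c)
        k_ev = int(np.clip(np.searchsorted(knots, T, side="right") - 1, 0, len(knots) - 1))
        lp = lp + delta * (np.log(rates[k_ev]) + eta + a * (c + d * T)) - H

        total += logsumexp(lp) + np.log(steps)
    return float(total)
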