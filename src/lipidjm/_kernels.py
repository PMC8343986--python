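"""Optional numba acceleration for the adaptive Gauss-Hermite likelihood.

One fused kernel per likelihood evaluation: for every subject it runs the
Newton search for the posterior mode of the random effects, forms the
mode Hessian, places the scaled Gauss-Hermite nodes and accumulates the
log integral -- no intermediate (n, nodes, intervals) arrays. joint.py
falls back to a pure-numpy implementation when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba is normally installed
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]

_LOG2PI = np.log(2.0 * np.pi)


@njit(cache=True, inline="always")
def _interval_integrals(s, u0, u1, rates, want):  # pragma: no cover - jitted
    """sum_k rates_k * Int_{[u0_k,u1_k]} u^m exp(s u) du for m = 0,1,2."""
    I0 = 0.0
    I1 = 0.0
    I2 = 0.0
    K = rates.shape[0]
    for k in range(K):
        a0 = u0[k]
        a1 = u1[k]
        d = a1 - a0
        if d <= 0.0:
            continue
        sd = s * d
        if abs(sd) < 1e-3:
            e0 = np.exp(min(s * a0, 600.0))
            j0 = d * (1.0 + sd * (0.5 + sd * (1.0 / 6.0 + sd / 24.0)))
            v0 = e0 * j0
            if want > 0:
                j1 = d * d * (0.5 + sd * (1.0 / 3.0 + sd * (0.125 + sd / 30.0)))
                v1 = e0 * (a0 * j0 + j1)
                if want > 1:
                    j2 = d * d * d * (1.0 / 3.0 + sd * (0.25 + sd * (0.1 + sd / 36.0)))
                    v2 = e0 * (a0 * a0 * j0 + 2.0 * a0 * j1 + j2)
        else:
            e0 = np.exp(min(s * a0, 600.0))
            e1 = np.exp(min(s * a1, 600.0))
            v0 = (e1 - e0) / s
            if want > 0:
                v1 = (a1 * e1 - a0 * e0 - v0) / s
                if want > 1:
                    v2 = (a1 * a1 * e1 - a0 * a0 * e0 - 2.0 * v1) / s
        I0 += rates[k] * v0
        if want > 0:
            I1 += rates[k] * v1
            if want > 1:
                I2 += rates[k] * v2
    return I0, I1, I2


@njit(cache=True, inline="always")
def _g_subject(x0, x1, rtr, h0, h1, A00, A01, A11, n_i, sigma2, ls2,
               c0, d0, eta, lrT, T, delta, u0, u1, rates, a,
               Di00, Di01, Di11, logdet_D, q):  # pragma: no cover - jitted
    quad = A00 * x0 * x0 + 2.0 * A01 * x0 * x1 + A11 * x1 * x1
    lin = h0 * x0 + h1 * x1
    g = -0.5 * (rtr - 2.0 * lin + quad) / sigma2 - 0.5 * n_i * (_LOG2PI + ls2)

    s = a * (d0 + x1)
    I0, _, _ = _interval_integrals(s, u0, u1, rates, 0)
    lev = eta + a * (c0 + x0)
    logH = lev + np.log(I0)
    if logH > 690.0:
        logH = 690.0
    g += delta * (lrT + eta + a * (c0 + x0 + T * (d0 + x1))) - np.exp(logH)

    bq = Di00 * x0 * x0 + 2.0 * Di01 * x0 * x1 + Di11 * x1 * x1
    g += -0.5 * bq - 0.5 * (q * _LOG2PI + logdet_D)
    return g


@njit(cache=True)
def agq_loglik(b_cache, z, logw_zsq, rtr, h0, h1, A00, A01, A11, n_i, sigma2,
               c0, d0, eta, lrT, T, delta, u0, u1, rates, a,
               Di00, Di01, Di11, logdet_D, q):  # pragma: no cover - jitted
    """Adaptive GH log-likelihood summed over subjects; updates b_cache."""
    n = rtr.shape[0]
    J = z.shape[0]
    ls2 = np.log(sigma2)
    sqrt2 = np.sqrt(2.0)
    total = 0.0
    gvals = np.empty(J)

    for i in range(n):
        # ---- Newton for the posterior mode (g is log-concave in b) ----
        x0 = b_cache[i, 0]
        x1 = b_cache[i, 1]
        g = _g_subject(x0, x1, rtr[i], h0[i], h1[i], A00[i], A01[i], A11[i],
                       n_i[i], sigma2, ls2, c0[i], d0, eta[i], lrT[i], T[i],
                       delta[i], u0[i], u1[i], rates, a,
                       Di00, Di01, Di11, logdet_D, q)
        M00 = M01 = M11 = 0.0
        for _ in range(60):
            s = a * (d0 + x1)
            lev = eta[i] + a * (c0[i] + x0)
            H0, H1, H2 = _interval_integrals(s, u0[i], u1[i], rates, 2)
            e = np.exp(min(lev, 690.0))
            H = e * H0
            Hu = e * H1
            Huu = e * H2

            g0 = (h0[i] - A00[i] * x0 - A01[i] * x1) / sigma2 - (Di00 * x0 + Di01 * x1) \
                + delta[i] * a - a * H
            m00 = A00[i] / sigma2 + Di00 + a * a * H
            if q == 2:
                g1 = (h1[i] - A01[i] * x0 - A11[i] * x1) / sigma2 - (Di01 * x0 + Di11 * x1) \
                    + delta[i] * a * T[i] - a * Hu
                m01 = A01[i] / sigma2 + Di01 + a * a * Hu
                m11 = A11[i] / sigma2 + Di11 + a * a * Huu
                det = m00 * m11 - m01 * m01
                s0 = (m11 * g0 - m01 * g1) / det
                s1 = (m00 * g1 - m01 * g0) / det
            else:
                m01 = 0.0
                m11 = 1.0
                s0 = g0 / m00
                s1 = 0.0
            M00, M01, M11 = m00, m01, m11
            if abs(s0) < 1e-10 and abs(s1) < 1e-10:
                break
            scale = 1.0
            for _ in range(30):
                g_new = _g_subject(x0 + scale * s0, x1 + scale * s1, rtr[i], h0[i], h1[i],
                                   A00[i], A01[i], A11[i], n_i[i], sigma2, ls2, c0[i], d0,
                                   eta[i], lrT[i], T[i], delta[i], u0[i], u1[i], rates, a,
                                   Di00, Di01, Di11, logdet_D, q)
                if g_new >= g - 1e-12:
                    break
                scale *= 0.5
            x0 += scale * s0
            x1 += scale * s1
            g = g_new
            if abs(scale * s0) < 1e-9 and abs(scale * s1) < 1e-9:
                break
        b_cache[i, 0] = x0
        if q == 2:
            b_cache[i, 1] = x1

        # ---- scaled nodes: b = b_hat + sqrt(2) L z, L = chol(M^{-1}) ----
        if q == 2:
            det = M00 * M11 - M01 * M01
            s00 = M11 / det
            s01 = -M01 / det
            s11 = M00 / det
            l11 = np.sqrt(s00)
            l21 = s01 / l11
            t = s11 - l21 * l21
            if t < 1e-300:
                t = 1e-300
            l22 = np.sqrt(t)
            logdet_L = np.log(l11) + np.log(l22)
        else:
            l11 = 1.0 / np.sqrt(M00)
            l21 = 0.0
            l22 = 0.0
            logdet_L = np.log(l11)

        gmax = -np.inf
        for j in range(J):
            z0 = z[j, 0]
            z1 = z[j, 1]
            n0 = x0 + sqrt2 * l11 * z0
            n1 = x1 + sqrt2 * (l21 * z0 + l22 * z1) if q == 2 else 0.0
            gj = _g_subject(n0, n1, rtr[i], h0[i], h1[i], A00[i], A01[i], A11[i],
                            n_i[i], sigma2, ls2, c0[i], d0, eta[i], lrT[i], T[i],
                            delta[i], u0[i], u1[i], rates, a,
                            Di00, Di01, Di11, logdet_D, q) + logw_zsq[j]
            gvals[j] = gj
            if gj > gmax:
                gmax = gj
        acc = 0.0
        for j in range(J):
            acc += np.exp(gvals[j] - gmax)
        total += 0.5 * q * np.log(2.0) + logdet_L + gmax + np.log(acc)
    return total
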