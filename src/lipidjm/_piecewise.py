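"""Closed-form integrals of exp(s*u) and polynomial moments over intervals.

These are the workhorse for a piecewise-constant baseline hazard combined
with a latent trajectory that is linear in time: on each constant-hazard
interval the cumulative hazard is an integral of exp(level + slope*u), which
has the closed forms below. All functions broadcast and are numerically
stable as slope -> 0 (Taylor switch-over).
"""

from __future__ import annotations

import numpy as np

_SMALL = 1e-3  # |s*delta| below this uses the Taylor branch


def _taylor_branch(exact_fn, taylor_fn, s, d):
    """exact_fn everywhere except where |s*d| is small, where taylor_fn is
    accurate; skips the exact branch entirely when all entries are small."""
    s, d = np.broadcast_arrays(s, d)
    sd = s * d
    small = np.abs(sd) < _SMALL
    n_small = np.count_nonzero(small)
    if n_small == small.size:
        return taylor_fn(sd, d)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        out = exact_fn(s, d, sd)
    if n_small:
        idx = np.nonzero(small)
        out[idx] = taylor_fn(sd[idx], d[idx])
    return out


def _j0(s, d):
    """Integral of exp(s*v) dv over [0, d]."""
    return _taylor_branch(
        lambda s, d, sd: np.expm1(sd) / s,
        lambda sd, d: d * (1.0 + sd * (0.5 + sd * (1.0 / 6.0 + sd / 24.0))),
        s, d)


def _j1(s, d):
    """Integral of v*exp(s*v) dv over [0, d]."""
    return _taylor_branch(
        lambda s, d, sd: (d * np.exp(sd) - np.expm1(sd) / s) / s,
        lambda sd, d: d * d * (0.5 + sd * (1.0 / 3.0 + sd * (0.125 + sd / 30.0))),
        s, d)


def _j2(s, d):
    """Integral of v^2*exp(s*v) dv over [0, d]."""
    def exact(s, d, sd):
        e = np.exp(sd)
        j1 = (d * e - np.expm1(sd) / s) / s
        return (d * d * e - 2.0 * j1) / s

    return _taylor_branch(
        exact,
        lambda sd, d: d * d * d * (1.0 / 3.0 + sd * (0.25 + sd * (0.1 + sd / 36.0))),
        s, d)


def exp_int0(s, u0, u1):
    """Integral of exp(s*u) du over [u0, u1]."""
    u0, u1 = np.broadcast_arrays(u0, u1)
    return np.exp(np.asarray(s) * u0) * _j0(s, u1 - u0)


def exp_int1(s, u0, u1):
    """Integral of u*exp(s*u) du over [u0, u1]."""
    s = np.asarray(s, float)
    u0, u1 = np.broadcast_arrays(u0, u1)
    d = u1 - u0
    return np.exp(s * u0) * (u0 * _j0(s, d) + _j1(s, d))


def exp_int2(s, u0, u1):
    """Integral of u^2*exp(s*u) du over [u0, u1]."""
    s = np.asarray(s, float)
    u0, u1 = np.broadcast_arrays(u0, u1)
    d = u1 - u0
    return np.exp(s * u0) * (u0**2 * _j0(s, d) + 2.0 * u0 * _j1(s, d) + _j2(s, d))


def interval_bounds(knots: np.ndarray, t):
    """Clip the half-open hazard intervals [knots[k], knots[k+1]) to [0, t].

    Returns (u0, u1) arrays of shape t.shape + (K,) with u1 >= u0 (empty
    intervals collapse to zero length). The last interval extends to t.
    """
    knots = np.asarray(knots, float)
    t = np.asarray(t, float)
    upper = np.concatenate([knots[1:], [np.inf]])
    u0 = np.minimum(knots, t[..., None])
    u1 = np.minimum(upper, t[..., None])
    return u0, np.maximum(u1, u0)


def interval_index(knots: np.ndarray, t):
    """Index k of the hazard interval containing each time t."""
    return np.clip(np.searchsorted(np.asarray(knots, float), np.asarray(t, float), side="right") - 1, 0, len(knots) - 1)
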