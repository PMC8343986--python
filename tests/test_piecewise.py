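"""The closed-form interval integrals against numerical quadrature."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from lipidjm._piecewise import exp_int0, exp_int1, exp_int2, interval_bounds, interval_index


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    s=st.floats(-3.0, 3.0),
    u0=st.floats(0.0, 10.0),
    d=st.floats(1e-6, 8.0),
)
def test_exponential_moment_integrals_match_quadrature(s, u0, d):
    u1 = u0 + d
    for m, fn in enumerate((exp_int0, exp_int1, exp_int2)):
        exact = fn(np.array(s), np.array(u0), np.array(u1))
        num, _ = quad(lambda u: u**m * np.exp(s * u), u0, u1)
        assert np.isclose(float(exact), num, rtol=1e-8, atol=1e-12)


@pytest.mark.parametrize("s", [0.0, 1e-12, -1e-9, 1e-4])
def test_small_slope_limit_is_polynomial(s):
    u0, u1 = 1.0, 4.0
    assert np.isclose(float(exp_int0(s, u0, u1)), (u1 - u0) * np.exp(s * 2.5), rtol=1e-3)
    assert np.isclose(float(exp_int1(np.array(0.0), u0, u1)), (u1**2 - u0**2) / 2, rtol=1e-12)
    assert np.isclose(float(exp_int2(np.array(0.0), u0, u1)), (u1**3 - u0**3) / 3, rtol=1e-12)


def test_interval_clipping_and_index():
    knots = np.array([0.0, 3.0, 6.0])
    u0, u1 = interval_bounds(knots, np.array([4.5, 10.0, 2.0]))
    assert np.allclose(u0[0], [0, 3, 4.5]) and np.allclose(u1[0], [3, 4.5, 4.5])
    assert np.allclose(u1[1], [3, 6, 10.0])
    assert np.allclose(u1[2] - u0[2], [2.0, 0.0, 0.0])
    assert list(interval_index(knots, np.array([0.5, 3.0, 100.0]))) == [0, 1, 2]
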