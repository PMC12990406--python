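"""Cascade kinetics: closed forms, the numeric integrator and their invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dwatch import (
    CascadeParams,
    System,
    bateman_abc,
    simulate_biphasic_intermediate,
    simulate_cascade,
    simulate_conversion_pair,
    simulate_stable,
)
from dwatch.errors import ParameterError

GRID = np.arange(0.0, 240.0 + 1e-9, 0.5)


def rk4_chain(A0, k1, k2, t_end, dt=0.01):
    """Independent fixed-step RK4 oracle for the fully dissolved chain A→B→C."""

    def f(y):
        A, B, C = y
        return np.array([-k1 * A, k1 * A - k2 * B, k2 * B])

    y = np.array([A0, 0.0, 0.0])
    n = int(round(t_end / dt))
    for _ in range(n):
        k1_ = f(y)
        k2_ = f(y + 0.5 * dt * k1_)
        k3_ = f(y + 0.5 * dt * k2_)
        k4_ = f(y + dt * k3_)
        y = y + dt / 6.0 * (k1_ + 2 * k2_ + 2 * k3_ + k4_)
    return y


class TestClosedForms:
    def test_pure_dissolution_closed_form(self):
        """With no hydrolysis, A follows M0·f(t) = M0·(1−e^{−k_d t}) exactly."""
        p = CascadeParams(M0=10.0, k_d=0.05, k1=0.0, k2=0.0, f0=0.0)
        res = simulate_cascade(p, GRID)
        expected = 10.0 * (1.0 - np.exp(-0.05 * GRID))
        np.testing.assert_allclose(res.A.values, expected, rtol=1e-8, atol=1e-9)
        assert np.all(res.B.values == 0) and np.all(res.C.values == 0)

    def test_bateman_at_named_point_vs_rk4(self):
        """A = A0·e^{−1} at t=50 for k1=0.02; B matches an RK4 oracle to 1e−6."""
        A0, k1, k2 = 100.0, 0.02, 0.01
        t = np.array([50.0])
        A, B, C = bateman_abc(t, A0, k1, k2)
        assert A[0] == pytest.approx(A0 * np.exp(-1.0), rel=1e-12)
        oracle = rk4_chain(A0, k1, k2, 50.0)
        np.testing.assert_allclose([A[0], B[0], C[0]], oracle, rtol=1e-6)

    @pytest.mark.parametrize("draw", range(20))
    def test_bateman_vs_numeric_integrator(self, draw):
        """Closed form and the ODE integrator agree to <1e−6 relative."""
        rng = np.random.default_rng(1000 + draw)
        k1, k2 = rng.uniform(0.002, 0.1, size=2)
        if abs(k1 - k2) < 1e-4:
            k2 = k1 * 1.5
        A0 = rng.uniform(1.0, 100.0)
        p = CascadeParams(M0=A0, k_d=0.0, k1=k1, k2=k2, f0=1.0)
        closed = simulate_cascade(p, GRID)
        numeric = simulate_cascade(p, GRID, force_numeric=True)
        scale = A0
        for a, b in ((closed.A, numeric.A), (closed.B, numeric.B), (closed.C, numeric.C)):
            np.testing.assert_allclose(a.values / scale, b.values / scale, atol=1e-6)

    def test_equal_rates_degenerate_limit(self):
        """k1 = k2 uses the t·e^{−kt} closed form and matches the integrator."""
        p = CascadeParams(M0=50.0, k_d=0.0, k1=0.03, k2=0.03, f0=1.0)
        closed = simulate_cascade(p, GRID)
        expected_B = 50.0 * 0.03 * GRID * np.exp(-0.03 * GRID)
        np.testing.assert_allclose(closed.B.values, expected_B, rtol=1e-10)
        numeric = simulate_cascade(p, GRID, force_numeric=True)
        np.testing.assert_allclose(closed.B.values / 50.0, numeric.B.values / 50.0,
                                   atol=1e-6)

    def test_mass_conservation_closed_form(self):
        p = CascadeParams(M0=7.0, k_d=0.0, k1=0.05, k2=0.02, f0=1.0)
        res = simulate_cascade(p, GRID)
        np.testing.assert_allclose(res.total, 7.0, rtol=1e-9)


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    M0=st.floats(1.0, 1e4),
    k_d=st.floats(0.0, 0.3),
    k1=st.floats(0.0, 0.2),
    k2=st.floats(0.0, 0.2),
    f0=st.floats(0.0, 1.0),
)
def test_mass_conservation_property(M0, k_d, k1, k2, f0):
    """M+A+B+C stays equal to M0 on every grid point for any parameters."""
    grid = np.arange(0.0, 120.0 + 1e-9, 1.0)
    res = simulate_cascade(CascadeParams(M0=M0, k_d=k_d, k1=k1, k2=k2, f0=f0), grid)
    np.testing.assert_allclose(res.total, M0, rtol=2e-6, atol=1e-9 * max(M0, 1.0))


class TestValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(M0=1.0, k_d=-0.1), dict(M0=1.0, k_d=0.1, k1=-1e-3),
        dict(M0=1.0, k_d=0.1, f0=-0.01), dict(M0=1.0, k_d=0.1, f0=1.01),
        dict(M0=-1.0, k_d=0.1), dict(M0=1.0, k_d=0.1, inhibition=0.0),
    ])
    def test_bad_parameters_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            CascadeParams(**kwargs)

    def test_bad_grid_rejected(self):
        p = CascadeParams(M0=1.0, k_d=0.1)
        with pytest.raises(ParameterError):
            simulate_cascade(p, np.array([0.0, 1.0, 1.0]))
        with pytest.raises(ParameterError):
            simulate_cascade(p, np.array([-1.0, 1.0]))


class TestInhibition:
    def test_stronger_inhibition_never_decreases_monoester(self):
        """Raising the k2 inhibition factor preserves B(t) pointwise."""
        base = dict(M0=100.0, k_d=0.1, k1=0.05, k2=0.02, f0=0.15)
        prev = None
        for inhibition in (1.0, 1.5, 2.0, 5.0, 20.0):
            res = simulate_cascade(CascadeParams(**base, inhibition=inhibition),
                                   GRID, system=System.CO)
            if prev is not None:
                assert np.all(res.B.values >= prev - 1e-9 * 100.0)
            prev = res.B.values

    def test_single_system_ignores_inhibition(self):
        base = dict(M0=100.0, k_d=0.1, k1=0.05, k2=0.02, f0=0.15)
        a = simulate_cascade(CascadeParams(**base, inhibition=5.0), GRID)
        b = simulate_cascade(CascadeParams(**base, inhibition=1.0), GRID)
        np.testing.assert_array_equal(a.B.values, b.B.values)


class TestParameterRecovery:
    def test_rates_recovered_from_noiseless_cascade(self):
        """Least squares on a noiseless cascade recovers k1, k2 to <0.1 %."""
        from scipy.optimize import least_squares

        true = CascadeParams(M0=100.0, k_d=0.1, k1=0.04, k2=0.015, f0=0.15)
        target = simulate_cascade(true, GRID)

        def resid(x):
            p = CascadeParams(M0=100.0, k_d=0.1, k1=x[0], k2=x[1], f0=0.15)
            res = simulate_cascade(p, GRID)
            return np.concatenate([res.B.values - target.B.values,
                                   res.C.values - target.C.values])

        sol = least_squares(resid, [0.06, 0.01], bounds=([1e-5, 1e-5], [1.0, 1.0]))
        assert sol.x[0] == pytest.approx(0.04, rel=1e-3)
        assert sol.x[1] == pytest.approx(0.015, rel=1e-3)


class TestBiphasic:
    def test_no_consumption_is_monotone(self):
        tr = simulate_biphasic_intermediate(0.02, 0.0, 100.0, GRID)
        assert np.all(np.diff(tr.values) >= -1e-12)

    def test_zero_source_pool_is_zero(self):
        tr = simulate_biphasic_intermediate(0.02, 0.01, 0.0, GRID)
        np.testing.assert_allclose(tr.values, 0.0, atol=1e-12)

    def test_single_interior_maximum(self):
        tr = simulate_biphasic_intermediate(0.03, 0.02, 100.0, GRID)
        i = int(np.argmax(tr.values))
        assert 0 < i < tr.values.size - 1
        assert np.all(np.diff(tr.values[: i + 1]) >= -1e-9)
        assert np.all(np.diff(tr.values[i:]) <= 1e-9)

    def test_staged_source_delays_the_maximum(self):
        plain = simulate_biphasic_intermediate(0.03, 0.02, 100.0, GRID,
                                               source_release_rate=0.03)
        staged = simulate_biphasic_intermediate(0.03, 0.02, 100.0, GRID,
                                                source_release_rate=0.03,
                                                source_stages=8)
        assert GRID[np.argmax(staged.values)] > GRID[np.argmax(plain.values)]


class TestConversionPair:
    def test_zero_rate_keeps_product_constant(self):
        p = CascadeParams(M0=10.0, k_d=0.1, f0=0.15, B0=3.0)
        _, product = simulate_conversion_pair(p, 0.0, GRID)
        np.testing.assert_allclose(product.values, 3.0, rtol=1e-9)

    def test_product_monotone_and_total_conserved(self):
        p = CascadeParams(M0=10.0, k_d=0.1, f0=0.15, B0=1.0)
        precursor, product = simulate_conversion_pair(p, 0.01, GRID)
        assert np.all(np.diff(product.values) >= -1e-12)
        # only dissolution + conversion act: M + precursor + product constant
        M = 10.0 * 0.85 * np.exp(-0.1 * GRID)
        np.testing.assert_allclose(M + precursor.values + product.values,
                                   11.0, rtol=1e-6)


class TestStable:
    def test_frozen_pool_is_constant(self):
        tr = simulate_stable(CascadeParams(M0=4.0, k_d=0.0, f0=1.0), GRID)
        np.testing.assert_allclose(tr.values, 4.0, rtol=1e-12)

    def test_fast_dissolution_reaches_plateau_before_50_min(self):
        k_d = 0.12  # 1 − e^{−0.12·50} ≈ 0.9975 of the plateau
        tr = simulate_stable(CascadeParams(M0=8.0, k_d=k_d, f0=0.15), GRID)
        i50 = int(50.0 / 0.5)
        assert tr.values[i50] >= 0.99 * 8.0

    def test_plateau_value_is_total_load(self):
        tr = simulate_stable(CascadeParams(M0=8.0, k_d=0.08, f0=0.15), GRID)
        assert tr.values[-1] == pytest.approx(8.0, rel=1e-6)
        assert np.all(np.diff(tr.values) >= -1e-12)
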