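"""Closed-form Riccati solution: examples, invariants, regime labels."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfrel import riccati


class TestParamsFromCoefficients:
    def test_oscillatory_example(self):
        p = riccati.params_from_coefficients(riccati.RiccatiCoefficients(1, 0, -1))
        assert p.amp_A == 1.0
        assert p.offset_B == 0.0
        assert p.omega == pytest.approx(1.0)

    def test_zero_a1_rejected(self):
        with pytest.raises(ValueError):
            riccati.RiccatiCoefficients(0, 1, 1)

    def test_real_root_regime_rejected(self):
        with pytest.raises(riccati.NonOscillatoryError):
            riccati.params_from_coefficients(riccati.RiccatiCoefficients(1, 0, 1))


class TestClosedForm:
    def test_r_zero_is_constant(self):
        p = riccati.RiccatiParams(amp_A=2.0, offset_B=0.5, omega=3.0, r=0.0)
        t = np.linspace(0, 10, 50)
        z = riccati.z_solution(p, t)
        assert np.allclose(z, 0.5 + 2.0 * 3.0 * 1j)

    def test_hand_value_at_phi_pi(self):
        # A=1, B=0, Omega=1, r=0.5, t = pi/2: denominator (1-r)^2,
        # Re = 0, Im = (1-r^2)/(1-r)^2 = (1+r)/(1-r) = 3
        p = riccati.RiccatiParams(omega=1.0, r=0.5)
        z = riccati.z_solution(p, math.pi / 2)
        assert z == pytest.approx(3j, abs=1e-12)

    @given(
        omega=st.floats(0.1, 50.0),
        r=st.floats(0.0, 0.95),
        A=st.floats(-3.0, 3.0).filter(lambda x: abs(x) > 1e-3),
        B=st.floats(-2.0, 2.0),
        t=st.floats(-5.0, 5.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_periodicity(self, omega, r, A, B, t):
        p = riccati.RiccatiParams(amp_A=A, offset_B=B, omega=omega, r=r)
        z1 = riccati.z_solution(p, t)
        z2 = riccati.z_solution(p, t + p.period)
        assert z2 == pytest.approx(z1, rel=1e-9, abs=1e-9)

    @given(omega=st.floats(0.5, 20.0), r=st.floats(0.0, 0.9))
    @settings(max_examples=50, derandomize=True)
    def test_im_z_positive_and_bounded(self, omega, r):
        p = riccati.RiccatiParams(omega=omega, r=r)
        t = np.linspace(0, 3 * p.period, 400)
        im = riccati.z_solution(p, t).imag
        lo = omega * (1 - r) / (1 + r)
        hi = omega * (1 + r) / (1 - r)
        assert np.all(im > 0)
        assert np.all(im >= lo - 1e-9)
        assert np.all(im <= hi + 1e-9)

    def test_extrema_closed_form_vs_search(self):
        for omega, r in riccati.FIG_SWEEP_PAIRS:
            p = riccati.RiccatiParams(omega=omega, r=r, offset_B=0.3, amp_A=1.2)
            mn_c, mx_c = riccati.re_z_extrema(p)
            mn_s, mx_s = riccati._extrema_by_search(p)
            assert mx_s == pytest.approx(mx_c, abs=1e-8)
            assert mn_s == pytest.approx(mn_c, abs=1e-8)

    def test_period_mean_closed_forms(self):
        p = riccati.RiccatiParams(amp_A=1.5, offset_B=-0.7, omega=2.5, r=0.6)
        re_mean, im_mean = riccati._mean_over_period(p)
        assert re_mean == pytest.approx(p.offset_B, abs=1e-6)
        assert im_mean == pytest.approx(p.amp_A * p.omega, rel=1e-6)


class TestSweep:
    def test_figure_pairs_bounded(self):
        t = np.linspace(0, 20, 2001)
        series = riccati.regime_sweep([1.1, 1.5, 14, 28], [0.1, 0.5], t)
        assert len(series) == 8
        for s in series:
            lo, hi = riccati.re_z_extrema(s.params)
            assert s.re_z.max() <= hi + 1e-9
            assert s.re_z.min() >= lo - 1e-9

    def test_single_point_grids(self):
        series = riccati.regime_sweep([2.0], [0.3], np.array([0.0]))
        assert len(series) == 1 and len(series[0].re_z) == 1

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            riccati.regime_sweep([], [0.1], np.linspace(0, 1, 10))

    def test_r_out_of_range(self):
        with pytest.raises(ValueError):
            riccati.regime_sweep([1.0], [1.0], np.linspace(0, 1, 10))


class TestOdeResidual:
    def test_small_residual_on_fine_grid(self):
        p = riccati.RiccatiParams(omega=2.0, r=0.4)
        t = np.linspace(0, 2 * p.period, 2001)  # ~1000 points/period
        assert riccati.ode_residual(p, t) < 1e-3 * p.omega

    def test_r_zero_residual_exactly_zero(self):
        p = riccati.RiccatiParams(omega=3.0, r=0.0)
        t = np.linspace(0, 2 * p.period, 101)
        assert riccati.ode_residual(p, t) == 0.0

    def test_second_order_convergence(self):
        p = riccati.RiccatiParams(omega=1.5, r=0.55)
        t1 = np.linspace(0, 2 * p.period, 501)
        t2 = np.linspace(0, 2 * p.period, 1001)
        ratio = riccati.ode_residual(p, t1) / riccati.ode_residual(p, t2)
        assert ratio == pytest.approx(4.0, rel=0.15)

    def test_coarse_grid_rejected(self):
        p = riccati.RiccatiParams(omega=1.0, r=0.3)
        t = np.linspace(0, 10 * p.period, 30)  # 3 points per period
        with pytest.raises(ValueError):
            riccati.ode_residual(p, t)


class TestRegimeClassification:
    @pytest.mark.parametrize("r,label", [(0.05, "near-harmonic"), (0.9, "spike-train")])
    def test_limiting_regimes(self, r, label):
        p = riccati.RiccatiParams(omega=2.0, r=r)
        t = np.linspace(0, 8 * p.period, 4000)
        series = riccati.RegimeSeries(
            t, riccati.z_solution(p, t).real, riccati.z_solution(p, t).imag, p
        )
        assert riccati.classify_regime(series) == label

    def test_deterministic(self):
        p = riccati.RiccatiParams(omega=1.1, r=0.5)
        t = np.linspace(0, 10 * p.period, 3000)
        z = riccati.z_solution(p, t)
        s = riccati.RegimeSeries(t, z.real, z.imag, p)
        assert riccati.classify_regime(s) == riccati.classify_regime(s)

    def test_short_series_rejected(self):
        p = riccati.RiccatiParams(omega=1.0, r=0.5)
        t = np.linspace(0, 2 * p.period, 500)
        z = riccati.z_solution(p, t)
        with pytest.raises(ValueError):
            riccati.classify_regime(riccati.RegimeSeries(t, z.real, z.imag, p))
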