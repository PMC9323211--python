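"""Kink law, classical dissolution baselines, fitting and preprocessing."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfrel import release_models as rm
from mfrel import synth


def make_kink_curve(p: rm.KinkParams, times=None, drug="x") -> rm.ReleaseCurve:
    t = np.asarray(times if times is not None else synth.DEFAULT_TIMES_MIN, dtype=float)
    return rm.ReleaseCurve(drug, t, rm.kink_mass(t, p), units="fraction")


class TestKinkLaw:
    def test_value_at_lag_is_offset(self):
        p = rm.KinkParams(B=0.2, a=0.5, A_scale=100.0, t0=40.0)
        assert rm.kink_mass(40.0, p) == pytest.approx(0.2)

    def test_asymptote(self):
        p = rm.KinkParams(B=0.2, a=0.5, A_scale=10.0, t0=0.0)
        t_far = 8 * p.A_scale / p.a
        assert rm.kink_mass(t_far, p) == pytest.approx(0.7, abs=1e-6)

    def test_hand_value_tanh1(self):
        p = rm.KinkParams(B=0.0, a=1.0, A_scale=1.0, t0=0.0)
        assert rm.kink_mass(1.0, p) == pytest.approx(math.tanh(1.0))

    @given(
        delta=st.floats(0.0, 500.0),
        B=st.floats(0.0, 0.5),
        a=st.floats(0.1, 0.9),
    )
    @settings(max_examples=100, derandomize=True)
    def test_point_symmetry_about_lag(self, delta, B, a):
        """M(t0+d) + M(t0-d) = 2B: the kink is odd about its lag point."""
        p = rm.KinkParams(B=B, a=a, A_scale=50.0, t0=100.0)
        s = rm.kink_mass(p.t0 + delta, p) + rm.kink_mass(p.t0 - delta, p)
        assert s == pytest.approx(2 * B, abs=1e-12)


class TestClassicalModels:
    def test_higuchi_hand_value(self):
        assert rm.classical_model("higuchi", 4.0, {"k": 0.1}) == pytest.approx(0.2)

    def test_kp_half_power_equals_higuchi(self):
        t = np.linspace(0.1, 500, 40)
        kp = rm.classical_model("korsmeyer-peppas", t, {"k": 0.03, "n": 0.5})
        hg = rm.classical_model("higuchi", t, {"k": 0.03})
        assert np.allclose(kp, hg)

    def test_weibull_at_lambda(self):
        v = rm.classical_model("weibull", 120.0, {"Minf": 0.8, "lam": 120.0, "b": 1.0})
        assert v == pytest.approx(0.8 * (1 - math.exp(-1)))

    def test_hixson_crowell_clips_at_complete_dissolution(self):
        v = rm.classical_model("hixson-crowell", 1e4, {"M0": 0.9, "k": 1 / 400})
        assert v == pytest.approx(0.9)

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            rm.classical_model("zeroth-order", 1.0, {})


class TestFitKink:
    def test_noiseless_recovery_exact(self):
        truth = synth.recovery_kink_params()
        fit = rm.fit_kink(make_kink_curve(truth))
        assert fit.converged
        for name, tv in [
            ("B", truth.B),
            ("a", truth.a),
            ("A_scale", truth.A_scale),
            ("t0", truth.t0),
        ]:
            assert fit.params[name] == pytest.approx(tv, rel=1e-6)

    def test_noisy_recovery_fixed_seed(self):
        truth = synth.recovery_kink_params()
        spec = synth.SyntheticSpec(
            seed=3,
            params={"B": truth.B, "a": truth.a, "A_scale": truth.A_scale, "t0": truth.t0},
        )
        fit = rm.fit_kink(synth.gen_release_curve(spec))
        for name, tv in [("B", truth.B), ("a", truth.a), ("t0", truth.t0)]:
            assert fit.params[name] == pytest.approx(tv, rel=0.05)
        assert fit.params["A_scale"] == pytest.approx(truth.A_scale, rel=0.15)

    def test_constant_curve_rejected(self):
        t = np.arange(10.0)
        with pytest.raises(ValueError):
            rm.fit_kink(rm.ReleaseCurve("c", t, np.full(10, 0.4), units="fraction"))

    def test_too_few_points_rejected(self):
        p = synth.default_kink_params()
        with pytest.raises(ValueError):
            rm.fit_kink(make_kink_curve(p, times=[0, 100, 200, 300]))


class TestFitAllModels:
    def test_higuchi_data_ranks_higuchi_first(self):
        spec = synth.SyntheticSpec(
            seed=0, model_name="higuchi", params=synth.SELF_CONSISTENCY_TRUTH["higuchi"]
        )
        fits = rm.fit_all_models(synth.gen_release_curve(spec))
        assert fits[0].model_name == "higuchi"

    def test_kink_data_outranks_plateau_free_higuchi(self):
        spec = synth.SyntheticSpec(seed=1)  # default kink with plateau
        fits = rm.fit_all_models(synth.gen_release_curve(spec))
        names = [f.model_name for f in fits]
        assert names.index("kink") < names.index("higuchi")

    def test_deterministic_ranking(self, demo_curve):
        r1 = [f.model_name for f in rm.fit_all_models(demo_curve)]
        r2 = [f.model_name for f in rm.fit_all_models(demo_curve)]
        assert r1 == r2

    def test_aicc_ordering_is_sorted(self, demo_curve):
        fits = rm.fit_all_models(demo_curve)
        converged = [f for f in fits if f.converged]
        assert all(a.aicc <= b.aicc for a, b in zip(converged, converged[1:]))


class TestAbsorbancePreprocessing:
    def test_hand_concentration(self):
        cal = rm.CalibrationLine(slope=0.05, intercept=0.0, wavelength_nm=241)
        curve = rm.release_from_absorbance([0.5], cal, bath_volume_mL=1.0)
        assert curve.mean_release[0] == pytest.approx(10.0)

    def test_zero_sample_volume_is_conc_times_bath(self):
        cal = rm.CalibrationLine(slope=0.1)
        curve = rm.release_from_absorbance([0.1, 0.2, 0.3], cal, 50.0, 0.0)
        assert np.allclose(curve.mean_release, [50.0, 100.0, 150.0])

    def test_withdrawal_correction_accumulates(self):
        cal = rm.CalibrationLine(slope=1.0)
        curve = rm.release_from_absorbance([1.0, 1.0], cal, 50.0, 5.0)
        # second draw: 50*1 + 5*1 = 55
        assert curve.mean_release[1] == pytest.approx(55.0)

    def test_all_zero_absorbance(self):
        cal = rm.CalibrationLine(slope=0.05)
        curve = rm.release_from_absorbance([0.0, 0.0], cal, 50.0)
        assert np.all(curve.mean_release == 0.0)

    def test_below_intercept_clipped(self):
        cal = rm.CalibrationLine(slope=0.05, intercept=0.2)
        curve = rm.release_from_absorbance([0.1, 0.3], cal, 50.0)
        assert curve.mean_release[0] == 0.0
        assert curve.mean_release[1] > 0.0

    def test_nondecreasing_for_nondecreasing_conc(self):
        cal = rm.CalibrationLine(slope=0.05)
        curve = rm.release_from_absorbance(np.linspace(0.1, 0.9, 12), cal, 50.0, 2.0)
        assert np.all(np.diff(curve.mean_release) >= 0)


class TestPlateauTime:
    def test_exact_kink_matches_analytic_inversion(self):
        p = synth.default_kink_params()
        t = np.linspace(0.0, 4320.0, 2000)
        curve = rm.ReleaseCurve("k", t, rm.kink_mass(t, p), units="fraction")
        # closed-form inversion of B + a*tanh(a(t-t0)/A) = 0.95*(B+a)
        target = 0.95 * p.plateau
        t_analytic = p.t0 + (p.A_scale / p.a) * math.atanh((target - p.B) / p.a)
        assert rm.plateau_time(curve) == pytest.approx(t_analytic, rel=0.01)

    def test_step_curve(self):
        # linear interpolation inside the jump segment: 4 + 0.76/0.8 = 4.95,
        # converging to the step time 5.0 as sampling densifies
        t = np.arange(10.0)
        y = np.where(t < 5, 0.0, 0.8)
        curve = rm.ReleaseCurve("s", t, y, units="fraction")
        assert rm.plateau_time(curve) == pytest.approx(4.95)

    def test_unbounded_ramp_rejected(self):
        t = np.arange(20.0)
        curve = rm.ReleaseCurve("r", t, 0.5 * t, units="ug_per_ml")
        with pytest.raises(ValueError):
            rm.plateau_time(curve)
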