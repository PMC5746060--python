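"""Simulator unit and property tests: steady-state rates, kobs laws,
closed-form vs ODE equivalence, noise determinism."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import slowbind as sb
from slowbind.simulate import subseed


class TestSteadyRate:
    def test_half_rate_at_Ki_noncompetitive(self, scheme11):
        # for alpha = 1 the denominator doubles exactly at I = Ki
        for S in (1.0, 10.0, 50.0):
            v0 = sb.steady_rate(scheme11, S, 0.0, 1.0)
            v = sb.steady_rate(scheme11, S, scheme11.Ki, 1.0)
            assert v == pytest.approx(0.5 * v0, rel=1e-12)

    def test_michaelis_half_saturation(self, scheme11):
        v = sb.steady_rate(scheme11, scheme11.Km, 0.0, 2.0)
        assert v == pytest.approx(scheme11.kcat * 2.0 / 2.0, rel=1e-12)

    def test_competitive_third_at_Ki_and_Km(self):
        # denominator Km(1+1) + Km = 3 Km -> rate = kcat E0 / 3
        s = sb.KineticScheme(modality="competitive", Ki=45.0, koff=4e-3,
                             Km=10.0, kcat=0.3)
        v = sb.steady_rate(s, 10.0, 45.0, 1.0)
        assert v == pytest.approx(0.3 / 3.0, rel=1e-12)

    def test_rejects_negative_concentrations(self, scheme11):
        with pytest.raises(ValueError):
            sb.steady_rate(scheme11, -1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            sb.steady_rate(scheme11, 1.0, -5.0, 1.0)

    @settings(deadline=None, max_examples=50)
    @given(I1=st.floats(0, 1e4), I2=st.floats(0, 1e4),
           S=st.floats(0.01, 100), modality=st.sampled_from(list(sb.Modality)))
    def test_monotone_in_inhibitor(self, I1, I2, S, modality):
        alpha = 1.0 if modality is sb.Modality.noncompetitive else 2.5
        s = sb.KineticScheme(modality=modality, Ki=50.0, koff=1e-3,
                             Km=10.0, kcat=0.1, alpha=alpha)
        lo, hi = sorted((I1, I2))
        assert sb.steady_rate(s, S, hi, 1.0) <= sb.steady_rate(s, S, lo, 1.0) + 1e-15

    @settings(deadline=None, max_examples=50)
    @given(S1=st.floats(0, 200), S2=st.floats(0, 200), I=st.floats(0, 1e3))
    def test_monotone_in_substrate(self, S1, S2, I, scheme11):
        lo, hi = sorted((S1, S2))
        assert sb.steady_rate(scheme11, hi, I, 1.0) >= sb.steady_rate(scheme11, lo, I, 1.0) - 1e-15


class TestKobsPredict:
    def test_intercept_is_koff(self, scheme10):
        assert sb.kobs_predict(scheme10, 25.0, 0.0) == pytest.approx(scheme10.koff)

    def test_compound10_highest_concentration(self, scheme10):
        # koff + (koff/Ki)*I = 4.2e-3 + (4.2e-3/123)*1333
        assert sb.kobs_predict(scheme10, 25.0, 1333.0) == pytest.approx(4.972e-2, rel=1e-3)

    def test_doubles_at_Ki_noncompetitive(self, scheme10):
        assert sb.kobs_predict(scheme10, 25.0, scheme10.Ki) == pytest.approx(
            2 * scheme10.koff, rel=1e-12)

    def test_affine_in_inhibitor(self, scheme10):
        I = np.linspace(0, 2000, 9)
        k = np.array([sb.kobs_predict(scheme10, 25.0, i) for i in I])
        slope = np.diff(k) / np.diff(I)
        assert np.allclose(slope, slope[0], rtol=1e-12)

    @pytest.mark.parametrize("modality,expected_factor", [
        ("competitive", 1 / (1 + 25.0 / 10.0)),
        ("noncompetitive", 1.0),
        ("uncompetitive", 1 / (1 + 10.0 / 25.0)),
    ])
    def test_substrate_correction_per_modality(self, modality, expected_factor):
        s = sb.KineticScheme(modality=modality, Ki=100.0, koff=2e-3, Km=10.0, kcat=0.1)
        slope = (sb.kobs_predict(s, 25.0, 100.0) - s.koff) / 100.0
        assert slope == pytest.approx(s.kon * expected_factor, rel=1e-12)

    def test_two_step_saturates_at_k5_plus_k6(self):
        s = sb.KineticScheme(Ki=100.0, koff=0.5, Km=10.0, kcat=0.1,
                             two_step=True, k5=0.05, k6=0.001)
        assert sb.kobs_predict(s, 0.0, 1e9) == pytest.approx(0.051, rel=1e-4)

    def test_two_step_requires_constants(self):
        s = sb.KineticScheme(Ki=100.0, koff=2e-3, Km=10.0, kcat=0.1)
        object.__setattr__(s, "two_step", True)  # bypass validation on purpose
        with pytest.raises(ValueError):
            sb.kobs_predict(s, 10.0, 10.0)


class TestClosedFormCurve:
    def test_uninhibited_curve_is_linear(self, scheme10, slow_binding_design):
        c = sb.closed_form_curve(scheme10, slow_binding_design, 0.0)
        t = c.time_min
        slope = sb.steady_rate(scheme10, 25.0, 0.0, 0.5) * slow_binding_design.gain / 1000.0
        assert np.allclose(c.signal_au, slope * t, rtol=1e-12)

    def test_known_quadrature_value(self):
        # dP/dt = vs + (vi - vs) e^{-kobs t}; vi=2, vs=0.5, kobs=0.05, t=60
        P = sb.product_progress(np.array([60.0]), 2.0, 0.5, 0.05)[0]
        assert P == pytest.approx(30 + 30 * (1 - np.exp(-3)), rel=1e-12)
        assert P == pytest.approx(58.51, abs=0.01)

    def test_kobs_to_zero_limit(self):
        t = np.linspace(0, 120, 50)
        P = sb.product_progress(t, 2.0, 0.5, 1e-8)
        assert np.allclose(P[1:], 2.0 * t[1:], rtol=1e-4)

    def test_signal_starts_at_baseline_and_is_nondecreasing(self, scheme10):
        d = sb.AssayDesign(E0=0.5, S0=25.0, I_grid=(0.0, 100.0),
                           t_grid=np.arange(0.0, 121.0, 1.0), baseline=7.5)
        c = sb.closed_form_curve(scheme10, d, 100.0)
        assert c.signal_au[0] == pytest.approx(7.5)
        assert np.all(np.diff(c.signal_au) >= 0)

    def test_depletion_flag(self):
        fast = sb.KineticScheme(Ki=123.0, koff=4.2e-3, Km=10.0, kcat=100.0)
        d = sb.AssayDesign(E0=5.0, S0=2.0, I_grid=(0.0,),
                           t_grid=np.arange(0.0, 121.0, 1.0))
        with pytest.warns(UserWarning, match="conversion"):
            c = sb.closed_form_curve(fast, d, 0.0)
        assert c.meta.get("depletion_warning")

    def test_preincubation_lowers_vi(self, scheme10, slow_binding_design):
        pre = slow_binding_design.model_copy(update={"preincubation_min": 60.0})
        c0 = sb.closed_form_curve(scheme10, slow_binding_design, 500.0)
        c1 = sb.closed_form_curve(scheme10, pre, 500.0)
        assert c1.meta["vi_nM_min"] < c0.meta["vi_nM_min"]
        # preincubated vi approaches vs as incubation -> equilibrium
        assert c1.meta["vi_nM_min"] >= c1.meta["vs_nM_min"] - 1e-12


class TestOdeCurve:
    def test_uninhibited_matches_linear_rate(self, scheme10, slow_binding_design):
        c = sb.ode_curve(scheme10, slow_binding_design, 0.0)
        v = sb.steady_rate(scheme10, 25.0, 0.0, 0.5) * slow_binding_design.gain / 1000.0
        expect = v * c.time_min
        assert np.allclose(c.signal_au[1:], expect[1:], rtol=1e-2)

    def test_matches_closed_form_at_highest_inhibitor(self, scheme10, slow_binding_design):
        cf = sb.closed_form_curve(scheme10, slow_binding_design, 1333.0)
        od = sb.ode_curve(scheme10, slow_binding_design, 1333.0)
        dev = np.max(np.abs(cf.signal_au - od.signal_au)) / od.signal_au[-1]
        assert dev < 0.01

    def test_family_equivalence_under_low_conversion(self, scheme10, slow_binding_design):
        for I in slow_binding_design.I_grid:
            cf = sb.closed_form_curve(scheme10, slow_binding_design, I)
            od = sb.ode_curve(scheme10, slow_binding_design, I)
            denom = max(od.signal_au[-1], 1e-12)
            assert np.max(np.abs(cf.signal_au - od.signal_au)) / denom < 0.01

    def test_two_step_with_k5_zero_reduces_to_one_step(self, slow_binding_design):
        one = sb.KineticScheme(Ki=123.0, koff=4.2e-3, Km=10.0, kcat=0.1)
        two = sb.KineticScheme(Ki=123.0, koff=4.2e-3, Km=10.0, kcat=0.1,
                               two_step=True, k5=0.0, k6=0.0)
        c1 = sb.ode_curve(one, slow_binding_design, 444.0)
        c2 = sb.ode_curve(two, slow_binding_design, 444.0)
        assert np.allclose(c1.signal_au, c2.signal_au, rtol=1e-9, atol=1e-9)


class TestNoise:
    def test_zero_noise_is_identity(self, scheme10, slow_binding_design):
        c = sb.closed_form_curve(scheme10, slow_binding_design, 100.0)
        assert sb.add_noise(c, sb.NoiseModel()) is c

    def test_fixed_seed_is_bit_identical(self, scheme10, slow_binding_design, noise2pct):
        a = sb.simulate_experiment(scheme10, slow_binding_design, noise2pct)
        b = sb.simulate_experiment(scheme10, slow_binding_design, noise2pct)
        for x, y in zip(a, b):
            assert np.array_equal(x.signal_au, y.signal_au)

    def test_subseed_depends_on_curve_id_and_seed(self):
        assert subseed(1, "a") != subseed(1, "b")
        assert subseed(1, "a") != subseed(2, "a")
        assert subseed(1, "a") == subseed(1, "a")

    def test_absolute_noise_sd(self):
        t = np.arange(0.0, 1e4)
        clean = sb.ProgressCurve("sd_check", t, np.full(t.size, 50.0), 0.0, 10.0, 1.0)
        noisy = sb.add_noise(clean, sb.NoiseModel(sigma_abs=1.0, seed=3))
        sd = np.std(noisy.signal_au - clean.signal_au)
        assert 0.95 < sd < 1.05


class TestSimulateExperiment:
    def test_monotone_family(self, scheme10, slow_binding_design):
        curves = sb.simulate_experiment(scheme10, slow_binding_design)
        finals = {c.inhibitor_nM: c.signal_au[-1] for c in curves}
        I_sorted = sorted(finals)
        vals = [finals[i] for i in I_sorted]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_provenance_records_simulator(self, scheme10, slow_binding_design):
        for sim in ("closed_form", "ode"):
            c = sb.simulate_experiment(scheme10, slow_binding_design, simulator=sim)[0]
            assert c.meta["simulator"].startswith(sim)
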