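"""RC-circuit capacitance estimation: model algebra, fitting, leakage rule.

Oracles: closed-form limits of the charging current, the exact identity
tau = R_m R_s C_m / (R_m + R_s), and the closed-form charge integral
C_Q = C_m (R_m / (R_m + R_s))^2.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr

from lipodeform import capacitance as cap
from lipodeform import synthetic
from lipodeform.capacitance import (
    CapacitanceSeries,
    PlateModel,
    PulseSegmentationError,
    PulseTransient,
    capacitance_from_charge,
    find_time_zero,
    fit_transient,
    infer_relative_permittivity,
    normalized_capacitance,
    parallel_plate_capacitance,
    rc_current,
    segment_pulses,
    time_constant,
)


def make_trace(**kw):
    kw.setdefault("duration_s", 0.02)
    kw.setdefault("C_m", 50e-12)
    kw.setdefault("R_m", 1e9)
    kw.setdefault("R_s", 1e6)
    kw.setdefault("noise_sd", 0.0)
    scn = synthetic.TraceScenario(**kw)
    trace, truth = synthetic.simulate_capacitance_trace(scn)
    return trace.time_s.to_numpy(), trace.current_A.to_numpy(), truth


class TestRcModel:
    def test_onset_current_is_v_over_rs(self):
        assert rc_current(0.0, 5e-3, 1e9, 1e6, 50e-12) == pytest.approx(
            5e-9, rel=1e-12)

    def test_long_time_limit_is_ohmic(self):
        assert rc_current(1.0, 5e-3, 1e9, 1e6, 50e-12) == pytest.approx(
            5e-3 / (1e9 + 1e6), rel=1e-9)

    def test_nonpositive_parameters_raise(self):
        with pytest.raises(ValueError):
            rc_current(0.0, 5e-3, -1e9, 1e6, 50e-12)

    def test_time_constant_printed_example(self):
        tau_exact, tau_approx = time_constant(1e9, 1e6, 100e-12)
        assert tau_exact == pytest.approx(99.9e-6, rel=1e-4)
        assert tau_approx == pytest.approx(100e-6, rel=1e-12)

    def test_equal_resistances_halve_the_approximation(self):
        tau_exact, tau_approx = time_constant(1e6, 1e6, 50e-12)
        assert tau_exact == pytest.approx(tau_approx / 2, rel=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(rm=st.floats(1e6, 1e12), rs=st.floats(1e4, 1e8),
           cm=st.floats(1e-13, 1e-9))
    def test_approximation_gap_is_exactly_rs_over_rm_plus_rs(self, rm, rs, cm):
        tau_exact, tau_approx = time_constant(rm, rs, cm)
        gap = (tau_approx - tau_exact) / tau_approx
        assert gap == pytest.approx(rs / (rm + rs), rel=1e-9)


class TestSegmentPulses:
    def test_pulse_count(self):
        t, I, _ = make_trace(duration_s=0.05)
        assert len(segment_pulses(t, I, 1000.0, 5e-3)) == 50

    def test_trace_shorter_than_one_period_raises(self):
        t = np.arange(100) / 500_000.0
        with pytest.raises(PulseSegmentationError):
            segment_pulses(t, np.ones(100), 1000.0, 5e-3)

    def test_low_sample_rate_raises(self):
        t = np.arange(1000) / 10_000.0
        with pytest.raises(PulseSegmentationError):
            segment_pulses(t, np.ones(1000), 1000.0, 5e-3)

    def test_noiseless_onset_is_each_pulse_maximum(self):
        t, I, _ = make_trace(duration_s=0.01)
        for tr in segment_pulses(t, I, 1000.0, 5e-3):
            assert tr.current_A[0] == pytest.approx(tr.current_A.max())


class TestFitTransient:
    def test_noiseless_tau_recovered_to_0p1_percent(self):
        t, I, truth = make_trace()
        tr = segment_pulses(t, I, 1000.0, 5e-3)[0]
        fit = fit_transient(tr)
        assert fit.valid
        assert fit.tau_s == pytest.approx(truth.tau_s[0], rel=1e-3)
        assert fit.I_peak == pytest.approx(5e-9, rel=1e-3)

    def test_pure_dc_segment_is_invalid(self):
        tr = PulseTransient(time_s=np.arange(50) * 2e-6,
                            current_A=np.full(50, 1e-9), V=5e-3)
        assert not fit_transient(tr).valid

    def test_noisy_tau_within_5_percent(self):
        # 1% of peak current noise, 250 samples per transient
        t, I, truth = make_trace(duration_s=0.05, noise_sd=5e-11, seed=13)
        fits = [fit_transient(tr) for tr in segment_pulses(t, I, 1000.0, 5e-3)]
        errs = [abs(f.tau_s / truth.tau_s[i] - 1)
                for i, f in enumerate(fits) if f.valid]
        assert np.median(errs) < 0.05

    def test_fixed_series_resistance_option(self):
        t, I, _ = make_trace()
        tr = segment_pulses(t, I, 1000.0, 5e-3)[0]
        fit = fit_transient(tr, R_s_fixed=1e6)
        assert fit.R_s_est == 1e6
        assert fit.C_tau == pytest.approx(fit.tau_s / 1e6, rel=1e-12)


class TestChargeCapacitance:
    def test_closed_form_charge_integral(self):
        # C_Q -> C_m (R_m / (R_m + R_s))^2 for a long noiseless window
        t, I, _ = make_trace(C_m=30e-12)   # window ~ 16 tau
        tr = segment_pulses(t, I, 1000.0, 5e-3)[0]
        fit = fit_transient(tr)
        expected = 30e-12 * (1e9 / (1e9 + 1e6)) ** 2
        assert fit.C_Q == pytest.approx(expected, rel=2e-3)

    def test_high_rm_rs_ratio_approaches_true_cm(self):
        t, I, _ = make_trace(C_m=30e-12)
        fit = fit_transient(segment_pulses(t, I, 1000.0, 5e-3)[0])
        assert fit.C_Q == pytest.approx(30e-12, rel=2.5e-3)

    def test_negative_charge_flags_fit_invalid(self):
        tr = PulseTransient(time_s=np.arange(50) * 2e-6,
                            current_A=np.linspace(1e-9, 5e-9, 50), V=5e-3)
        fit = fit_transient(tr)
        fit.I_ss = 1e-8   # above the whole trace -> negative integral
        fit.valid = True
        cq = capacitance_from_charge(tr, fit)
        assert cq < 0 and not fit.valid


class TestTimeZero:
    def test_concordant_from_start_returns_zero(self):
        c = np.full(30, 50e-12)
        assert find_time_zero(c, c * 1.001) == 0

    def test_programmed_leak_prefix_is_excluded(self):
        scn = synthetic.control_trace_scenario(
            n_pulses=100, leak_pulses=20, C_start=60e-12, C_plateau=60e-12,
            seed=17)
        trace, truth = synthetic.simulate_capacitance_trace(scn)
        series = cap.analyze_trace(trace.time_s.to_numpy(),
                                   trace.current_A.to_numpy(), 5e-3, 1000.0)
        assert 20 <= series.time_zero <= 30
        assert not series.valid[:series.time_zero].any()

    def test_permanently_leaky_trace_raises(self):
        # R_m / R_s = 10 throughout: C_Q / C_tau = 10/11 stays discordant
        t, I, _ = make_trace(duration_s=0.05, R_m=1e7)
        with pytest.raises(ValueError, match="leakage-free"):
            cap.analyze_trace(t, I, 5e-3, 1000.0)

    def test_too_few_pulses_raises(self):
        with pytest.raises(ValueError):
            find_time_zero(np.ones(5), np.ones(5))


class TestNormalizedCapacitance:
    def _series(self, c_pF):
        c = np.asarray(c_pF, dtype=float) * 1e-12
        return CapacitanceSeries(time_s=np.arange(c.size) * 1e-3, C_m=c,
                                 C_Q=c.copy(), valid=np.ones(c.size, bool))

    def test_ratio_of_max_to_initial(self):
        s = normalized_capacitance(self._series([40] * 10 + [60, 84]),
                                   min_window=5)
        assert s.C_nor == pytest.approx(2.1)

    def test_constant_series_is_unity(self):
        s = normalized_capacitance(self._series([50] * 20), min_window=5)
        assert s.C_nor == pytest.approx(1.0)

    def test_ceiling_truncates_the_valid_series(self):
        s = normalized_capacitance(self._series([40] * 10 + [60, 84]),
                                   min_window=5, C_ceiling=70e-12)
        assert s.C_nor == pytest.approx(1.5)

    def test_gain_invariance_of_c_nor(self):
        scn = synthetic.binding_trace_scenario(n_pulses=60, seed=19)
        trace, _ = synthetic.simulate_capacitance_trace(scn)
        t = trace.time_s.to_numpy()
        I = trace.current_A.to_numpy()
        a = cap.analyze_trace(t, I, 5e-3, 1000.0)
        b = cap.analyze_trace(t, 2.7 * I, 5e-3, 1000.0)
        assert b.C_nor == pytest.approx(a.C_nor, rel=1e-9)

    def test_binding_preset_exceeds_control_preset(self):
        c_nor = {}
        for name, factory in (("control", synthetic.control_trace_scenario),
                              ("binding", synthetic.binding_trace_scenario)):
            scn = factory(n_pulses=150, seed=23)
            trace, _ = synthetic.simulate_capacitance_trace(scn)
            series = cap.analyze_trace(trace.time_s.to_numpy(),
                                       trace.current_A.to_numpy(), 5e-3, 1000.0)
            c_nor[name] = series.C_nor
        assert c_nor["binding"] > c_nor["control"]


class TestScheduleRecovery:
    def test_rising_schedule_recovered_in_level_and_shape(self):
        scn = synthetic.binding_trace_scenario(n_pulses=100, seed=29)
        trace, truth = synthetic.simulate_capacitance_trace(scn)
        series = cap.analyze_trace(trace.time_s.to_numpy(),
                                   trace.current_A.to_numpy(), 5e-3, 1000.0)
        v = series.valid
        errs = np.abs(series.C_m[v] / truth.C_m_F.to_numpy()[v] - 1)
        assert np.median(errs) < 0.05
        rho = spearmanr(series.C_m[v], truth.C_m_F.to_numpy()[v]).statistic
        assert rho > 0.95


class TestPlateModel:
    def test_printed_example(self):
        model = PlateModel(eps_r=3.0, area_m2=np.pi * (50e-6) ** 2,
                           thickness_m=5e-9)
        assert parallel_plate_capacitance(model) == pytest.approx(
            41.7e-12, rel=1e-3)

    def test_forward_inverse_round_trip(self):
        model = PlateModel(eps_r=3.0, area_m2=1e-8, thickness_m=5e-9)
        c = parallel_plate_capacitance(model)
        assert infer_relative_permittivity(c, 1e-8, 5e-9) == pytest.approx(
            3.0, rel=1e-12)

    def test_linearity_in_area(self):
        m1 = PlateModel(eps_r=2.5, area_m2=1e-8, thickness_m=5e-9)
        m2 = PlateModel(eps_r=2.5, area_m2=2e-8, thickness_m=5e-9)
        assert parallel_plate_capacitance(m2) == pytest.approx(
            2 * parallel_plate_capacitance(m1), rel=1e-12)

    def test_invalid_geometry_raises(self):
        with pytest.raises(ValueError):
            PlateModel(eps_r=3.0, area_m2=1e-8, thickness_m=0.0)
        with pytest.raises(ValueError):
            infer_relative_permittivity(4e-11, -1e-8, 5e-9)
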