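"""Generator contracts: boundary shape model, rasterization, trace physics."""

import numpy as np
import pytest

from lipodeform import shape, synthetic
from lipodeform.synthetic import (
    LiposomeAbsentError,
    ScenarioError,
    ShapeScenario,
    TraceScenario,
    radial_boundary,
    render_frame,
    simulate_capacitance_trace,
    simulate_timelapse,
)


def _scenario(**kw):
    kw.setdefault("n_liposomes", 1)
    kw.setdefault("n_frames", 1)
    kw.setdefault("addition_frame", 0)
    kw.setdefault("center_jitter_px", 0.0)
    return ShapeScenario(**kw)


def _radii(poly, center):
    return np.hypot(poly[:, 0] - center[0], poly[:, 1] - center[1])


class TestRadialBoundary:
    def test_circle_has_constant_radius(self):
        scn = _scenario(radius_px=30)
        poly = radial_boundary(scn, 0, 0)
        r = _radii(poly, scn.centers[0])
        np.testing.assert_allclose(r, 30.0, rtol=1e-9)

    def test_ellipse_diameter_ratio_matches_axis_ratio(self):
        scn = _scenario(ellipticity=1.5)
        poly = radial_boundary(scn, 0, 0)
        r = _radii(poly, scn.centers[0])
        assert r.max() / r.min() == pytest.approx(1.5, abs=0.01)

    def test_third_mode_radius_at_known_angles(self):
        # r(theta) = R0 (1 + 0.1 cos 3 theta): 1.1 R0 at 0, 0.9 R0 at pi/3
        scn = _scenario(radius_px=30, mode_amps=[(3, 0.1, 0.0)])
        poly = radial_boundary(scn, 0, 0, n_samples=720)
        r = _radii(poly, scn.centers[0])
        assert r[0] == pytest.approx(33.0, abs=1e-9)
        assert r[120] == pytest.approx(27.0, abs=1e-9)  # theta = pi/3

    @pytest.mark.parametrize("scale", [0.8, 1.0, 1.44])
    def test_enclosed_area_scales_linearly_with_area_scale(self, scale):
        scn = _scenario(radius_px=30, area_scale=scale)
        poly = radial_boundary(scn, 0, 0)
        area = synthetic._shoelace_area(poly)
        assert area == pytest.approx(np.pi * 30 ** 2 * scale, rel=0.01)

    def test_phase_rotation_preserves_radius_extrema_and_area(self):
        base = _scenario(mode_amps=[(3, 0.15, 0.0)])
        rot = _scenario(mode_amps=[(3, 0.15, 0.9)])
        p0 = radial_boundary(base, 0, 0, 3600)
        p1 = radial_boundary(rot, 0, 0, 3600)
        r0 = _radii(p0, base.centers[0])
        r1 = _radii(p1, rot.centers[0])
        assert r0.max() == pytest.approx(r1.max(), rel=1e-4)
        assert r0.min() == pytest.approx(r1.min(), rel=1e-4)
        assert synthetic._shoelace_area(p0) == pytest.approx(
            synthetic._shoelace_area(p1), rel=1e-6)

    def test_ruptured_liposome_is_absent(self):
        scn = _scenario(n_frames=10, addition_frame=2, rupture_frames=[5])
        radial_boundary(scn, 4, 0)
        with pytest.raises(LiposomeAbsentError):
            radial_boundary(scn, 5, 0)

    def test_scenario_validation_errors(self):
        with pytest.raises(ScenarioError):
            _scenario(mode_amps=[(3, 0.6, 0.0)])       # not star-convex
        with pytest.raises(ScenarioError):
            _scenario(ellipticity=0.8)
        with pytest.raises(ScenarioError):
            _scenario(n_frames=10, addition_frame=4, rupture_frames=[3])
        with pytest.raises(ScenarioError):
            _scenario(area_scale=-1.0)


class TestRenderFrame:
    def test_empty_boundary_list_gives_no_segmentable_object(self):
        img = render_frame([], (128, 128), rng=np.random.default_rng(0))
        assert shape.segment_all(img) == []

    def test_noiseless_unblurred_circle_thresholds_to_programmed_area(self):
        scn = _scenario(radius_px=30, psf_sigma_px=0.0,
                        poisson_noise=False, read_noise_sd=0.0)
        stack, truth = simulate_timelapse(scn)
        obj = shape.segment_frame(stack[0])
        assert obj.area_px == pytest.approx(truth.true_area[0], rel=0.02)

    def test_interior_intensity_well_above_background_noise(self):
        scn = _scenario(radius_px=30, seed=7)
        stack, _ = simulate_timelapse(scn)
        img = stack[0]
        yy, xx = np.mgrid[:img.shape[0], :img.shape[1]]
        cy, cx = scn.centers[0]
        inside = np.hypot(yy - cy, xx - cx) < 25
        bg = np.hypot(yy - cy, xx - cx) > 60
        assert img[inside].mean() - img[bg].mean() >= 3 * img[bg].std()

    def test_out_of_frame_boundary_warns_and_clips(self):
        poly = np.column_stack([20 + 30 * np.sin(np.linspace(0, 2 * np.pi, 360)),
                                20 + 30 * np.cos(np.linspace(0, 2 * np.pi, 360))])
        with pytest.warns(UserWarning, match="clip"):
            img = render_frame([poly], (128, 128))
        assert img.shape == (128, 128)

    def test_same_seed_gives_bit_identical_stacks(self):
        scn1 = _scenario(n_frames=3, seed=42)
        scn2 = _scenario(n_frames=3, seed=42)
        s1, _ = simulate_timelapse(scn1)
        s2, _ = simulate_timelapse(scn2)
        assert np.array_equal(s1, s2)


class TestSimulateTimelapse:
    def test_rupture_bookkeeping_counts_disappearances(self):
        rupture_frames = [6 + (i % 10) for i in range(17)] + [None] * 3
        scn = ShapeScenario(n_liposomes=20, n_frames=20, addition_frame=4,
                            image_shape=(512, 512), radius_px=30,
                            rupture_frames=rupture_frames, seed=1)
        _, truth = simulate_timelapse(scn)
        disappeared = truth.groupby("liposome")["ruptured"].any()
        assert int(disappeared.sum()) == 17
        # ruptured liposomes are absent from every frame >= rupture_frame
        for i, rf in enumerate(rupture_frames):
            if rf is None:
                continue
            sub = truth[truth.liposome == i]
            assert (sub[sub.frame >= rf].ruptured).all()
            assert not (sub[sub.frame < rf].ruptured).any()

    def test_control_preset_true_ar_is_one(self):
        scn = synthetic.control_shape_scenario(n_liposomes=2, n_frames=6,
                                               image_shape=(256, 512), seed=2)
        _, truth = simulate_timelapse(scn)
        np.testing.assert_array_equal(truth.true_ar, 1.0)

    def test_distortion_preset_true_ar_peaks_as_programmed(self):
        scn = synthetic.distortion_shape_scenario(
            peak_ellipticity=1.3, n_frames=20, addition_frame=4, seed=3)
        _, truth = simulate_timelapse(scn)
        peak_frame = int(truth.true_ar.idxmax())
        assert truth.true_ar.max() == pytest.approx(1.3, abs=1e-12)
        assert truth.frame[peak_frame] == 4 + (20 - 4) // 2


class TestSimulateTrace:
    def test_noiseless_trace_matches_rc_law_pointwise(self):
        scn = TraceScenario(duration_s=0.005, C_m=50e-12, R_m=1e9, R_s=1e6,
                            noise_sd=0.0)
        trace, truth = simulate_capacitance_trace(scn)
        t = trace.time_s.to_numpy()
        I = trace.current_A.to_numpy()
        n_period = 500
        tau = 1e9 * 1e6 * 50e-12 / (1e9 + 1e6)
        for p in range(scn.n_pulses):
            tl = t[p * n_period:p * n_period + 250] - p / 1000.0
            expected = 5e-3 / (1e9 + 1e6) * (1 + (1e9 / 1e6) * np.exp(-tl / tau))
            got = I[p * n_period:p * n_period + 250]
            np.testing.assert_allclose(got, expected, rtol=1e-12)
        np.testing.assert_allclose(truth.tau_s, tau, rtol=1e-12)

    def test_onset_current_and_late_current_limits(self):
        scn = TraceScenario(duration_s=0.002, C_m=30e-12, R_m=1e9, R_s=1e6,
                            noise_sd=0.0)
        trace, _ = simulate_capacitance_trace(scn)
        I = trace.current_A.to_numpy()
        assert I[0] == pytest.approx(5e-3 / 1e6, rel=1e-12)        # V / R_s
        assert I[249] == pytest.approx(5e-3 / (1e9 + 1e6), rel=1e-4)

    def test_truth_time_constant_exact_vs_approx(self):
        # R_m = 1 GOhm, R_s = 1 MOhm, C_m = 100 pF: tau 99.9 us vs 100 us
        scn = TraceScenario(duration_s=0.002, C_m=100e-12, R_m=1e9, R_s=1e6,
                            noise_sd=0.0)
        _, truth = simulate_capacitance_trace(scn)
        assert truth.tau_s[0] == pytest.approx(99.9e-6, rel=1e-4)
        assert 1e6 * 100e-12 == pytest.approx(100e-6, rel=1e-12)

    def test_sample_rate_validation(self):
        with pytest.raises(ScenarioError):
            simulate_capacitance_trace(
                TraceScenario(duration_s=0.01, sample_rate_hz=10_000.0))

    def test_seeded_trace_is_reproducible(self):
        a, _ = simulate_capacitance_trace(
            TraceScenario(duration_s=0.005, noise_sd=5e-11, seed=9))
        b, _ = simulate_capacitance_trace(
            TraceScenario(duration_s=0.005, noise_sd=5e-11, seed=9))
        assert np.array_equal(a.current_A.to_numpy(), b.current_A.to_numpy())
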