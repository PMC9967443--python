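"""Shared fixtures: rendered scenarios are session-scoped because the
cohort renders (512x512 stacks) dominate suite runtime."""

import numpy as np
import pytest

from lipodeform import pipeline, synthetic


def render_single(ellipticity=1.0, mode_amps=(), orientation_deg=0.0,
                  noiseless=True, radius_px=30.0, seed=1, **kw):
    """One-frame, one-liposome scenario -> (frame, truth row, scenario)."""
    params = dict(
        n_liposomes=1, n_frames=1, addition_frame=0, radius_px=radius_px,
        ellipticity=ellipticity, mode_amps=list(mode_amps),
        orientation_rad=np.array([np.deg2rad(orientation_deg)]),
        center_jitter_px=0.0, seed=seed, **kw)
    if noiseless:
        params.setdefault("poisson_noise", False)
        params.setdefault("read_noise_sd", 0.0)
    scn = synthetic.ShapeScenario(**params)
    stack, truth = synthetic.simulate_timelapse(scn)
    return stack[0], truth.iloc[0], scn


@pytest.fixture(scope="session")
def rupture_cohort():
    """20 liposomes, 17 programmed ruptures uniformly in minutes 2-25 after
    addition, default noise, 30-min post-addition window."""
    scn = synthetic.rupture_shape_scenario(seed=11)
    stack, truth = synthetic.simulate_timelapse(scn)
    tracks = pipeline.analyze_stack(stack, scn.addition_frame,
                                    frame_interval_s=scn.frame_interval_s)
    return scn, stack, truth, tracks


@pytest.fixture(scope="session")
def distortion_cohort():
    """20 liposomes, 30 frames, default noise; per-liposome gains place peak
    AR and peak dA at 1.0 / 1.06 / 1.2 / 1.3 in groups of five."""
    gains = np.repeat([0.0, 0.2, 0.67, 1.0], 5)
    scn = synthetic.distortion_shape_scenario(
        n_liposomes=20, peak_ellipticity=1.3, peak_area_scale=1.3,
        n_frames=30, addition_frame=4, shape_gain=gains,
        image_shape=(512, 512), seed=21)
    stack, truth = synthetic.simulate_timelapse(scn)
    tracks = pipeline.analyze_stack(stack, scn.addition_frame,
                                    frame_interval_s=scn.frame_interval_s)
    return scn, stack, truth, tracks


def match_track_to_liposome(track, scenario):
    """Map a track back to the generator liposome by its first centroid."""
    f0 = next(f for f in range(track.n_frames) if track.objects[f] is not None)
    c = np.asarray(track.objects[f0].centroid)
    return int(np.argmin(np.hypot(*(scenario.centers - c).T)))
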