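"""Seeded synthetic recordings with exhaustive ground truth.

Two generators stand in for the study's raw data:

* a fluorescence time-lapse of cell-sized liposomes (bright membrane-dye ring
  around a dimmer lumen), with programmed ellipticity, radial Fourier-mode
  distortion, area drift and rupture (abrupt disappearance) per liposome; and
* a square-pulse current trace from an RC bilayer circuit with a per-pulse
  schedule of membrane capacitance and resistance ("control" preset: rise to
  a plateau; "binding" preset: continuous rise; optional leaky prefix).

Every programmed quantity is returned as a tidy ground-truth table so that
each analysis stage can be tested as a parameter-recovery problem.

Boundary shape model, radius from the centroid at angle theta:

    r(theta) = R0 * sqrt(area_scale) * s(theta) * (1 + sum_k a_k cos(k theta + phi_k))

where ``s`` is the equal-area radial factor of an ellipse with axis ratio
``e`` (``s = 1 / sqrt(cos^2/e + e sin^2)``, max/min radius ratio exactly
``e``), and the Fourier term adds contour ripple (star-convex for
``sum |a_k| < 0.5``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon2mask

from .capacitance import rc_current, time_constant

__all__ = [
    "ScenarioError",
    "ShapeScenario",
    "TraceScenario",
    "radial_boundary",
    "render_frame",
    "simulate_timelapse",
    "simulate_capacitance_trace",
    "control_shape_scenario",
    "distortion_shape_scenario",
    "rupture_shape_scenario",
    "control_trace_scenario",
    "binding_trace_scenario",
]


class ScenarioError(ValueError):
    """Raised for invalid generator parameterizations."""


class LiposomeAbsentError(LookupError):
    """Requested the boundary of a liposome after its rupture frame."""


def _per_frame(value, n_frames, name):
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n_frames,)).copy()
    if not np.all(np.isfinite(arr)):
        raise ScenarioError(f"{name} must be finite")
    return arr


def _default_centers(n, image_shape, radius_px):
    """Liposome centers on a regular grid with margin; errors if they cannot
    fit without touching."""
    h, w = image_shape
    n_cols = int(math.ceil(math.sqrt(n * w / h)))
    n_rows = int(math.ceil(n / n_cols))
    margin = 1.6 * radius_px
    if n_cols > 1:
        xs = np.linspace(margin, w - 1 - margin, n_cols)
    else:
        xs = np.array([(w - 1) / 2.0])
    if n_rows > 1:
        ys = np.linspace(margin, h - 1 - margin, n_rows)
    else:
        ys = np.array([(h - 1) / 2.0])
    spacing = min(np.diff(xs).min(initial=np.inf), np.diff(ys).min(initial=np.inf))
    if spacing < 2.6 * radius_px:
        raise ScenarioError(
            f"{n} liposomes of radius {radius_px} px do not fit in a "
            f"{image_shape} frame without overlap"
        )
    centers = [(y, x) for y in ys for x in xs]
    return np.asarray(centers[:n], dtype=float)


# ----------------------------------------------------------------------------
# Image scenario
# ----------------------------------------------------------------------------

@dataclass
class ShapeScenario:
    """Programmed time-lapse of fluorescent liposome cross-sections.

    Shape schedules (``ellipticity``, ``area_scale``, ``mode_schedule``) are
    per-frame and shared by the cohort; ``shape_gain`` scales each liposome's
    departure from a circle so cohorts mix deforming and quiescent members.
    ``rupture_frames`` holds the first absent frame per liposome (None = never).
    Default geometry: 256x256 px frames, 0.1 um/px, radius 30 px (~6 um
    diameter liposomes).
    """

    n_liposomes: int = 1
    n_frames: int = 30
    addition_frame: int = 4
    radius_px: float = 30.0
    frame_interval_s: float = 30.0
    image_shape: tuple = (256, 256)
    centers: np.ndarray | None = None               # (n, 2) row, col
    ellipticity: float | np.ndarray = 1.0           # per-frame a/b >= 1
    mode_amps: list = field(default_factory=list)   # [(k, a_k, phi_k), ...]
    mode_schedule: float | np.ndarray = 1.0         # per-frame multiplier on a_k
    area_scale: float | np.ndarray = 1.0            # per-frame area multiplier
    shape_gain: np.ndarray | None = None            # per-liposome gain
    orientation_rad: np.ndarray | None = None       # per-liposome ellipse tilt
    rupture_frames: list = None                     # per-liposome int or None
    center_jitter_px: float = 1.0
    # imaging / noise model
    background: float = 10.0
    signal: float = 120.0
    lumen_frac: float = 0.45
    ring_width_px: float = 1.0
    ring_offset_px: float = 3.0
    psf_sigma_px: float = 1.0
    read_noise_sd: float = 3.0
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self):
        self.image_shape = tuple(int(v) for v in self.image_shape)
        if self.centers is None:
            self.centers = _default_centers(self.n_liposomes, self.image_shape,
                                            self.radius_px)
        self.centers = np.asarray(self.centers, dtype=float)
        if self.rupture_frames is None:
            self.rupture_frames = [None] * self.n_liposomes
        if self.shape_gain is None:
            self.shape_gain = np.ones(self.n_liposomes)
        self.shape_gain = np.asarray(self.shape_gain, dtype=float)
        if self.orientation_rad is None:
            self.orientation_rad = np.zeros(self.n_liposomes)
        self.orientation_rad = np.asarray(self.orientation_rad, dtype=float)
        self.validate()

    def validate(self):
        if self.n_liposomes < 1 or self.n_frames < 1:
            raise ScenarioError("need at least one liposome and one frame")
        if not (0 <= self.addition_frame < self.n_frames):
            raise ScenarioError("addition_frame must lie inside the stack")
        if self.centers.shape != (self.n_liposomes, 2):
            raise ScenarioError("centers must be (n_liposomes, 2)")
        e = _per_frame(self.ellipticity, self.n_frames, "ellipticity")
        if np.any(e < 1):
            raise ScenarioError("ellipticity must be >= 1")
        a = _per_frame(self.area_scale, self.n_frames, "area_scale")
        if np.any(a <= 0):
            raise ScenarioError("area_scale must be positive")
        sched = _per_frame(self.mode_schedule, self.n_frames, "mode_schedule")
        amp_sum = sum(abs(a_k) for _, a_k, _ in self.mode_amps)
        if amp_sum * max(1.0, np.max(np.abs(sched)) if sched.size else 1.0) \
                * max(1.0, np.max(np.abs(self.shape_gain))) >= 0.5:
            raise ScenarioError("sum |a_k| must stay below 0.5 (star-convexity)")
        if len(self.rupture_frames) != self.n_liposomes:
            raise ScenarioError("rupture_frames must have one entry per liposome")
        for rf in self.rupture_frames:
            if rf is not None and rf <= self.addition_frame:
                raise ScenarioError("rupture_frame must come after addition_frame")

    # per-frame schedules, broadcast once
    def frame_ellipticity(self):
        return _per_frame(self.ellipticity, self.n_frames, "ellipticity")

    def frame_area_scale(self):
        return _per_frame(self.area_scale, self.n_frames, "area_scale")

    def frame_mode_schedule(self):
        return _per_frame(self.mode_schedule, self.n_frames, "mode_schedule")

    def liposome_ellipticity(self, frame, liposome):
        e = self.frame_ellipticity()[frame]
        return 1.0 + self.shape_gain[liposome] * (e - 1.0)

    def is_ruptured(self, frame, liposome):
        rf = self.rupture_frames[liposome]
        return rf is not None and frame >= rf

    def jittered_center(self, frame, liposome):
        if self.center_jitter_px == 0:
            return self.centers[liposome]
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed & 0x7FFFFFFF, 101, frame, liposome]))
        return self.centers[liposome] + rng.normal(0, self.center_jitter_px, 2)

    def to_dict(self):
        d = asdict(self)
        d["centers"] = self.centers.tolist()
        d["shape_gain"] = self.shape_gain.tolist()
        d["orientation_rad"] = self.orientation_rad.tolist()
        for key in ("ellipticity", "area_scale", "mode_schedule"):
            v = d[key]
            d[key] = v.tolist() if isinstance(v, np.ndarray) else v
        d["mode_amps"] = [list(m) for m in self.mode_amps]
        d["image_shape"] = list(self.image_shape)
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        for key in ("centers", "shape_gain", "orientation_rad"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], dtype=float)
        for key in ("ellipticity", "area_scale", "mode_schedule"):
            if isinstance(d.get(key), list):
                d[key] = np.asarray(d[key], dtype=float)
        if d.get("mode_amps"):
            d["mode_amps"] = [tuple(m) for m in d["mode_amps"]]
        return cls(**d)


def _ellipse_radial_factor(theta, e):
    """Equal-area ellipse radial factor with axis ratio e (max/min = e)."""
    return 1.0 / np.sqrt(np.cos(theta) ** 2 / e + e * np.sin(theta) ** 2)


def _shoelace_area(points):
    y, x = points[:, 0], points[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def radial_boundary(scenario, frame, liposome, n_samples=720):
    """Angle-sampled boundary polygon of one liposome at one frame.

    Returns an ``(n_samples, 2)`` array of (row, col) points, closed
    implicitly (last point connects to first).  Raises
    ``LiposomeAbsentError`` for a ruptured liposome.
    """
    if not (0 <= frame < scenario.n_frames):
        raise IndexError(f"frame {frame} outside stack of {scenario.n_frames}")
    if not (0 <= liposome < scenario.n_liposomes):
        raise IndexError(f"liposome {liposome} out of range")
    if scenario.is_ruptured(frame, liposome):
        raise LiposomeAbsentError(
            f"liposome {liposome} ruptured at frame {scenario.rupture_frames[liposome]}")
    gain = scenario.shape_gain[liposome]
    e = scenario.liposome_ellipticity(frame, liposome)
    scale = 1.0 + gain * (scenario.frame_area_scale()[frame] - 1.0)
    sched = scenario.frame_mode_schedule()[frame]
    theta = np.linspace(0, 2 * np.pi, n_samples, endpoint=False)
    phase = theta - scenario.orientation_rad[liposome]
    r = scenario.radius_px * math.sqrt(scale) * _ellipse_radial_factor(phase, e)
    for k, a_k, phi_k in scenario.mode_amps:
        r = r * (1.0 + gain * sched * a_k * np.cos(k * phase + phi_k))
    if np.any(r <= 0):
        raise ScenarioError("shape model produced non-positive radius")
    cy, cx = scenario.jittered_center(frame, liposome)
    return np.column_stack([cy + r * np.sin(theta), cx + r * np.cos(theta)])


def render_frame(boundaries, image_shape, *, background=10.0, signal=120.0,
                 lumen_frac=0.45, ring_width_px=1.0, ring_offset_px=3.0,
                 psf_sigma_px=1.0, read_noise_sd=3.0, poisson_noise=True,
                 rng=None):
    """Rasterize boundary polygons into a noisy fluorescence frame.

    Each liposome is drawn as a Gaussian membrane ring whose centerline sits
    ``ring_offset_px`` inside the programmed boundary (the polygon is the
    outer surface of the dye shell) over a dimmer lumen fill, blurred with a
    Gaussian PSF; Poisson shot noise and Gaussian read noise are then applied
    with ``rng`` (deterministic for a fixed generator state).
    """
    h, w = image_shape
    img = np.zeros((h, w), dtype=float)
    support = ring_offset_px + 4.0 * ring_width_px + 2.0
    for poly in boundaries:
        poly = np.asarray(poly, dtype=float)
        if (poly[:, 0].min() < 0 or poly[:, 1].min() < 0
                or poly[:, 0].max() > h - 1 or poly[:, 1].max() > w - 1):
            warnings.warn("boundary extends outside the image; clipping",
                          stacklevel=2)
        r0 = int(max(0, np.floor(poly[:, 0].min() - support)))
        r1 = int(min(h, np.ceil(poly[:, 0].max() + support) + 1))
        c0 = int(max(0, np.floor(poly[:, 1].min() - support)))
        c1 = int(min(w, np.ceil(poly[:, 1].max() + support) + 1))
        if r1 <= r0 or c1 <= c0:
            continue
        local = poly - [r0, c0]
        mask = polygon2mask((r1 - r0, c1 - c0), local)
        if not mask.any():
            continue
        d_in = ndimage.distance_transform_edt(mask)
        d_out = ndimage.distance_transform_edt(~mask)
        signed = d_out - d_in          # positive outside the boundary
        ring = np.exp(-(signed + ring_offset_px) ** 2 / (2 * ring_width_px ** 2))
        img[r0:r1, c0:c1] += signal * (lumen_frac * mask + ring)
    img += background
    if psf_sigma_px > 0:
        img = ndimage.gaussian_filter(img, psf_sigma_px)
    if rng is not None:
        if poisson_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if read_noise_sd > 0:
            img = img + rng.normal(0.0, read_noise_sd, img.shape)
    return img.astype(np.float32)


def simulate_timelapse(scenario):
    """Render the full time-lapse and its ground-truth table.

    Returns ``(stack, truth)`` where ``stack`` is a float32 array of shape
    ``(n_frames, H, W)`` and ``truth`` a DataFrame with one row per
    (frame, liposome): programmed aspect ratio, boundary-polygon area in
    px^2 (NaN once ruptured), ruptured flag and center coordinates.
    """
    scenario.validate()
    stack = np.empty((scenario.n_frames,) + scenario.image_shape,
                     dtype=np.float32)
    rows = []
    for f in range(scenario.n_frames):
        boundaries = []
        for i in range(scenario.n_liposomes):
            ruptured = scenario.is_ruptured(f, i)
            if ruptured:
                true_ar = np.nan
                true_area = np.nan
                cy = cx = np.nan
            else:
                poly = radial_boundary(scenario, f, i)
                boundaries.append(poly)
                true_ar = scenario.liposome_ellipticity(f, i)
                true_area = _shoelace_area(poly)
                cy, cx = poly[:, 0].mean(), poly[:, 1].mean()
            rows.append(dict(frame=f, liposome=i, true_ar=true_ar,
                             true_area=true_area, ruptured=ruptured,
                             center_row=cy, center_col=cx))
        rng = np.random.default_rng(
            np.random.SeedSequence([scenario.seed & 0x7FFFFFFF, 202, f]))
        stack[f] = render_frame(
            boundaries, scenario.image_shape,
            background=scenario.background, signal=scenario.signal,
            lumen_frac=scenario.lumen_frac, ring_width_px=scenario.ring_width_px,
            ring_offset_px=scenario.ring_offset_px,
            psf_sigma_px=scenario.psf_sigma_px,
            read_noise_sd=scenario.read_noise_sd,
            poisson_noise=scenario.poisson_noise, rng=rng)
    return stack, pd.DataFrame(rows)


# ----------------------------------------------------------------------------
# Image-scenario presets (study conditions)
# ----------------------------------------------------------------------------

def control_shape_scenario(n_liposomes=10, seed=0, **kw):
    """Quiescent cohort: circular liposomes, no distortion, no rupture."""
    kw.setdefault("n_frames", 34)
    kw.setdefault("addition_frame", 4)
    return ShapeScenario(n_liposomes=n_liposomes, seed=seed, **kw)


def _ramp(n_frames, addition_frame, peak, peak_frame=None, width=None):
    """Triangular per-frame ramp 1 -> peak -> 1 over the post-addition window."""
    post = n_frames - addition_frame
    if peak_frame is None:
        peak_frame = addition_frame + post // 2
    if width is None:
        width = post // 2 or 1
    f = np.arange(n_frames)
    ramp = np.clip(1.0 - np.abs(f - peak_frame) / width, 0.0, 1.0)
    ramp[:addition_frame] = 0.0
    return 1.0 + (peak - 1.0) * ramp


def distortion_shape_scenario(n_liposomes=1, peak_ellipticity=1.3,
                              peak_area_scale=1.0, mode_amps=(),
                              n_frames=34, addition_frame=4, seed=0, **kw):
    """Deforming cohort: ellipticity (and optionally area / Fourier modes)
    ramps from 1 to a peak and back across the post-addition window."""
    ell = _ramp(n_frames, addition_frame, peak_ellipticity)
    area = _ramp(n_frames, addition_frame, peak_area_scale)
    sched = _ramp(n_frames, addition_frame, 2.0) - 1.0  # 0 -> 1 -> 0
    return ShapeScenario(
        n_liposomes=n_liposomes, n_frames=n_frames,
        addition_frame=addition_frame, ellipticity=ell, area_scale=area,
        mode_amps=list(mode_amps), mode_schedule=sched, seed=seed, **kw)


def rupture_shape_scenario(n_liposomes=20, n_ruptured=17, n_frames=65,
                           addition_frame=4, frame_interval_s=30.0,
                           rupture_window_min=(2.0, 25.0),
                           image_shape=(512, 512), seed=0, **kw):
    """Rupture cohort: ``n_ruptured`` of ``n_liposomes`` disappear at frames
    drawn uniformly over ``rupture_window_min`` minutes after addition."""
    rng = np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, 303]))
    lo = addition_frame + int(round(rupture_window_min[0] * 60 / frame_interval_s))
    hi = addition_frame + int(round(rupture_window_min[1] * 60 / frame_interval_s))
    lo = max(lo, addition_frame + 1)
    hi = min(hi, n_frames - 1)
    which = rng.choice(n_liposomes, size=n_ruptured, replace=False)
    frames = rng.integers(lo, hi + 1, size=n_ruptured)
    rupture_frames = [None] * n_liposomes
    for i, f in zip(which, frames):
        rupture_frames[i] = int(f)
    return ShapeScenario(
        n_liposomes=n_liposomes, n_frames=n_frames,
        addition_frame=addition_frame, frame_interval_s=frame_interval_s,
        image_shape=image_shape, rupture_frames=rupture_frames, seed=seed, **kw)


# ----------------------------------------------------------------------------
# Current-trace scenario
# ----------------------------------------------------------------------------

@dataclass
class TraceScenario:
    """Square-pulse RC recording with a per-pulse C_m / R_m schedule.

    Defaults: +5 mV pulses; 1 kHz pulse frequency so each half-period spans
    many time constants at the default R_s = 1 MOhm and tens-of-pF membrane
    (the study's 40 kHz amplifier setting remains configurable); membrane
    parameters are piecewise-constant per pulse (capacitance evolves on
    seconds, pulses last sub-milliseconds).
    """

    duration_s: float = 0.3
    V: float = 5e-3
    pulse_freq_hz: float = 1000.0
    sample_rate_hz: float = 500_000.0
    R_s: float = 1e6
    R_m: float | np.ndarray = 1e9       # scalar or per-pulse array (ohm)
    C_m: float | np.ndarray = 50e-12    # scalar or per-pulse array (farad)
    noise_sd: float = 0.0               # additive current noise (amps)
    seed: int = 0

    @property
    def n_pulses(self):
        return int(round(self.duration_s * self.pulse_freq_hz))

    def validate(self):
        if min(self.duration_s, self.V, self.pulse_freq_hz,
               self.sample_rate_hz, self.R_s) <= 0:
            raise ScenarioError("all trace parameters must be positive")
        if self.sample_rate_hz < 20 * self.pulse_freq_hz:
            raise ScenarioError("sample_rate_hz must be >= 20 x pulse_freq_hz")
        if self.n_pulses < 1:
            raise ScenarioError("duration shorter than one pulse period")
        if np.any(self.rm_per_pulse() <= 0) or np.any(self.cm_per_pulse() <= 0):
            raise ScenarioError("R_m and C_m must be positive")

    def rm_per_pulse(self):
        return np.broadcast_to(np.asarray(self.R_m, dtype=float),
                               (self.n_pulses,)).copy()

    def cm_per_pulse(self):
        return np.broadcast_to(np.asarray(self.C_m, dtype=float),
                               (self.n_pulses,)).copy()

    def to_dict(self):
        d = asdict(self)
        for key in ("R_m", "C_m"):
            if isinstance(d[key], np.ndarray):
                d[key] = d[key].tolist()
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        for key in ("R_m", "C_m"):
            if isinstance(d.get(key), list):
                d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


def simulate_capacitance_trace(scenario):
    """Simulate the current response to a unipolar square-pulse train.

    Within each pulse the on-half current follows the RC charging law with
    that pulse's (R_m, C_m); the off-half carries the matching discharge
    (negative decaying current).  Returns ``(trace, truth)`` DataFrames:
    ``trace`` has columns ``time_s, current_A``; ``truth`` one row per pulse
    with the programmed C_m, R_m and exact time constant.
    """
    scenario.validate()
    fs = scenario.sample_rate_hz
    f = scenario.pulse_freq_hz
    n_period = int(round(fs / f))
    if abs(fs / f - n_period) > 1e-9:
        warnings.warn("sample_rate_hz is not an integer multiple of "
                      "pulse_freq_hz; pulse edges fall between samples")
    n_half = n_period // 2
    rm = scenario.rm_per_pulse()
    cm = scenario.cm_per_pulse()
    n_samples = scenario.n_pulses * n_period
    t = np.arange(n_samples) / fs
    current = np.empty(n_samples)
    V, R_s = scenario.V, scenario.R_s
    for p in range(scenario.n_pulses):
        tau = time_constant(rm[p], R_s, cm[p])[0]
        t_local = np.arange(n_half) / fs
        on = rc_current(t_local, V, rm[p], R_s, cm[p])
        # discharge from the on-half steady state when the pulse returns to 0
        B = V * rm[p] / (R_s * (rm[p] + R_s))
        off = -B * np.exp(-(np.arange(n_period - n_half) / fs) / tau)
        start = p * n_period
        current[start:start + n_half] = on
        current[start + n_half:start + n_period] = off
    if scenario.noise_sd > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence([scenario.seed & 0x7FFFFFFF, 404]))
        current = current + rng.normal(0.0, scenario.noise_sd, n_samples)
    trace = pd.DataFrame({"time_s": t, "current_A": current})
    tau_exact = np.array([time_constant(rm[p], R_s, cm[p])[0]
                          for p in range(scenario.n_pulses)])
    truth = pd.DataFrame({
        "pulse": np.arange(scenario.n_pulses),
        "time_s": np.arange(scenario.n_pulses) / f,
        "C_m_F": cm, "R_m_ohm": rm, "tau_s": tau_exact,
    })
    truth.attrs["R_s"] = R_s
    truth.attrs["V"] = V
    return trace, truth


# ----------------------------------------------------------------------------
# Trace presets (study conditions)
# ----------------------------------------------------------------------------

def _trace_preset(n_pulses, c_schedule, leak_pulses=0, leak_R_m=1e7,
                  R_m=1e9, R_s=1e6, noise_frac=0.01, seed=0, **kw):
    rm = np.full(n_pulses, float(R_m))
    rm[:leak_pulses] = leak_R_m
    kw.setdefault("pulse_freq_hz", 1000.0)
    kw.setdefault("sample_rate_hz", 500_000.0)
    kw.setdefault("V", 5e-3)
    noise_sd = noise_frac * kw["V"] / R_s   # fraction of the onset current
    scn = TraceScenario(duration_s=n_pulses / kw["pulse_freq_hz"],
                        R_s=R_s, R_m=rm, C_m=c_schedule,
                        noise_sd=noise_sd, seed=seed, **kw)
    return scn


def control_trace_scenario(n_pulses=300, C_start=50e-12, C_plateau=70e-12,
                           rise_pulses=60, **kw):
    """Peptide-free bilayer: capacitance rises from the monolayer-contact
    value and saturates at the thinned-bilayer plateau."""
    p = np.arange(n_pulses)
    c = C_plateau - (C_plateau - C_start) * np.exp(-p / rise_pulses)
    return _trace_preset(n_pulses, c, **kw)


def binding_trace_scenario(n_pulses=300, C_start=50e-12, C_end=125e-12, **kw):
    """Peptide-binding bilayer: capacitance rises continuously (no plateau)
    until the end of the recording."""
    c = np.linspace(C_start, C_end, n_pulses)
    return _trace_preset(n_pulses, c, **kw)
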