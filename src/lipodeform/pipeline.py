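"""Cohort-level time-lapse analysis: tracking, rupture and deformation stats.

Liposomes settled in a confined chamber barely move between frames, so
tracking is nearest-centroid frame-to-frame linking with a maximum jump.
Time is referenced to peptide addition: the peptide is added immediately
after the last pre-addition frame, so the first post-addition frame (index
``addition_frame``) is captured one frame interval after addition and times
"after addition" are strictly positive.

The cohort statistics mirror the deformation / distortion / partial-
deformation readouts of the study: the rupture ratio over the observation
window, per-time-bin deforming ratios (fraction of surviving liposomes with
AR > 1.1, resp. dA > 1.1), per-track maxima AR_m and dA_m with their times,
the top-k most distorted tracks, and per-track before/after contour-profile
pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import shape
from .shape import SegmentedObject, ShapeMetrics

logger = logging.getLogger("lipodeform")

MAX_JUMP_PX = 15.0
RUPTURE_PERSISTENCE = 3
BASELINE_WINDOW_S = 60.0
DEFAULT_BIN_S = 300.0

__all__ = [
    "LiposomeTrack",
    "TrackExtrema",
    "PartialDeformation",
    "DeformationSummary",
    "link_tracks",
    "detect_rupture",
    "rupture_ratio",
    "baseline_area",
    "extrema_analysis",
    "deforming_ratio_timeseries",
    "select_top_distorted",
    "partial_deformation_report",
    "analyze_stack",
    "summarize_cohort",
    "tracks_to_table",
    "tracks_from_table",
]


@dataclass
class LiposomeTrack:
    """One liposome followed across the stack.

    ``objects[f]``/``metrics[f]`` are None on frames where the liposome is
    absent.  ``a_ave`` is the pre-addition baseline area; ``rupture_frame``
    the first frame of a terminal disappearance (None = survives).
    """

    liposome_id: int
    n_frames: int
    addition_frame: int
    frame_interval_s: float
    objects: list = field(repr=False, default=None)
    metrics: list = field(repr=False, default=None)
    a_ave: float = np.nan
    rupture_frame: int | None = None

    def __post_init__(self):
        if self.objects is None:
            self.objects = [None] * self.n_frames
        if self.metrics is None:
            self.metrics = [None] * self.n_frames

    def present(self, frame):
        return self.objects[frame] is not None or self.metrics[frame] is not None

    def time_after_addition_s(self, frame):
        """Seconds after peptide addition; the first post-addition frame is
        one interval after addition."""
        return (frame - self.addition_frame + 1) * self.frame_interval_s

    def metric_array(self, attr):
        return np.array([getattr(m, attr) if m is not None else np.nan
                         for m in self.metrics], dtype=float)

    def post_addition_frames(self):
        return [f for f in range(self.addition_frame, self.n_frames)
                if self.metrics[f] is not None]

    def pre_addition_frames(self):
        return [f for f in range(self.addition_frame)
                if self.metrics[f] is not None]


# ----------------------------------------------------------------------------
# Tracking
# ----------------------------------------------------------------------------

def link_tracks(frame_objects, addition_frame, frame_interval_s=30.0,
                max_jump_px=MAX_JUMP_PX):
    """Greedy nearest-centroid linking of per-frame segmented objects.

    ``frame_objects`` is a list (one entry per frame) of lists of
    SegmentedObject.  Each object joins the track whose last known centroid
    is nearest within ``max_jump_px``; when two objects claim one track the
    nearer wins and the other is discarded with a warning.  Objects that
    match no track seed a new track only before ``addition_frame`` (debris
    and rupture remnants do not enter the cohort afterwards).
    """
    n_frames = len(frame_objects)
    tracks: list[LiposomeTrack] = []
    last_centroid: dict[int, np.ndarray] = {}

    def new_track(frame, obj):
        t = LiposomeTrack(liposome_id=len(tracks), n_frames=n_frames,
                          addition_frame=addition_frame,
                          frame_interval_s=frame_interval_s)
        t.objects[frame] = obj
        tracks.append(t)
        last_centroid[t.liposome_id] = np.asarray(obj.centroid, dtype=float)

    for f, objects in enumerate(frame_objects):
        if not tracks:
            for obj in objects:
                if f < addition_frame or f == 0:
                    new_track(f, obj)
            continue
        # candidate (distance, track, object) pairs within the jump limit
        cands = []
        for ti, track in enumerate(tracks):
            c0 = last_centroid[track.liposome_id]
            for oi, obj in enumerate(objects):
                d = float(np.hypot(*(np.asarray(obj.centroid) - c0)))
                if d <= max_jump_px:
                    cands.append((d, ti, oi))
        cands.sort()
        used_tracks, used_objects = set(), set()
        for d, ti, oi in cands:
            if ti in used_tracks or oi in used_objects:
                continue
            used_tracks.add(ti)
            used_objects.add(oi)
            tracks[ti].objects[f] = objects[oi]
            last_centroid[tracks[ti].liposome_id] = np.asarray(
                objects[oi].centroid, dtype=float)
        for oi, obj in enumerate(objects):
            if oi in used_objects:
                continue
            if f < addition_frame:
                new_track(f, obj)
            else:
                logger.warning("frame %d: unmatched object at %s discarded",
                               f, tuple(round(c, 1) for c in obj.centroid))
    return tracks


def detect_rupture(track, persistence=RUPTURE_PERSISTENCE):
    """First frame of a terminal absence run of at least ``persistence``
    frames; transient dropouts shorter than that are ignored (segmentation
    blinks are not rupture).  Returns None for surviving tracks."""
    last_present = None
    for f in range(track.n_frames - 1, -1, -1):
        if track.objects[f] is not None or track.metrics[f] is not None:
            last_present = f
            break
    if last_present is None:
        return 0 if track.n_frames >= persistence else None
    run = track.n_frames - 1 - last_present
    if run >= persistence:
        return last_present + 1
    return None


def rupture_ratio(tracks, window_s=1800.0):
    """Fraction of tracks whose rupture falls within ``window_s`` seconds
    after peptide addition."""
    if not tracks:
        raise ValueError("empty cohort")
    n_rupt = 0
    for t in tracks:
        if t.rupture_frame is None:
            continue
        rt = t.time_after_addition_s(t.rupture_frame)
        if 0 < rt <= window_s:
            n_rupt += 1
    return n_rupt / len(tracks)


def baseline_area(track, window_s=BASELINE_WINDOW_S):
    """Mean area over present frames within ``window_s`` seconds before
    addition — the half-open window [addition - 60 s, addition)."""
    n_window = max(1, int(round(window_s / track.frame_interval_s)))
    first = max(0, track.addition_frame - n_window)
    areas = [track.objects[f].area_px
             for f in range(first, track.addition_frame)
             if track.objects[f] is not None]
    if not areas:
        raise ValueError(
            f"track {track.liposome_id}: no present frame in the baseline window")
    return float(np.mean(areas))


# ----------------------------------------------------------------------------
# Per-track statistics
# ----------------------------------------------------------------------------

@dataclass
class TrackExtrema:
    liposome_id: int
    ar_m: float
    t_ar_m_min: float      # minutes after addition
    da_m: float
    t_da_m_min: float
    eligible: bool         # False when ruptured before any post-addition frame


def extrema_analysis(track):
    """Post-addition maxima of AR and dA with their times (minutes after
    addition); ties resolve to the earliest frame.  Tracks with no present
    post-addition frame are flagged ineligible."""
    frames = track.post_addition_frames()
    if not frames:
        return TrackExtrema(track.liposome_id, np.nan, np.nan, np.nan,
                            np.nan, eligible=False)
    ar = np.array([track.metrics[f].ar for f in frames])
    da = np.array([track.metrics[f].delta_a for f in frames])
    i_ar = int(np.nanargmax(ar))
    i_da = int(np.nanargmax(da)) if np.any(np.isfinite(da)) else i_ar
    return TrackExtrema(
        liposome_id=track.liposome_id,
        ar_m=float(ar[i_ar]),
        t_ar_m_min=track.time_after_addition_s(frames[i_ar]) / 60.0,
        da_m=float(da[i_da]) if np.isfinite(da[i_da]) else np.nan,
        t_da_m_min=track.time_after_addition_s(frames[i_da]) / 60.0,
        eligible=True,
    )


def deforming_ratio_timeseries(tracks, bin_s=DEFAULT_BIN_S,
                               ar_threshold=shape.AR_THRESHOLD,
                               da_threshold=shape.DELTA_A_THRESHOLD):
    """Per-time-bin fraction of surviving liposomes over each threshold.

    Bins tile the post-addition window.  A track counts toward a bin's
    denominator when it has at least one present frame in the bin (ruptured
    tracks therefore leave the denominator after rupture); it counts toward
    a numerator when any of those frames exceeds the threshold.  Bins where
    no track is present yield NaN.
    """
    if not tracks:
        raise ValueError("empty cohort")
    t0 = tracks[0]
    end_s = t0.time_after_addition_s(t0.n_frames - 1)
    n_bins = int(np.ceil(end_s / bin_s))
    rows = []
    for b in range(n_bins):
        lo, hi = b * bin_s, (b + 1) * bin_s
        n_present = n_ar = n_da = 0
        for track in tracks:
            frames = [f for f in track.post_addition_frames()
                      if lo < track.time_after_addition_s(f) <= hi]
            if not frames:
                continue
            n_present += 1
            if any(track.metrics[f].ar > ar_threshold for f in frames):
                n_ar += 1
            if any(np.isfinite(track.metrics[f].delta_a)
                   and track.metrics[f].delta_a > da_threshold for f in frames):
                n_da += 1
        rows.append(dict(
            bin_start_min=lo / 60.0, bin_end_min=hi / 60.0,
            n_tracks=n_present,
            frac_ar=n_ar / n_present if n_present else np.nan,
            frac_da=n_da / n_present if n_present else np.nan))
    return pd.DataFrame(rows)


def select_top_distorted(tracks, k=5):
    """The k tracks with the highest post-addition AR_m, in descending
    order; ties rank the earlier t(AR_m) first."""
    extrema = [extrema_analysis(t) for t in tracks]
    eligible = [(e, t) for e, t in zip(extrema, tracks) if e.eligible]
    if len(eligible) < k:
        warnings.warn(f"only {len(eligible)} eligible tracks for top-{k} "
                      "selection; returning all", stacklevel=2)
    eligible.sort(key=lambda et: (-et[0].ar_m, et[0].t_ar_m_min))
    return [t for _, t in eligible[:k]]


@dataclass
class PartialDeformation:
    """Before/after contour-profile pair of one liposome: the pre-addition
    frame with the median AR, and the post-addition frame of dA_m."""

    liposome_id: int
    pre_frame: int
    post_frame: int
    pre_r_nor: np.ndarray
    post_r_nor: np.ndarray
    pre_amplitude: float
    post_amplitude: float


def partial_deformation_report(track):
    """Pair the median-AR pre-addition frame (lower median for even counts)
    with the dA_m post-addition frame, returning both normalized-radius
    profiles and their distortion amplitudes."""
    pre = track.pre_addition_frames()
    post = track.post_addition_frames()
    if not pre or not post:
        raise ValueError(
            f"track {track.liposome_id}: needs both pre- and post-addition frames")
    pre_ar = np.array([track.metrics[f].ar for f in pre])
    order = np.argsort(pre_ar, kind="stable")
    pre_frame = pre[order[(len(pre) - 1) // 2]]      # lower median
    post_da = np.array([track.metrics[f].delta_a for f in post])
    post_frame = post[int(np.nanargmax(post_da))]
    m_pre, m_post = track.metrics[pre_frame], track.metrics[post_frame]
    return PartialDeformation(
        liposome_id=track.liposome_id, pre_frame=pre_frame,
        post_frame=post_frame, pre_r_nor=m_pre.r_nor, post_r_nor=m_post.r_nor,
        pre_amplitude=m_pre.amplitude, post_amplitude=m_post.amplitude)


# ----------------------------------------------------------------------------
# Stack-level driver and cohort summary
# ----------------------------------------------------------------------------

def analyze_stack(stack, addition_frame, frame_interval_s=30.0,
                  min_area_px=shape.MIN_AREA_PX, max_jump_px=MAX_JUMP_PX,
                  persistence=RUPTURE_PERSISTENCE, n_angles=360,
                  amplitude_method="rms", ar_threshold=shape.AR_THRESHOLD,
                  da_threshold=shape.DELTA_A_THRESHOLD):
    """Segment, link and measure every liposome in a time-lapse stack.

    Returns the list of LiposomeTrack with per-frame metrics, baseline
    areas and rupture frames filled in.  Tracks without a usable baseline
    get dA = NaN rather than aborting the cohort.
    """
    frame_objects = [shape.segment_all(frame, min_area_px=min_area_px)
                     for frame in stack]
    tracks = link_tracks(frame_objects, addition_frame,
                         frame_interval_s=frame_interval_s,
                         max_jump_px=max_jump_px)
    for track in tracks:
        track.rupture_frame = detect_rupture(track, persistence=persistence)
        try:
            track.a_ave = baseline_area(track)
        except ValueError as exc:
            logger.warning("%s; dA unavailable for this track", exc)
            track.a_ave = np.nan
        for f in range(track.n_frames):
            obj = track.objects[f]
            if obj is None:
                continue
            try:
                track.metrics[f] = shape.compute_metrics(
                    obj,
                    a_ave=track.a_ave if np.isfinite(track.a_ave) else None,
                    n_angles=n_angles, amplitude_method=amplitude_method,
                    ar_threshold=ar_threshold, da_threshold=da_threshold)
            except ValueError as exc:
                logger.warning("track %d frame %d: %s", track.liposome_id,
                               f, exc)
    return tracks


@dataclass
class DeformationSummary:
    rupture_ratio: float
    extrema: pd.DataFrame            # per-track AR_m, dA_m and times
    deforming_ratio: pd.DataFrame    # per-bin fractions
    top_distorted_ids: list
    amplitude_mean: float            # cohort distortion amplitude at dA_m
    amplitude_sd: float
    n_tracks: int

    def to_dict(self):
        return {
            "rupture_ratio": self.rupture_ratio,
            "n_tracks": self.n_tracks,
            "top_distorted_ids": list(self.top_distorted_ids),
            "amplitude_mean": self.amplitude_mean,
            "amplitude_sd": self.amplitude_sd,
            "extrema": self.extrema.to_dict(orient="records"),
            "deforming_ratio": self.deforming_ratio.to_dict(orient="records"),
        }


def summarize_cohort(tracks, window_s=1800.0, bin_s=DEFAULT_BIN_S, k=5,
                     ar_threshold=shape.AR_THRESHOLD,
                     da_threshold=shape.DELTA_A_THRESHOLD):
    """Cohort statistics: rupture ratio over the window, per-track extrema,
    deforming-ratio time series, top-k distorted tracks and the mean +/- sd
    distortion amplitude at each track's dA_m frame."""
    extrema = [extrema_analysis(t) for t in tracks]
    ext_df = pd.DataFrame([e.__dict__ for e in extrema])
    amplitudes = []
    for track in tracks:
        try:
            amplitudes.append(partial_deformation_report(track).post_amplitude)
        except ValueError:
            continue
    top = select_top_distorted(tracks, k=min(k, len(tracks)))
    return DeformationSummary(
        rupture_ratio=rupture_ratio(tracks, window_s=window_s),
        extrema=ext_df,
        deforming_ratio=deforming_ratio_timeseries(
            tracks, bin_s=bin_s, ar_threshold=ar_threshold,
            da_threshold=da_threshold),
        top_distorted_ids=[t.liposome_id for t in top],
        amplitude_mean=float(np.mean(amplitudes)) if amplitudes else np.nan,
        amplitude_sd=float(np.std(amplitudes, ddof=1))
        if len(amplitudes) > 1 else np.nan,
        n_tracks=len(tracks),
    )


# ----------------------------------------------------------------------------
# Tidy-table round trip (metrics CSV <-> metric-only tracks)
# ----------------------------------------------------------------------------

def tracks_to_table(tracks):
    """Per-(frame, liposome) tidy metrics table, including absent frames."""
    rows = []
    for track in tracks:
        for f in range(track.n_frames):
            m = track.metrics[f]
            rows.append(dict(
                frame=f, liposome_id=track.liposome_id,
                present=m is not None,
                area_px=m.area_px if m else np.nan,
                ar=m.ar if m else np.nan,
                dA=m.delta_a if m else np.nan,
                amplitude=m.amplitude if m else np.nan,
                deformed_ar=bool(m.deformed_by_ar) if m else False,
                deformed_dA=bool(m.deformed_by_da) if m else False,
            ))
    return pd.DataFrame(rows)


def tracks_from_table(df, addition_frame, frame_interval_s=30.0,
                      persistence=RUPTURE_PERSISTENCE):
    """Rebuild metric-only tracks (no masks/contours) from a metrics table,
    sufficient for every cohort statistic except the R_nor profiles."""
    n_frames = int(df["frame"].max()) + 1
    tracks = []
    for lid, sub in df.groupby("liposome_id"):
        track = LiposomeTrack(liposome_id=int(lid), n_frames=n_frames,
                              addition_frame=addition_frame,
                              frame_interval_s=frame_interval_s)
        for _, row in sub.iterrows():
            if not row["present"]:
                continue
            track.metrics[int(row["frame"])] = ShapeMetrics(
                area_px=row["area_px"], ar=row["ar"], delta_a=row["dA"],
                amplitude=row["amplitude"], r_nor=None,
                deformed_by_ar=bool(row["deformed_ar"]),
                deformed_by_da=bool(row["deformed_dA"]))
        track.rupture_frame = detect_rupture(track, persistence=persistence)
        tracks.append(track)
    return tracks
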