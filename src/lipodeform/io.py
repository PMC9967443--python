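"""Run configuration, file I/O and the pipeline driver.

Formats: multi-page TIFF (image stacks), CSV (per-frame metrics, current
traces, per-pulse capacitance), JSON (summaries, ground truth), YAML (run
configuration and generator scenarios).  Every CSV/JSON artifact carries the
seed and a hash of the configuration that produced it, and re-running with
the same seed is byte-stable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from dataclasses import dataclass, asdict, fields
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from . import capacitance, pipeline, shape, synthetic

logger = logging.getLogger("lipodeform")

MODES = ("simulate-images", "simulate-trace", "analyze-images",
         "analyze-trace", "report")

__all__ = ["RunConfig", "read_stack", "read_trace", "run_pipeline"]


@dataclass
class RunConfig:
    """Run parameters; thresholds default to the study's printed values."""

    mode: str = "analyze-images"
    input_path: str | None = None
    out_dir: str = "."
    scenario: dict | None = None       # generator scenario (simulate modes)
    pixel_size_um: float = 0.1
    addition_frame: int = 4
    frame_interval_s: float = 30.0
    V: float = 5e-3
    pulse_freq_hz: float = 1000.0
    ar_threshold: float = 1.1
    da_threshold: float = 1.1
    tol: float = 0.08
    persistence: int = 3
    min_window: int = 10
    min_area_px: int = shape.MIN_AREA_PX
    max_jump_px: float = pipeline.MAX_JUMP_PX
    bin_s: float = 300.0
    window_s: float = 1800.0
    R_s_fixed: float | None = None
    C_ceiling: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data):
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(data) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {', '.join(unknown)}")
        return cls(**data)

    def to_dict(self):
        return asdict(self)

    def config_hash(self):
        """Hash of the analysis-relevant configuration (paths excluded, so
        the same run into a different directory is byte-identical)."""
        d = {k: v for k, v in self.to_dict().items()
             if k not in ("input_path", "out_dir")}
        canon = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ----------------------------------------------------------------------------
# Readers
# ----------------------------------------------------------------------------

_NUM_RE = re.compile(r"(\d+)")


def _numeric_key(path):
    m = _NUM_RE.findall(path.stem)
    return (int(m[-1]) if m else 0, path.name)


def read_stack(path):
    """Load a time-lapse as a (frames, H, W) grayscale float array.

    Accepts a multi-page TIFF or a directory of numbered single-frame
    images (sorted by the trailing number in the file name).  Errors name
    the offending frame; mixed frame dimensions are rejected.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted((p for p in path.iterdir()
                        if p.suffix.lower() in {".png", ".tif", ".tiff"}),
                       key=_numeric_key)
        if not files:
            raise ValueError(f"no image files found in {path}")
        frames = []
        for p in files:
            try:
                frames.append(np.asarray(iio.imread(p), dtype=float))
            except Exception as exc:
                raise ValueError(f"unreadable frame {p.name}: {exc}") from exc
        shapes = {f.shape for f in frames}
        if len(shapes) != 1:
            raise ValueError(f"mixed frame dimensions in {path}: {sorted(shapes)}")
        stack = np.stack(frames)
    else:
        try:
            stack = np.asarray(tifffile.imread(path), dtype=float)
        except Exception as exc:
            raise ValueError(f"unreadable stack {path}: {exc}") from exc
        if stack.ndim == 2:
            stack = stack[None]
    if stack.ndim == 4:   # RGB -> luminance
        stack = stack.mean(axis=-1)
    if stack.ndim != 3:
        raise ValueError(f"expected a (frames, H, W) stack, got shape {stack.shape}")
    return stack


def read_trace(path):
    """Load a current trace CSV with time_s, current_A columns."""
    df = pd.read_csv(path, comment="#")
    missing = {"time_s", "current_A"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


# ----------------------------------------------------------------------------
# Writers (seed + config hash stamped into every artifact)
# ----------------------------------------------------------------------------

def _write_csv(df, path, config):
    header = f"# seed={config.seed} config_sha256={config.config_hash()}\n"
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, index=False, float_format="%.10g", lineterminator="\n")


def _write_json(obj, path, config):
    payload = {"seed": config.seed, "config_sha256": config.config_hash(),
               **obj}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(v):
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, float) and not np.isfinite(v):
        return None
    raise TypeError(f"not JSON serializable: {type(v)}")


def _clean_nan(obj):
    if isinstance(obj, dict):
        return {k: _clean_nan(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_clean_nan(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


# ----------------------------------------------------------------------------
# Pipeline driver
# ----------------------------------------------------------------------------

def run_pipeline(config):
    """Execute one configured run and write its artifacts to ``out_dir``.

    Returns the list of paths written.  Per-track failures are logged and
    skipped; they do not abort the cohort.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    if config.mode == "simulate-images":
        scn_dict = dict(config.scenario or {})
        preset = scn_dict.pop("preset", None)
        scn_dict.setdefault("seed", config.seed)
        if preset == "control":
            scn = synthetic.control_shape_scenario(**scn_dict)
        elif preset == "distortion":
            scn = synthetic.distortion_shape_scenario(**scn_dict)
        elif preset == "rupture":
            scn = synthetic.rupture_shape_scenario(**scn_dict)
        else:
            scn = synthetic.ShapeScenario.from_dict(scn_dict)
        stack, truth = synthetic.simulate_timelapse(scn)
        tifffile.imwrite(out / "stack.tiff", stack)
        written.append(out / "stack.tiff")
        _write_json({"truth": _clean_nan(truth.to_dict(orient="records"))},
                    out / "truth.json", config)
        written.append(out / "truth.json")
        with open(out / "scenario.yaml", "w") as fh:
            yaml.safe_dump(scn.to_dict(), fh, sort_keys=True)
        written.append(out / "scenario.yaml")

    elif config.mode == "simulate-trace":
        scn_dict = dict(config.scenario or {})
        preset = scn_dict.pop("preset", None)
        scn_dict.setdefault("seed", config.seed)
        if preset == "control":
            scn = synthetic.control_trace_scenario(**scn_dict)
        elif preset == "binding":
            scn = synthetic.binding_trace_scenario(**scn_dict)
        else:
            scn = synthetic.TraceScenario.from_dict(scn_dict)
        trace, truth = synthetic.simulate_capacitance_trace(scn)
        _write_csv(trace, out / "trace.csv", config)
        _write_csv(truth, out / "trace_truth.csv", config)
        written += [out / "trace.csv", out / "trace_truth.csv"]

    elif config.mode == "analyze-images":
        stack = read_stack(config.input_path)
        tracks = pipeline.analyze_stack(
            stack, config.addition_frame,
            frame_interval_s=config.frame_interval_s,
            min_area_px=config.min_area_px, max_jump_px=config.max_jump_px,
            persistence=config.persistence,
            ar_threshold=config.ar_threshold,
            da_threshold=config.da_threshold)
        _write_csv(pipeline.tracks_to_table(tracks), out / "metrics.csv", config)
        summary = pipeline.summarize_cohort(
            tracks, window_s=config.window_s, bin_s=config.bin_s,
            ar_threshold=config.ar_threshold, da_threshold=config.da_threshold)
        _write_csv(summary.deforming_ratio, out / "deforming_ratio.csv", config)
        _write_json(_clean_nan(summary.to_dict()), out / "summary.json", config)
        written += [out / "metrics.csv", out / "deforming_ratio.csv",
                    out / "summary.json"]

    elif config.mode == "analyze-trace":
        trace = read_trace(config.input_path)
        series = capacitance.analyze_trace(
            trace["time_s"].to_numpy(), trace["current_A"].to_numpy(),
            V=config.V, pulse_freq_hz=config.pulse_freq_hz,
            R_s_fixed=config.R_s_fixed, tol=config.tol,
            min_window=config.min_window, C_ceiling=config.C_ceiling)
        _write_csv(series.to_dataframe(), out / "pulses.csv", config)
        _write_json({"time_zero": int(series.time_zero),
                     "C_i_F": series.C_i, "C_max_F": series.C_max,
                     "C_nor": series.C_nor},
                    out / "capacitance_summary.json", config)
        written += [out / "pulses.csv", out / "capacitance_summary.json"]

    elif config.mode == "report":
        df = pd.read_csv(config.input_path, comment="#")
        tracks = pipeline.tracks_from_table(
            df, config.addition_frame,
            frame_interval_s=config.frame_interval_s,
            persistence=config.persistence)
        summary = pipeline.summarize_cohort(
            tracks, window_s=config.window_s, bin_s=config.bin_s,
            ar_threshold=config.ar_threshold, da_threshold=config.da_threshold)
        _write_json(_clean_nan(summary.to_dict()), out / "report.json", config)
        written.append(out / "report.json")

    logger.info("mode=%s seed=%d config=%s -> %d artifact(s)", config.mode,
                config.seed, config.config_hash(), len(written))
    return written
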