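"""Membrane-capacitance estimation from square-pulse current recordings.

A planar lipid bilayer in a droplet-contact (droplet interface bilayer)
measurement behaves, to first order, as a membrane capacitance ``C_m`` in
parallel with a membrane resistance ``R_m``, in series with the access
resistance ``R_s`` (electrodes plus electrolyte).  When a voltage step ``V``
is applied, the charging current decays as

    I(t) = V / (R_m + R_s) * (1 + (R_m / R_s) * exp(-t / tau)),
    tau  = R_m * R_s * C_m / (R_m + R_s)  ~=  R_s * C_m   for R_m >> R_s.

This module recovers ``C_m`` per pulse from a recorded current trace by two
independent routes:

* ``C_tau``: fit the exponential decay, take ``tau`` over the series
  resistance estimated from the onset current (``R_s = V / I_peak``);
* ``C_Q``: integrate the capacitive charge ``Q = ∫ (I - I_ss) dt`` and use
  ``C = Q / V``.

When pores or defects lower ``R_m`` (leakage), the two routes disagree by
exactly ``R_s / (R_m + R_s)`` relative, which is the basis of the
leakage-exclusion ("time zero") rule: analysis starts at the first run of
pulses on which charge- and tau-based capacitance are concordant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

VACUUM_PERMITTIVITY = 8.854e-12  # F/m

__all__ = [
    "PulseSegmentationError",
    "PulseTransient",
    "TransientFit",
    "CapacitanceSeries",
    "PlateModel",
    "rc_current",
    "time_constant",
    "segment_pulses",
    "fit_transient",
    "capacitance_from_charge",
    "find_time_zero",
    "normalized_capacitance",
    "parallel_plate_capacitance",
    "infer_relative_permittivity",
    "analyze_trace",
]


class PulseSegmentationError(ValueError):
    """Raised when a trace has no usable square-pulse structure."""


# ----------------------------------------------------------------------------
# RC circuit model
# ----------------------------------------------------------------------------

def rc_current(t, V, R_m, R_s, C_m):
    """Charging current of the series-R_s / parallel-(R_m, C_m) circuit.

    Parameters are in SI units (s, V, ohm, F).  ``t`` may be scalar or array,
    measured from the pulse onset.  At ``t = 0`` the current is ``V / R_s``;
    as ``t -> inf`` it settles to the ohmic value ``V / (R_m + R_s)``.
    """
    for name, v in (("V", V), ("R_m", R_m), ("R_s", R_s), ("C_m", C_m)):
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v!r}")
    tau = time_constant(R_m, R_s, C_m)[0]
    t = np.asarray(t, dtype=float)
    return V / (R_m + R_s) * (1.0 + (R_m / R_s) * np.exp(-t / tau))


def time_constant(R_m, R_s, C_m):
    """Return ``(tau_exact, tau_approx)`` for the RC circuit.

    ``tau_exact = R_m R_s C_m / (R_m + R_s)``; ``tau_approx = R_s C_m`` is
    the usual R_m >> R_s simplification.  Their relative gap is exactly
    ``R_s / (R_m + R_s)``.
    """
    tau_exact = R_m * R_s * C_m / (R_m + R_s)
    tau_approx = R_s * C_m
    return tau_exact, tau_approx


# ----------------------------------------------------------------------------
# Pulse segmentation
# ----------------------------------------------------------------------------

@dataclass
class PulseTransient:
    """One capacitive decay segment, time measured from the pulse onset."""

    time_s: np.ndarray       # strictly increasing, starts at 0
    current_A: np.ndarray
    V: float                 # commanded pulse amplitude (volts)
    onset_time_s: float = 0.0  # absolute onset time within the parent trace

    def __post_init__(self):
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.current_A = np.asarray(self.current_A, dtype=float)
        if self.time_s.size < 10:
            raise ValueError("transient needs >= 10 samples")
        if self.time_s[0] != 0 or np.any(np.diff(self.time_s) <= 0):
            raise ValueError("transient time must increase strictly from 0")


def segment_pulses(time_s, current_A, pulse_freq_hz, V):
    """Cut a recorded trace into per-pulse transients.

    The trace is assumed to be sampled uniformly.  The onset phase is located
    at the current maximum within the first pulse period (the capacitive
    charging current peaks at the onset and decays monotonically); subsequent
    onsets follow at one period spacing.  Each transient is trimmed to the
    positive half-period.
    """
    time_s = np.asarray(time_s, dtype=float)
    current_A = np.asarray(current_A, dtype=float)
    if time_s.size < 2:
        raise PulseSegmentationError("trace too short")
    dt = np.median(np.diff(time_s))
    fs = 1.0 / dt
    if fs < 20 * pulse_freq_hz:
        raise PulseSegmentationError(
            f"sample rate {fs:.3g} Hz < 20 x pulse frequency {pulse_freq_hz:.3g} Hz"
        )
    n_period = int(round(fs / pulse_freq_hz))
    n_half = n_period // 2
    if time_s.size < n_period:
        raise PulseSegmentationError("trace shorter than one pulse period")
    start = int(np.argmax(current_A[:n_period]))
    transients = []
    for onset in range(start, time_s.size - n_half + 1, n_period):
        seg = current_A[onset:onset + n_half]
        transients.append(
            PulseTransient(
                time_s=np.arange(n_half) * dt,
                current_A=seg,
                V=V,
                onset_time_s=time_s[onset],
            )
        )
    if not transients:
        raise PulseSegmentationError("no complete pulse found in trace")
    return transients


# ----------------------------------------------------------------------------
# Per-transient fitting
# ----------------------------------------------------------------------------

@dataclass
class TransientFit:
    """Exponential fit ``I(t) = I_ss + (I_peak - I_ss) exp(-t/tau)`` plus the
    circuit quantities derived from it."""

    I_peak: float
    I_ss: float
    tau_s: float
    R_s_est: float
    R_m_est: float
    C_tau: float        # tau / R_s
    C_Q: float          # charge integral / V
    rmse: float
    valid: bool
    message: str = ""


def _exp_model(t, A, B, tau):
    return A + B * np.exp(-t / tau)


def fit_transient(transient, R_s_fixed=None, rmse_rel_max=0.2):
    """Nonlinear least-squares fit of a single capacitive transient.

    ``A = I_ss`` and ``A + B = I_peak``.  Initial values come from the tail
    mean (``A``) and a log-linear regression of ``I - A`` (``tau``).  The fit
    is flagged invalid when there is no decaying component (``B`` not clearly
    positive), the residual is large relative to the decay amplitude, or the
    optimizer fails.

    ``R_s_fixed`` pins the series resistance instead of the per-pulse
    estimate ``V / I_peak``.
    """
    t = transient.time_s
    I = transient.current_A
    V = transient.V
    n_tail = max(5, len(I) // 10)
    A0 = float(np.mean(I[-n_tail:]))
    B0 = float(I[0] - A0)
    noise0 = float(np.std(I[-n_tail:]))

    invalid = dict(I_peak=float(I[0]), I_ss=A0, tau_s=np.nan, R_s_est=np.nan,
                   R_m_est=np.nan, C_tau=np.nan, C_Q=np.nan, rmse=noise0,
                   valid=False)
    if B0 <= max(3.0 * noise0, 1e-3 * abs(A0)):
        return TransientFit(**invalid, message="no decaying component")

    # log-linear init for tau on the early, clearly-positive part of I - A0
    y = I - A0
    pos = y > 0.05 * B0
    if pos.sum() >= 3:
        coef = np.polyfit(t[pos], np.log(y[pos]), 1)
        tau0 = -1.0 / coef[0] if coef[0] < 0 else t[-1] / 5.0
    else:
        tau0 = t[-1] / 5.0
    tau0 = float(np.clip(tau0, t[1], t[-1]))

    # fit in nondimensional units (currents / I(0), time / window) so the
    # pA-scale baseline and the nA-scale peak are equally well conditioned;
    # the baseline is bounded at 0: with R_m >> R_s the true steady-state
    # current sits below the noise floor and must not fit negative
    s_I, s_t = float(I[0]), float(t[-1])
    try:
        popt, _ = curve_fit(
            _exp_model, t / s_t, I / s_I,
            p0=(max(A0, 0.0) / s_I, B0 / s_I, tau0 / s_t),
            bounds=([0.0, 0.0, 1e-6], [np.inf, np.inf, 1e6]),
            maxfev=10000,
        )
    except RuntimeError as exc:
        return TransientFit(**invalid, message=f"fit failed: {exc}")
    A, B, tau = float(popt[0]) * s_I, float(popt[1]) * s_I, float(popt[2]) * s_t
    resid = I - _exp_model(t, A, B, tau)
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    I_peak = A + B
    I_ss = A
    if B <= 0 or rmse > rmse_rel_max * B or I_peak <= 0:
        return TransientFit(I_peak=I_peak, I_ss=I_ss, tau_s=tau, R_s_est=np.nan,
                            R_m_est=np.nan, C_tau=np.nan, C_Q=np.nan, rmse=rmse,
                            valid=False, message="poor fit")
    R_s_est = V / I_peak if R_s_fixed is None else float(R_s_fixed)
    R_m_est = V / I_ss - R_s_est if I_ss > 0 else np.inf
    C_tau = tau / R_s_est
    fit = TransientFit(I_peak=I_peak, I_ss=I_ss, tau_s=tau, R_s_est=R_s_est,
                       R_m_est=R_m_est, C_tau=C_tau, C_Q=np.nan, rmse=rmse,
                       valid=True)
    fit.C_Q = capacitance_from_charge(transient, fit)
    return fit


def capacitance_from_charge(transient, fit):
    """Charge-based capacitance ``C_Q = Q / V`` with
    ``Q = ∫ (I - I_ss) dt`` (trapezoid) over the transient window.

    For the noiseless RC model over an infinite window the closed form is
    ``C_Q = C_m (R_m / (R_m + R_s))^2``, i.e. within ``2 R_s / R_m`` relative
    of the true capacitance when R_m >> R_s.
    """
    Q = float(np.trapezoid(transient.current_A - fit.I_ss, transient.time_s))
    if Q < 0:
        fit.valid = False
        fit.message = (fit.message + "; " if fit.message else "") + "negative charge"
    return Q / transient.V


# ----------------------------------------------------------------------------
# Series-level analysis: time zero, C_nor
# ----------------------------------------------------------------------------

@dataclass
class CapacitanceSeries:
    """Per-pulse capacitance estimates with the leakage validity window."""

    time_s: np.ndarray          # pulse onset times
    C_m: np.ndarray             # tau-based estimate per pulse (farads)
    C_Q: np.ndarray             # charge-based estimate per pulse (farads)
    valid: np.ndarray           # bool per pulse
    fits: list = field(default_factory=list, repr=False)
    time_zero: int | None = None
    C_i: float = np.nan
    C_max: float = np.nan
    C_nor: float = np.nan

    def to_dataframe(self):
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "tau_s": [f.tau_s for f in self.fits] if self.fits else np.nan,
                "C_tau_F": self.C_m,
                "C_Q_F": self.C_Q,
                "valid": self.valid,
            }
        )


def find_time_zero(C_tau, C_Q, valid=None, tol=0.08, min_window=10):
    """First pulse index from which tau- and charge-based capacitance agree.

    Leakage (low membrane resistance) biases ``C_Q`` below ``C_tau`` by the
    factor ``R_m / (R_m + R_s)``, so their relative disagreement flags
    leakage-dominated pulses.  Returns the smallest index at which
    ``|C_Q / C_tau - 1| < tol`` holds for ``min_window`` consecutive valid
    pulses; raises ``ValueError`` if no such window exists.
    """
    C_tau = np.asarray(C_tau, dtype=float)
    C_Q = np.asarray(C_Q, dtype=float)
    n = C_tau.size
    if n < min_window:
        raise ValueError(f"need >= {min_window} pulses, got {n}")
    ok = np.isfinite(C_tau) & np.isfinite(C_Q) & (C_tau > 0)
    if valid is not None:
        ok &= np.asarray(valid, dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        concordant = ok & (np.abs(C_Q / C_tau - 1.0) < tol)
    run = 0
    for i, c in enumerate(concordant):
        run = run + 1 if c else 0
        if run >= min_window:
            return i - min_window + 1
    raise ValueError("no leakage-free window: tau- and charge-based capacitance "
                     "never concordant for the required run of pulses")


def normalized_capacitance(series, tol=0.08, min_window=10, C_ceiling=None):
    """Apply the time-zero rule and compute ``C_nor = C_max / C_i``.

    ``C_i`` is the capacitance at time zero (start of the leakage-free
    window); ``C_max`` the maximum valid capacitance from time zero on.  A
    ``C_ceiling`` (farads) models the readout limit of the acquisition
    equipment: pulses at or above it are truncated from the valid series.
    Marks pre-time-zero pulses invalid in place and returns the series.
    """
    t0 = find_time_zero(series.C_m, series.C_Q, series.valid,
                        tol=tol, min_window=min_window)
    series.valid[:t0] = False
    if C_ceiling is not None:
        series.valid[series.C_m >= C_ceiling] = False
    sel = series.valid.copy()
    sel[:t0] = False
    if not sel[t0]:
        raise ValueError("capacitance at time zero is invalid")
    C_i = float(series.C_m[t0])
    if C_i <= 0:
        raise ValueError("non-positive capacitance at time zero")
    C_max = float(np.max(series.C_m[sel]))
    series.time_zero = t0
    series.C_i = C_i
    series.C_max = C_max
    series.C_nor = C_max / C_i
    return series


def analyze_trace(time_s, current_A, V, pulse_freq_hz, R_s_fixed=None,
                  tol=0.08, min_window=10, C_ceiling=None):
    """Full capacitance pipeline: segment pulses, fit each transient, apply
    the time-zero rule and compute ``C_nor``.  Returns a CapacitanceSeries.
    """
    transients = segment_pulses(time_s, current_A, pulse_freq_hz, V)
    fits = [fit_transient(tr, R_s_fixed=R_s_fixed) for tr in transients]
    series = CapacitanceSeries(
        time_s=np.array([tr.onset_time_s for tr in transients]),
        C_m=np.array([f.C_tau for f in fits]),
        C_Q=np.array([f.C_Q for f in fits]),
        valid=np.array([f.valid for f in fits]),
        fits=fits,
    )
    return normalized_capacitance(series, tol=tol, min_window=min_window,
                                  C_ceiling=C_ceiling)


# ----------------------------------------------------------------------------
# Parallel-plate interpretation
# ----------------------------------------------------------------------------

@dataclass
class PlateModel:
    """Parallel-plate description of the bilayer: C = eps0 * eps_r * S / d."""

    eps_r: float           # relative permittivity (>= 1)
    area_m2: float         # membrane area S
    thickness_m: float     # membrane thickness d
    eps0: float = VACUUM_PERMITTIVITY

    def __post_init__(self):
        if self.eps_r < 1:
            raise ValueError("relative permittivity must be >= 1")
        if self.area_m2 <= 0 or self.thickness_m <= 0:
            raise ValueError("area and thickness must be positive")


def parallel_plate_capacitance(model):
    """Forward parallel-plate capacitance in farads."""
    return model.eps0 * model.eps_r * model.area_m2 / model.thickness_m


def infer_relative_permittivity(C_m, area_m2, thickness_m,
                                eps0=VACUUM_PERMITTIVITY):
    """Invert the plate model for the relative permittivity."""
    if area_m2 <= 0 or thickness_m <= 0:
        raise ValueError("area and thickness must be positive")
    return C_m * thickness_m / (eps0 * area_m2)
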