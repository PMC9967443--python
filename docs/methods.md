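# Methods

This note records the models implemented in `lipodeform`, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical decisions taken where the underlying procedure was open.

## Shape model of the synthetic liposomes

A liposome cross-section boundary is generated in polar form about its
center,

```
r(θ) = R0 · sqrt(area_scale) · s(θ; e) · (1 + Σ_k a_k cos(kθ + φ_k))
```

where `s(θ; e) = 1 / sqrt(cos²θ/e + e·sin²θ)` is the equal-area radial
factor of an ellipse with axis ratio `e` (its max/min radius ratio is
exactly `e`, and without Fourier modes the enclosed area is exactly
`π R0² · area_scale`), and the cosine modes add contour ripple. The family
is star-convex for `Σ|a_k| < 0.5`, which the scenario validator enforces.
This family was chosen because it spans the two experimentally observed
deformation types — anisotropic distortion (ellipticity, ripple) and size
change (area scale) — while keeping closed-form ground truth for AR, area
and the normalized-radius profile. Per-frame schedules of `e`,
`area_scale` and the mode envelope are shared by a cohort; a per-liposome
`shape_gain` scales each member's departure from a circle so cohorts mix
deforming and quiescent liposomes. Rupture is modeled as instantaneous
disappearance from the rupture frame onward; residual debris is not
rendered.

Default geometry: 256×256 px frames (512×512 for 20-liposome cohorts),
radius 30 px ≈ 3 µm at 0.1 µm/px (≈ 6 µm diameter liposomes), 30 s frame
interval, peptide addition after frame 4 (so a 2-minute pre-addition
baseline exists), centers on a non-overlapping grid with ~1 px frame-to-
frame jitter.

## Rendering and noise

Each boundary is rasterized as a Gaussian membrane-dye ring over a dimmer
lumen fill (fraction 0.45 of the ring peak), blurred with a Gaussian PSF
(σ = 1 px), plus background 10, Poisson shot noise and Gaussian read noise
(σ = 3). The ring centerline is drawn `ring_offset_px = 3` inside the
programmed polygon with width 1 px: the programmed polygon is the *outer
surface* of the dye shell, and with the default PSF this places the Otsu
threshold crossing of the blurred composite at the programmed boundary.
The offset was fixed once from this rasterization geometry; with it, the
segmented area of a noiseless circle matches the programmed area to ≈0.1%
(≈1% with default noise) and the measured AR of a rasterized ellipse is
within ~2% of the programmed axis ratio.

What the generator does **not** emulate: out-of-focus light and z-drift,
photobleaching, liposome-liposome contact and overlap, convective drift
beyond small jitter, rupture debris, and camera fixed-pattern noise.
Passing recovery tests therefore demonstrate correctness of the analysis
pipeline under the stated imaging model, not robustness to every
real-microscope artifact.

## Segmentation and shape metrics

Segmentation is a per-frame global Otsu threshold (per frame rather than
per stack, to track slow intensity drift), hole filling (the ring encloses
the lumen), and rejection of components below `min_area_px = 50`
(debris). A background-only frame would otherwise have its noise split in
half by Otsu, so a frame is declared empty unless the foreground/background
mean separation exceeds 6× the robust (MAD) noise level. The boundary is
the sub-pixel 0.5-level contour of the mask, smoothed by an 11-point
periodic moving average (~8 px of arc) to suppress pixelation ripple; the
smoothing window is much shorter than the distortion wavelengths of
interest (a mode-3 ripple on a 30 px radius has a ~63 px wavelength, so its
measured amplitude is attenuated by <2%).

* `AR` uses caliper (Feret) diameters of the contour's convex hull:
  maximum pairwise distance, and minimum width over edge-normal directions.
  Caliper diameters were chosen for "longest/shortest diameter" because
  they are rotation-robust and match common Fiji practice.
* The radial profile `R(θ)` is sampled at 1° steps (360 samples) by
  linear interpolation of the contour's polar representation about the
  mask center of mass; star-convexity is assumed (the generator guarantees
  it; for re-entrant real contours the interpolation approximates the
  outer envelope).
* The distortion amplitude is the RMS deviation of `R_nor(θ)` from 1.
  The choice of RMS (rather than maximum or standard deviation, both
  available as alternates) is this package's convention: for a pure mode
  `r = R0(1 + a cos kθ)` it equals `a/√2` exactly, giving a closed-form
  oracle.
* Deformation thresholds `AR > 1.1`, `ΔA > 1.1` are applied strictly, and
  the baseline `A_ave` is the mean area over present frames in the
  half-open minute `[addition − 60 s, addition)`.

## Tracking and cohort statistics

Liposomes settled in a confined chamber move little, so tracking is greedy
nearest-centroid linking with `max_jump_px = 15`; when two objects claim a
track the nearer wins. New tracks are seeded only before peptide addition,
so post-addition debris does not enter the cohort. Rupture is the first
frame of a terminal absence run of ≥ 3 frames (persistence guards against
single-frame segmentation dropouts). Time is referenced to addition: the
peptide is added immediately after the last pre-addition frame, so the
first post-addition frame is one interval after addition and all reported
post-addition times are positive minutes.

Deforming-ratio time series use a survivor denominator: a track counts in
a time bin only while it is present there, so ruptured liposomes leave the
denominator after rupture (a fixed-denominator variant is a one-line
change via the returned per-bin counts). The bin width defaults to 5 min
and is a configuration parameter. Median frame selection for the
before/after contour pair takes the lower median for even counts
(deterministic). Ties in extrema and top-k selection resolve to the
earlier frame.

## Capacitance pipeline

Pulses are segmented by locating the onset phase at the current maximum of
the first period (the charging current peaks at onset and decays
monotonically) and slicing one positive half-period per pulse. Each
transient is fitted with `I = I_ss + (I_peak − I_ss) e^(−t/τ)` by nonlinear
least squares, nondimensionalized (currents by the onset sample, time by
the window) so the pA-scale baseline and nA-scale peak are equally well
conditioned. The baseline is bounded at 0 because with `R_m ≫ R_s` the
true steady-state current lies below the noise floor. Initialization:
baseline from the tail mean, τ from a log-linear regression of the early
decay. A fit is invalid when there is no decaying component (amplitude not
clearly above the tail noise), the residual RMSE exceeds 20% of the decay
amplitude, or the optimizer fails.

Per pulse, `R_s = V / I_peak` (a global pinned `R_s` is available as an
option, matching the assumption that the access resistance is constant),
`C_τ = τ / R_s`, and `C_Q = Q/V` with `Q` the trapezoidal integral of
`I − I_ss` over the half-period. For the noiseless model over a long
window `C_Q = C_m (R_m/(R_m+R_s))²`, so both estimators agree with the
true `C_m` within `2 R_s/R_m` — better than 1% at `R_m/R_s = 10³` when the
half-period spans ≳8 τ.

**Time zero / leakage exclusion.** Leakage lowers `C_Q/C_τ` to
`R_m/(R_m+R_s)`. Time zero is the first index from which
`|C_Q/C_τ − 1| < tol` holds for `min_window = 10` consecutive valid
pulses; earlier pulses are marked invalid. `tol = 0.08` excludes any leak
with `R_m/R_s ≲ 12` deterministically while valid pulses (deviation ≲ 2%,
including finite-window charge truncation) pass with wide margin; a run of
10 is required so that noise cannot admit isolated leaky pulses. A
permanently leaky trace has no concordant window and raises an error.
`C_nor = C_max/C_i` uses the τ-based series from time zero; an optional
`C_ceiling` models the readout limit of the acquisition equipment by
truncating the valid series. `C_nor` is invariant to a uniform gain error
on the current trace, since gain cancels between `R_s` and τ.

**Simulated recordings.** The generator applies the charging law per
positive half-period and the matching discharge on the negative
half-period, with `C_m`/`R_m` piecewise-constant per pulse (membrane
properties evolve over seconds, pulses last sub-milliseconds, so each
transient has a single analytic τ). Defaults: +5 mV pulses, `R_s = 1 MΩ`,
`R_m = 1 GΩ`, tens of pF, additive Gaussian current noise at 1% of the
onset current. The default pulse frequency is 1 kHz rather than the 40 kHz
used by the amplifier in the motivating experiments: at 40 kHz a
half-period spans only a fraction of τ for these parameters and per-pulse
τ extraction is an instrument-internal procedure that is not reproduced
here; 1 kHz gives ≥ 5 τ per half-period so the decay is identifiable from
the raw trace. The frequency remains a scenario parameter. Presets:
*control* rises 50 → 70 pF and plateaus (monolayer-to-bilayer thinning,
`C_nor ≈ 1.4`); *binding* rises linearly 50 → 125 pF (progressive peptide
binding, `C_nor ≈ 2.5`); either can carry a leaky prefix
(`R_m = 10 MΩ` for the first N pulses).

The parallel-plate interpretation `C_m = ε0 ε_r S/d` is provided as a
forward model and an inverse (`ε_r` from `C_m`, `S`, `d`). The package
reports capacitance changes in farads and, separately, the inferred `ε_r`
under user-stated area and thickness; it does not assert a mapping between
a capacitance change in pF and a permittivity change.

## Problem sizes and tolerances in the test suite

Recovery tests run on one-frame single-liposome renders (256²), two
20-liposome cohorts (512², 30 and 65 frames) shared across tests, and
60–300-pulse traces; these sizes keep the full suite under a minute while
leaving every statistic well away from its tolerance. Key tolerances: AR
within 3% of programmed (2% for rotation invariance), area within 5%,
single-mode RMS amplitude within ±0.005 of `a/√2`, noiseless `C_τ`/`C_Q`
within 1% of truth, noisy per-pulse `C_m` median error below 5%, rupture
frames exact to ±1 frame.

## Known limitations

* The radial profile assumes star-convex contours; strongly re-entrant
  shapes (budding, pearling) would need a parametric arc-length profile.
* Liposomes that touch or overlap merge into one Otsu component; the
  generator keeps cohorts non-overlapping and the tracker does not split
  merged objects.
* Re-identification after rupture is out of scope: a reappearing liposome
  would be discarded post-addition rather than relinked.
* The capacitance fit assumes a single-exponential transient (one RC
  branch); multi-compartment bilayers or electrode polarization would bias
  τ.
* `C_Q` carries a small negative bias from finite-window truncation
  (`e^(−T/τ)` terms); it is used for concordance checking while the
  reported `C_m` series is τ-based.
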