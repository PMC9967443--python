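# lipodeform

Quantitative analysis of giant-liposome deformation and of bilayer
membrane-capacitance recordings, for studies of membrane-binding peptides
(cell-penetrating and antimicrobial peptides) acting on cell-sized
DOPC vesicles.

Peptides that bind a lipid bilayer distort and sometimes rupture giant
liposomes, and they change the electrical capacitance of a planar bilayer.
`lipodeform` implements both readouts as a tested, reusable pipeline:

* **Shape morphometry** on fluorescence time-lapse stacks. Each liposome
  cross-section (a bright membrane-dye ring around a dimmer lumen) is
  segmented per frame by global Otsu thresholding, tracked by
  nearest-centroid linking, and summarized by

  - the aspect ratio `AR = L_l / L_s` (longest over shortest caliper/Feret
    diameter; 1 for a circle),
  - the area ratio `ΔA = A_t / A_ave` (apparent cross-sectional area over
    the mean area during the minute before peptide addition),
  - the angle-resolved normalized radius `R_nor(θ) = R(θ) / R_ave`, whose
    RMS deviation from 1 is the contour-distortion amplitude.

  A liposome counts as deformed when `AR > 1.1` or `ΔA > 1.1` (strict).
  Cohort statistics include the rupture ratio over the observation window,
  per-time-bin deforming ratios, per-track maxima `AR_m`/`ΔA_m` with their
  times, and paired before/after contour profiles.

* **Membrane capacitance** from square-pulse current traces. The bilayer is
  modeled as capacitance `C_m` and resistance `R_m` in parallel, in series
  with access resistance `R_s`; the charging current of each pulse is

  `I(t) = V/(R_m+R_s) · (1 + (R_m/R_s) e^(−t/τ))`, `τ = R_m R_s C_m/(R_m+R_s) ≈ R_s C_m`.

  Per pulse, `C_m` is estimated two independent ways — from the fitted decay
  constant (`C_τ = τ/R_s`) and from the integrated capacitive charge
  (`C_Q = Q/V`). Leakage (low `R_m`) drives the two apart by exactly
  `R_s/(R_m+R_s)`, which yields the leakage-exclusion rule: analysis starts
  at "time zero", the first run of pulses on which the estimates are
  concordant. The headline statistic is `C_nor = C_max / C_i`, and the
  parallel-plate model `C_m = ε0 ε_r S / d` converts capacitance into an
  effective relative permittivity.

No raw recordings ship with the package. Instead, `lipodeform.synthetic`
generates seeded time-lapse stacks (~6 µm liposomes at 0.1 µm/px, programmed
ellipticity, radial Fourier-mode ripple, area drift, rupture) and
square-pulse traces (per-pulse `C_m`/`R_m` schedules, control-plateau and
continuous-rise presets, leaky prefixes) with exhaustive ground truth, so
every stage is tested as a parameter-recovery problem.

## Worked example

```python
import numpy as np
from lipodeform import synthetic, pipeline, capacitance as cap

# a liposome whose programmed ellipticity ramps 1.0 -> 1.3 -> 1.0 after
# peptide addition at frame 4 (30 s frame interval, default noise)
scn = synthetic.distortion_shape_scenario(peak_ellipticity=1.3, n_frames=34,
                                          addition_frame=4, seed=12)
stack, truth = synthetic.simulate_timelapse(scn)
tracks = pipeline.analyze_stack(stack, addition_frame=4, frame_interval_s=30.0)
ext = pipeline.extrema_analysis(tracks[0])
print(f"AR_m = {ext.ar_m:.3f} at t = {ext.t_ar_m_min:.1f} min after addition")

# a peptide-binding capacitance recording: C_m rises 50 -> 125 pF over
# 300 pulses (1 kHz, +5 mV, R_m/R_s = 1000, 1% current noise)
trace_scn = synthetic.binding_trace_scenario(seed=4)
trace, _ = synthetic.simulate_capacitance_trace(trace_scn)
series = cap.analyze_trace(trace.time_s.to_numpy(), trace.current_A.to_numpy(),
                           V=5e-3, pulse_freq_hz=1000.0)
print(f"time zero at pulse {series.time_zero}, "
      f"C_i = {series.C_i*1e12:.1f} pF, C_max = {series.C_max*1e12:.1f} pF, "
      f"C_nor = {series.C_nor:.2f}")
```

Output:

```
AR_m = 1.307 at t = 8.0 min after addition
time zero at pulse 0, C_i = 50.1 pF, C_max = 125.0 pF, C_nor = 2.50
```

The measured maximum aspect ratio (1.307) recovers the programmed
ellipticity peak of 1.3 from the noisy rendered images, at the programmed
mid-window peak time. The capacitance pipeline finds no leakage-dominated
prefix (time zero = pulse 0) and recovers the programmed 2.5-fold continuous
capacitance rise as `C_nor = 2.50` — the signature of progressive peptide
binding, as opposed to the rise-then-plateau of a peptide-free bilayer
(`C_nor ≈ 1.4` for the control preset).

## Command line

```bash
lipodeform simulate-images --scenario scenario.yaml --seed 1 --out sim/
lipodeform analyze-images  sim/stack.tiff --out results/
lipodeform simulate-trace  --scenario trace.yaml --seed 1 --out sim/
lipodeform analyze-trace   sim/trace.csv --out results/
lipodeform report          results/metrics.csv --out results/
```

Scenario YAML files either name a preset (`preset: control | distortion |
rupture` for images, `preset: control | binding` for traces) with overrides,
or spell out the full scenario. Every CSV/JSON artifact records the seed and
a configuration hash, and re-running with the same seed is byte-identical.

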