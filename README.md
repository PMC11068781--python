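# divekin

Markerless multi-camera kinematic analysis of soccer goalkeeper penalty
dives, for sports biomechanists who record dives in the field with ordinary
video cameras and a pose detector instead of a marker-based lab system.

Starting from per-camera 2D keypoint streams in the 25-landmark pose-detector
layout (BODY_25: `u, v, confidence` per landmark per frame at 120 Hz), the
pipeline produces:

1. **3D landmark trajectories** by the 11-parameter direct linear
   transformation (DLT): each camera is calibrated from surveyed control
   points on the goal frame, coordinates are gap-filled and smoothed with a
   zero-lag 4th-order Butterworth low-pass (7 Hz default, or automatic
   cutoff by residual analysis), then triangulated from two or more views.
2. **Whole-body centre of mass** (CM) by the segmental method: 14 body
   segments with standardized mass fractions `m_i` and CM position ratios
   `r_i`, so that `CM = sum_i m_i * (p_i + r_i (d_i - p_i))` over the
   segments' proximal/distal landmarks.
3. **The diving impulse cycle**: from the first frame the foot ipsilateral
   to the dive side leaves the ground to the frame of peak resultant CM
   velocity, searched up to the last ipsilateral ground contact plus six
   frames; curves are time-normalized to 0-100% on 101 nodes.
4. **Six outcome variables** per trial: peak resultant velocity (PRV, m/s),
   time to reach it (TRPRV, s), frontal step distance (FSD, m), stance
   width relative to leg length (DBLPP), frontal departure angle (FDA, deg)
   and the normalized knee flexion/extension angle curve.
5. **Statistics**: one-dimensional statistical parametric mapping (paired t
   over the normalized curves with sign-flip permutation inference and
   max-statistic family-wise control), scalar paired t tests, Cohen's d
   (`d = |m1 - m2| / sqrt((s1^2 + s2^2)/2)`), and a mixed two-way
   repeated-measures ANOVA with Bonferroni contrasts for the
   2 groups x pre/post study design.

Because raw field recordings are bulky and study-specific, the package
includes a first-class synthetic dive generator (`divekin.synthetic_data`)
that builds ground-truth 25-landmark dive motions with known events, stance
width, step length, departure angle and speed profile, renders them through
simulated DLT cameras with pixel noise and detection dropouts, and thereby
lets every pipeline stage be validated end to end.

## Worked example

```python
from divekin import (SyntheticDiveSpec, make_camera_rig,
                     analyze_synthetic_trial)

cameras, control_points = make_camera_rig("field3cam")
spec = SyntheticDiveSpec(side="right", noise_px=2.0, seed=7)
result, truth = analyze_synthetic_trial(spec, cameras)

v = result.variables
print(f"side={result.side}  PRV={v.prv:.2f} m/s  TRPRV={v.trprv:.3f} s")
print(f"FSD={v.fsd:.3f} m  DBLPP={v.dblpp:.3f}  FDA={v.fda:.1f} deg")
```

prints

```
side=right  PRV=3.35 m/s  TRPRV=0.533 s
FSD=0.456 m  DBLPP=0.741  FDA=16.9 deg
```

The dive was generated with the coached targets — stance at 75% of leg
length, a 0.45 m frontal step, an 18 degree departure angle, a 3.3 m/s peak
reached in 0.55 s — and recovered through the full chain (camera
projection with 2 px noise, gap-filling, 7 Hz zero-lag filtering, DLT
triangulation, segmental CM, event detection): PRV within 2%, the step
within 6 mm, the departure angle within 1.1 degrees.

A thin command-line front end covers the same flow on files:

```bash
divekin simulate  --out trial/ --noise-px 2 --seed 7
divekin calibrate --points trial/control_points.csv --out cams.json
divekin analyze   --trial-dir trial/ --out results/
divekin stats     --variables results/variables.csv --out results/
```

## Layout

| module | contents |
| --- | --- |
| `divekin.pose_io` | BODY_25 keypoint reading/writing, gap-filling |
| `divekin.calibration` | DLT calibration, projection, triangulation |
| `divekin.smoothing` | zero-lag Butterworth, residual-analysis cutoff |
| `divekin.body_model` | anthropometric table, segmental CM, knee angle |
| `divekin.dive_events` | dive side, foot-off/contact, PRV, normalization |
| `divekin.dive_variables` | the six per-trial outcomes |
| `divekin.stats` | permutation SPM, paired t, Cohen's d, mixed ANOVA |
| `divekin.synthetic_data` | dive generator, camera rigs, rendering, cohorts |
| `divekin.pipeline` / `divekin.cli` | orchestration, reports, command line |

See `docs/methods.md` for the modelling choices, parameter defaults and
known limitations.
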