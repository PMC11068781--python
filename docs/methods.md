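# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic generator does and does not emulate, and
the known limitations.

## Coordinate frame and landmark set

All 3D quantities live in a field frame with origin at the centre of the
goal line on the ground: X anteroposterior (positive toward the penalty
mark), Y mediolateral (positive toward the goalkeeper's left under the
default `y_positive_side="left"` mapping), Z vertical. Landmarks follow the
25-point pose-detector layout (BODY_25); the indices the analysis relies on
are hips 9/12, knees 10/13, ankles 11/14, big toes 22/19 and heels 24/21
(right/left). Frame indexing is 0-based, and the cameras are assumed
frame-synchronized on input — synchronizing unsynchronized footage is out
of scope.

## Keypoint conditioning

A keypoint with confidence 0 is missing; its coordinates carry no
information. `fill_gaps` replaces keypoints below `conf_min` (default 0.1)
by piecewise-linear interpolation between the nearest valid frames, holding
end gaps at the nearest valid value. A track with a gap longer than
`max_gap` frames (default 12, i.e. 0.1 s at 120 Hz) marks the trial
unusable rather than inventing long stretches of motion; the pipeline
records such trials as discarded with reason `gap`. Both limits are
configuration keys: field practice corrects such gaps manually, so any
automatic limit is a policy choice, and these defaults are deliberately
conservative.

## Zero-lag filtering and cutoff selection

Coordinates are smoothed in the image plane (2D), before triangulation,
with a 2nd-order Butterworth low-pass applied forward and backward — net
4th order, zero phase lag. The per-pass design cutoff is raised by the
dual-pass correction `(2^(1/2) - 1)^(-1/4) ≈ 1.247` so the −3 dB point of
the combined response sits at the requested cutoff (7 Hz default, the
standard human-movement band). Edges use odd-reflection padding of length
`min(6 * order, n - 1)`.

Automatic cutoff selection (`residual_analysis_cutoff`) follows the
classic residual procedure: the RMS difference between raw and filtered
series is computed over a cutoff grid (default 40 points from 1 Hz to
0.4 fs), a straight line is fitted to the top 40% of the grid (the
noise-dominated tail), and the selected cutoff is where the residual curve
crosses the line's 0 Hz intercept — the noise-floor estimate. Two
degenerate outcomes are handled explicitly: an intercept below `1e-4` of
the signal RMS is numerical residue rather than noise (the grid top is
returned with a warning), and a curve that never meets the noise level
falls back to the configured default with a warning.

## DLT calibration and triangulation

The 11-coefficient DLT maps metres to pixels as
`u = (L1 X + L2 Y + L3 Z + L4)/(L9 X + L10 Y + L11 Z + 1)` (v analogous
with L5–L8). Calibration solves the stacked linear system from at least six
surveyed control points by least squares; a control set whose centred
coordinates have a smallest-to-largest singular-value ratio below `1e-3` is
rejected as near-coplanar (the linear model needs volume). Triangulation
stacks the two linearized rows per camera and solves the normal equations;
all valid views are used, unweighted — confidence-weighted triangulation is
a non-goal. The synthetic goal rig places eleven control points on the
official 7.32 m x 2.44 m goal face plus back-frame depth points so the set
spans three dimensions; the rig reports its self-reconstruction error (mean
absolute error per axis when the goal is triangulated from its own
observations), which is the field's standard accuracy summary for this kind
of setup.

## Segmental centre of mass

Fourteen segments (head, trunk, and paired upper arms, forearms, hands,
thighs, shanks, feet) with de Leva-style male mass fractions and CM
position ratios, shipped as a CSV data file and validated on load (mass
fractions must sum to 1 within 1e-9, ratios in [0, 1], landmark ids in
0–24). Adaptations forced by the landmark set: the head segment runs
neck→nose with a 0.5 ratio (no vertex landmark), hands collapse onto the
wrists (no finger landmarks), feet run heel→big-toe. The table is fully
user-replaceable for other populations. CM velocity uses central
differences (one-sided at the ends); the resultant speed is the Euclidean
norm. The knee angle is the interior 3D angle at the knee between the
knee→hip and knee→ankle vectors (180° = full extension); callers preferring
the flexion convention can take 180° minus it.

## Dive-cycle events

Ground contact is decided from landmark heights: the ipsilateral foot is
"off" when both its heel and big toe exceed `ground_z + eps` (eps default
0.03 m) for at least `k` consecutive frames (default 3). The ground height
is estimated per trial as the 5th percentile of all four foot landmarks' Z
over the pre-dive standing window (default 0.4 s). A frontal-step dive
yields two off-periods: the cycle starts at the first frame of the first,
and the last contact is the final grounded frame before the last. The peak
resultant velocity is the maximum of the CM speed from the cycle start to
the last contact plus a 6-frame lookahead (50 ms at 120 Hz, excluding
gravitational free-fall from the impulse measure); ties break to the first
maximum, and the lookahead is expressed in frames so it scales with the
sampling rate only if the user overrides it. Curves are resampled onto 101
nodes (1% steps) by linear interpolation between the cycle start and the
peak-velocity frame.

## The six variables

* **PRV** — maximum resultant CM speed in the impulse window (m/s).
* **TRPRV** — `(t_prv − t_start)/fs` (s).
* **FSD** — anteroposterior big-toe displacement between the first foot-off
  and the first frame of the final off-period, signed toward the penalty
  mark. The end frame is the final departure rather than the step landing:
  the phrase "the last moment the foot leaves the ground" is read as the
  final push-off, and the choice is regression-tested on two-phase synthetic
  trials.
* **DBLPP** — heel-to-heel 3D distance divided by leg length, measured at
  the first frame of the final ipsilateral contact period (the preparatory
  posture from which the dive departs). Leg length is
  `|hip−knee| + |knee−ankle'|` at a standing reference frame, where the
  ankle's vertical coordinate is replaced by the heel's. DBLPP is stored as
  a unitless ratio; the report layer can render the x100 percentage form.
* **FDA** — `atan(|ΔX| / |ΔY|)` of the horizontal-plane CM displacement
  between the first and last ipsilateral ground contact: 0° is a dive
  parallel to the goal line, 90° straight forward. The vertical CM
  component is deliberately excluded — the angle quantifies how far forward
  of the goal line the dive departs — and the computation is isolated so a
  vertical-plane variant could be swapped in.
* **Knee curve** — the interior knee angle of the ipsilateral leg over the
  normalized cycle.

All variables are invariant to rigid world-frame translation and to
left/right mirroring, which the suite verifies.

## Statistics

**Permutation SPM.** Node-wise paired t over the 101-node curves; inference
by sign-flips of the paired differences. When `2^n` fits within the
permutation budget every sign pattern is enumerated (exact test; n = 8
pairs gives 256), otherwise patterns are sampled with the observed labeling
included. The critical threshold is the (1−α) quantile of the permutation
distribution of the maximum |t| across nodes; each maximal suprathreshold
run of the observed field is a cluster whose p-value is the fraction of
permutations with an at-least-as-long suprathreshold run. Sign flips leave
each node's sum of squares unchanged, so the permuted t fields follow from
the permuted means alone — the whole enumeration is a single matrix
product. Random-field-theory thresholds are a non-goal: permutation is
distribution-free and exactly implementable at these sample sizes. Pairing
is at the subject level (trials are averaged per subject per condition
first); for between-group curve comparisons, subjects are paired by their
within-group order, which the equal-sized groups of the study design make
well-defined.

**Scalars.** Classical paired t (two-sided); Cohen's d uses the
equal-weight pooled SD `sqrt((s1^2 + s2^2)/2)`, the convention that exactly
reproduces the published worked examples the suite pins. The mixed
two-way repeated-measures ANOVA (one between-subject factor, one
within-subject factor, one value per subject per level) is computed from
the standard mixed-design sums of squares, with the convention F = 0,
p = 1 when an effect's sum of squares vanishes — this keeps the all-equal
degenerate input well-defined, which off-the-shelf routines return NaN for.
The implementation is cross-checked in the tests against both a textbook
cell-means computation and an independent statistics package. The four
pairwise contrasts of the 2x2 design (pre-vs-post within each group,
between groups at each time point) use paired/independent t tests with a
four-fold Bonferroni adjustment. Normality/homogeneity/sphericity
assumption checks are left to standard library calls in user code; they are
not part of the implemented surface.

## The synthetic dive generator

The generator is the package's validation instrument: it builds a
25-landmark motion whose measurable properties are known, renders it
through DLT cameras, and lets the analysis chain be graded against the
construction.

A canonical right-side dive is assembled from: a standing phase (heels at
`stance_ratio x leg_length`, default 0.75 x 0.88 m); a frontal step of
`step_length` (default 0.45 m) by the ipsilateral foot, whose landing point
keeps the heel-to-heel distance at the stance target; a whole-body
horizontal displacement along the `departure_angle` direction (default
18°), with speed rising as `peak_speed * sin^4(pi t / (2 T))` to
`peak_speed` (default 3.3 m/s) over `impulse_duration` (default 0.55 s) and
decaying as the mirrored cos^4; a pelvis crouch sized so the planted-leg
interior knee angle reaches `knee_min_angle` (default 110°) at
`flexion_timing` of the impulse; and a trunk lean toward the dive. Legs are
posed by two-link inverse kinematics with a softplus-saturated effective
hip–ankle distance, so the knee approaches full extension smoothly (the
segments take up a mild virtual elongation late in the push-off instead of
producing a velocity corner the low-pass filter could not track). Foot
lift-offs blend the foot's horizontal velocity monotonically into the
whole-body velocity, with the airborne ipsilateral foot delaying its
horizontal catch-up until after the peak-velocity frame — both choices keep
the CM-speed maximum where the displacement profile puts it. The sin^4
profile itself was chosen over a half-cosine because its sharper peak makes
the discrete-time location of the maximum robust to filtering and pixel
noise; profile timing places the last ipsilateral contact five frames
before the peak, inside the 6-frame lookahead with margin for noise.

Because the CM aggregates planted and moving segments, the raw construction
would undershoot the peak speed by a few percent and bias the departure
direction slightly; a deterministic fixed-point calibration (four rebuilds)
scales the speed profile and rotates the heading until the measured PRV and
FDA equal the requested targets. Ground truth is then obtained by applying
the variable definitions to the noiseless trajectory, making it
self-consistent by construction; what the end-to-end comparisons actually
exercise is the measurement chain (projection, noise, dropouts, gap-fill,
filtering, triangulation, event detection). Left-side dives are exact
mirror images (Y negated, left/right landmarks swapped), so mirror
invariance holds to machine precision.

Rendering projects every landmark through each camera, adds i.i.d.
Gaussian pixel noise, draws per-keypoint dropouts (confidence 0), and flags
landmarks behind a camera as dropouts. Everything is deterministic given
the spec and seed.

**What the generator does not emulate** — and hence what passing tests do
not show about real footage: pose-detector error is not i.i.d. Gaussian
(it is structured, landmark-dependent and occasionally catastrophic);
real dives involve trunk/pelvis rotation and arm swing dynamics the
rigid-offset upper body only sketches; segment lengths are constant in real
bodies whereas the generator trades that for band-limited knee motion late
in the push-off; the contact model is a hard ground plane with no shoe or
turf compliance; and camera models are ideal pinholes without lens
distortion. Validation on this generator demonstrates the correctness of
the computational chain, not the field accuracy of pose detection.

The study-shaped cohort generators produce either per-trial variable tables
directly (fast, for exercising the statistics: 2 groups x 4 subjects x
pre/post x both sides x 4 trials, with configurable effect shifts applied
to the video group's post condition and/or the non-dominant side) or lists
of full dive specs for end-to-end runs. Baseline means and dispersions are
set to field-typical magnitudes for youth goalkeepers (TRPRV ≈ 0.55 s,
FSD ≈ 0.37 m, DBLPP ≈ 0.75, FDA ≈ 14°, PRV ≈ 3.3 m/s).

## Pipeline policy

Stages run in the field-processing order (gap-fill → 2D smoothing → DLT →
CM → events → variables). A trial failing any quality rule is flagged
discarded with a machine-readable reason (`gap`, `side`, `events`,
`cycle`, `angle`) and excluded from statistics, so processed = kept +
discarded always holds. Every constant is a named key in `RunConfig`
(YAML-loadable): filter cutoff 7 Hz, 6-frame lookahead, 101 nodes,
α = 0.05, contact eps 0.03 m, k = 3, conf_min 0.1, max_gap 12. Identical
config and seed reproduce bit-identical outputs.

## Problem sizes used in validation

The shipped suite and the acceptance script validate on: 1000-point DLT
round-trips; 100-pose CM oracles; 50 (suite) / 20 (script) noiseless dives
plus 20/10 dives at 2 px noise for event and variable recovery; 1000 null
cohorts of 8 paired curves for the SPM family-wise error rate (exhaustive
256-flip inference per cohort); and single balanced 2x2 designs for the
ANOVA oracle. These sizes keep a full run in seconds while leaving the
Monte-Carlo intervals tight enough to be informative.

## Known limitations

* Temporal camera synchronization is assumed, not estimated.
* The foot-contact threshold rule is a declared substitute for whatever
  manual or implicit criterion is used in field studies; it is validated
  only on synthetic data.
* Whether the plotted knee angle in field reports is the interior angle or
  its supplement is convention-dependent; the interior angle is the
  default here and the supplement is one subtraction away.
* DBLPP's reference instant (start of the final contact period) is an
  interpretation of "the first moment of the last contact"; it is isolated
  in one function argument.
* The SPM between-group pairing by within-group order is only meaningful
  for equal-sized groups, as in the study design this package mirrors.
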