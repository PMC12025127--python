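# Methods

## Coordinate conventions

All geometry lives in a right-handed camera frame with the camera at the
origin and lengths in centimetres (the unit of the published scene tables).
The default target board is parallel to the camera X–Y plane at
Z = −398.3 cm with seven named targets; the five protocol subject positions
sit at depths 55–340 cm. The board-target X/Y magnitudes (±576–603 cm) are
taken verbatim from the source tables even though they are large for a
board at 398.3 cm; they parameterise the scene, nothing in the algorithms
depends on their plausibility.

## Eyeball-center estimator

The eye is a sphere of radius R; landmarks are the two corners C₁, C₂, a
frontal surface point O′ₑ and the iris center Oᵢ. With C the chord midpoint,
h = |O′ₑ − C| and c = |C₁ − C₂|, circle geometry (intersecting chords /
sagitta) gives R = h/2 + c²/(8h); the center is O′ₑ + R·normalize(C − O′ₑ)
and the gaze ray is the anatomical axis center→iris. Choices worth noting:

- **What O′ₑ is.** The relation is exact only if O′ₑ is the arc midpoint
  over the chord, i.e. a surface point on the eye's frontal axis. The
  landmark provider is expected to supply such a point; the synthetic
  generator places it on the head's rest-pose forward axis. It is an input,
  not a constant.
- **Noisy landmarks.** C is always the exact chord midpoint and h is used
  directly even when O′ₑC is not perfectly perpendicular to the chord; the
  resulting bias shows up in the noise-sensitivity tests rather than being
  corrected ad hoc. With h ≈ R(1 − cos 40°) ≈ 0.28 cm for a 1.2 cm eye, the
  method is strongly noise-sensitive — which is why it is gated to close
  range.
- **Binocular combination.** The two monocular rays are merged with
  midpoint origin and normalised mean direction; if one eye's geometry is
  degenerate the output degrades to monocular, and only when both fail does
  the frame fall back to the head method (flagged) or become invalid.
- **No kappa-angle correction**: the anatomical axis stands in for the
  visual axis.

## Head-orientation estimator

Five face joints with Azure-Kinect-style confidences in {0 out-of-range,
1 occlusion-predicted, 2 moderate, 3 high}; a joint is trusted iff its
score ≥ 2. The gaze ray starts at MN (centroid of the two eye joints and
the nose) along ME→MN (ME = ear midpoint). The nose drags MN below the
eye line, compensating the upward tilt a pure eye–ear axis would have, and
MN is the natural forward face-center origin.

Occluded joints are recovered rigidly: the last frame in which all five
joints scored ≥ 2 becomes the template; a Kabsch least-squares rotation +
translation (SVD with the determinant forced to +1, so reflections are
impossible) is fitted from template to the ≥ 3 trusted joints and applied
to the missing ones. Fewer than three trusted joints, or a collinear
support (second singular value ≤ 1e-9 of the first), fails recovery and
the frame's head estimate is invalid. Templates are never refreshed from
frames containing recovered joints, preventing drift.

## Distance gate and per-frame pipeline

The gate compares |Z| of MN with a 70 cm threshold: at or below it the eye
method is used (eye landmarks are detailed enough), above it the head
method. Depth rather than Euclidean distance is used because the protocol's
"positions" are depths; with the tabulated 143 cm vertical offset a
Euclidean gate could never select the eye method. When the eye method is
gated on but unavailable (missing or degenerate eye landmarks) the frame
falls back to the head method with a `fallback` flag; frames where neither
method works are emitted invalid rather than dropped, keeping per-second
valid-frame denominators honest. `force_method="eye"|"head"` bypasses the
gate for method comparisons. The selected ray is intersected with the
scene's target plane (miss/behind-origin is a no-hit, not an error) and
with every configured head sphere; spheres anchored to a person use that
person's most recently resolved MN, and a person's own sphere is skipped.

## Interaction periods and metrics

Frame-level sphere hits are binned to whole seconds: a second is a hit iff
hit-frames / valid-frames ≥ `frame_fraction` (default 0.5); seconds with no
valid frames are non-hits. Runs of hit-seconds become closed [start, end]
intervals; gaps ≤ `max_gap_s` (default 0) are merged and merged runs with
span end − start < `min_duration_s` (default 1 s, matching the shortest
annotated periods) are discarded. A run of hit-seconds {337, 338} is
reported as 5:37–5:38, mirroring mm:ss annotation granularity. Mutual gaze
is the per-second AND of the two directed streams under the same rules.

Interval IoU is (min(Eₜ,Eₚ) − max(Sₜ,Sₚ)) / (max(Eₜ,Eₚ) − min(Sₜ,Sₚ)),
clipped to 0 for disjoint pairs (the raw formula would go negative, and the
nearest-neighbour fallback rows below need a defined value); two identical
zero-length intervals score 1. OBOA is the indicator that truth and
detected durations differ by ≤ 1 s (seconds are the only unit consistent
with the published 0/1 pattern). Matching is greedy in descending IoU, each
detection used at most once; truth periods with no positive-IoU candidate
are paired with the nearest unused detection by start time so every
annotated period yields a scored row; leftover detections are false
detections. Session means are taken over matched truth rows (for the first
recorded session, 11 rows — the only denominator consistent with the
published 0.67/0.73), with rounding applied only at presentation.

### Packaged session tables and a known inconsistency

The truth and detected period lists of the two recorded child–clinician
sessions ship as CSV under `rgbdgaze/data/`. Recomputing the metrics
reproduces every published Session-1 IoU/OBOA cell and the 0.67/0.73
averages, and the Session-2 rows starting 7:32, 11:49 and 22:20. The
published Session-2 row "40:04–41:06 / 1.000000 / 1" is internally
inconsistent with the IoU formula applied to its own tables (truth
40:04–40:11 vs detection 40:04–41:06 gives 7/62 ≈ 0.112903 and OBOA 0), so
the published Child-2 averages (0.75/0.73) are not recomputable; this
package reports the formula's values and makes no attempt to "fix" the row.
For Session 1, 45:18–45:20 is treated as truth and 45:17–45:19 as the
detection, per the two tables' roles.

## Synthetic generator

The generator emulates a fused, single-stream skeletal feed at 30 FPS:

- **Head**: a rigid five-joint template (ears (±7, 1, 0), eyes (±3, 0, −8),
  nose (0, −4, −10) cm about the head center — invented, anatomically
  plausible proportions, fully configurable) rotated so the ME→MN axis
  points *exactly* at the scripted target. Because the ray origin MN moves
  with the rotation, the aim is solved by fixed-point iteration to
  ~1e-13 rad.
- **Eyes**: eyeball spheres of radius 1.2 cm (adult average) at the eye
  joints; corners fixed in the head frame at ±40° from the forward axis,
  O′ₑ on the forward axis, iris displaced along the true per-eye gaze
  direction. Corners being head-fixed while the iris follows gaze lets the
  eye and head methods disagree under eye-in-head rotation, as in real
  data.
- **Corruption**: isotropic Gaussian noise (σ cm) per landmark coordinate
  and independent joint demotion to confidence 1 with probability p. The
  standard-normal draws are made unconditionally and scaled by σ, so a
  fixed seed produces a noise field that grows continuously with σ — the
  mean-error-vs-σ battery is then a near-deterministic monotonicity check
  rather than a fragile stochastic one.
- **Two-person sessions**: a "child" at (−50, 0, 150) and "clinician" at
  (50, 0, 150) cm face each other ~1 m apart; scheduled intervals (closed
  whole seconds) orient the gazer at the other's actual MN (a joint
  fixed-point, since each MN moves as its owner turns), otherwise at an
  away-point chosen ~1 m clear of both heads. The schedule is the exact
  ground truth for period recovery. An `active_seconds` mask generates only
  the occupied parts of long timelines; absent seconds binarise to
  non-hits, so sparse generation is exact for period extraction.

What the generator does **not** emulate: depth-sensor noise spectra,
landmark detector failure modes (profile faces, glasses), skeleton identity
swaps, or multi-camera fusion artefacts. Passing tests therefore establish
the correctness of the geometry, gating, recovery and metrics — not the
field accuracy of any landmark detector.

## Problem sizes and numerics

Zero-noise end-to-end checks use 15–300-frame sessions per depth/method;
the noise battery uses 500 frames per σ ∈ {0, 0.1, 0.3, 0.5} cm; the
scripted-schedule recovery drives the full 30 FPS pipeline over the
occupied sub-intervals (~220 s, two persons) of the 48-minute Session-1
timeline — sizes chosen to exercise every code path at full rate while
keeping the suite fast. Angles are computed as atan2(|v₁×v₂|, v₁·v₂),
exact near 0° and 180° where arccos of a clamped dot loses ~1e-8 rad.
Ray–plane intersections behind the origin (t ≤ 0) and rays parallel to the
plane are no-hits; ray–sphere tangency counts as a hit. Plane normals get a
deterministic sign (first non-zero of z, y, x made positive). Degenerate
landmark configurations raise typed errors at the operation level and are
converted to flagged invalid frames at the pipeline level.

## Known limitations

- The eye model ignores corneal refraction and the kappa angle; at
  clinical ranges the head method dominates anyway.
- Period endpoints are whole seconds; sub-second interaction dynamics are
  out of scope by construction.
- The binocular combination rule (midpoint/mean) is a documented package
  choice; monocular-vs-binocular output is not configurable per frame.
- Real angular-error benchmarks require the original restricted
  recordings; the synthetic-exactness and monotone-degradation properties
  are the substitute evidence this package can provide.
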