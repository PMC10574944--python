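# Methods

This note records the models, parameter choices and numerical decisions
behind `climbkit`, and what the synthetic validation does and does not
demonstrate.

## Problem setting and assumptions

The input is a fixed-rate stream (default 60 fps) of 13 body joints in
3-D, millimetres, from any keypoint detector plus depth source.  The
analysis assumes:

* the climbing wall is planar and rectangular, possibly tilted, and is
  visible without the climber at calibration time;
* the camera is static for the duration of a recording (different
  recordings may use different camera poses — calibration makes them
  comparable);
* the climber ascends: the route is delimited by the lowest hip position
  and the highest wrist position, and a recording without net hip rise is
  rejected;
* joint estimates carry zero-mean jitter of a few millimetres and
  occasional short spike artifacts; both are explicitly modelled and
  filtered.

Confidence scores, when present in the input, are carried through but not
consumed: the rules operate on geometry alone.

## Wall calibration

RANSAC (500 iterations, 20 mm inlier tolerance, seeded) fits the wall
plane; the consensus set is refined by a total-least-squares plane and
the inlier set recomputed once.  The unit normal is oriented toward the
camera origin — cameras always face the wall — which fixes the sign
conventions downstream: positive *z* in wall coordinates means "away from
the wall, toward the climber".

The wall rectangle is the minimum-area enclosing rectangle (rotating
calipers over the convex hull) of the inliers projected in-plane.  Corner
ordering is anchored in a gravity-aligned in-plane frame built from an
`up_hint` (default camera +y): the origin corner maximises (up − right),
which is robust to the near-tie in height between the two top corners
under noise, and the first edge walked is the more horizontal one — the
top edge.  The wall *y*-axis points up, so wall-interior points have
negative *y*; the *x*-axis completes a right-handed frame (x × y = z) and
therefore points to the *wall's* right, i.e. camera-left.  On synthetic
tilted walls with 5 mm plane noise and 10 % outliers the normal is
recovered to ≈0.015° and corners to ≈5 mm (bounds asserted: 0.5°, 10 mm).

Rectangle extraction assumes outliers do not lie within the inlier slab
of the plane itself: a point 2 cm off a wall is indistinguishable from
wall surface relief.  The synthetic clouds therefore model clutter as
points 100–2000 mm in front of the plane, which RANSAC rejects cleanly.

## Speed estimation and motion segmentation

Joint speed is a centred finite difference of the wall-plane-projected
position (edge frames replicated), times the frame rate.  Two filters act
on the velocity *components* before the magnitude is taken:

* a **median filter** (`spike_window`, default 7 frames) removes the
  paired velocity impulses that an isolated keypoint spike produces,
  without displacing step edges.  Spikes are worth removing early: they
  would otherwise inflate the global envelope maximum Ok and, through the
  50 %-of-Ok rule below, raise the motion threshold past genuine
  movements;
* a **moving average** (`smooth_window`, default 15 frames ≈ 0.25 s)
  cancels zero-mean jitter.  Smoothing the rectified magnitude instead
  would leave a noise floor of order E|jitter velocity| (≈170 mm/s at
  σ = 5 mm, 60 fps) that no amount of averaging removes; smoothing the
  vector reduces it to ≈45 mm/s, an order of magnitude below typical limb
  speeds (300–700 mm/s).

The motion envelope is `g = rolling_mean(v, window) + n·rolling_std(v,
window)` with `n = 2` and a deliberately short `window` of 3 frames, the
smoothing having already been done in the speed estimate.  A wide
envelope window is counterproductive here: the mean+2σ statistic of a
window of width W displaces the 50 %-crossing by roughly 0.4–0.6·W frames
per side, so W around one second would stretch every detected movement by
nearly a second — incompatible with judging a 1 s supporting-hand limit —
whereas W = 3 keeps the boundary error at ±1–3 frames.  Frames with
`g ≥ rho·max g` (rho = 0.5) are motion; maximal runs shorter than
`Kμ = 30` frames are discarded as jitter.  Using the *global* maximum Ok
makes the threshold scale-free per joint but means a movement at less
than half the speed of the fastest movement of the same joint is
invisible; a warning is emitted when detected segments differ by more
than 4× in peak speed.  The standard-score transform `z = (v − μ)/σ` uses
the population σ over the whole series, so results do not depend on
series length conventions.

## Route delimitation

`rs` = first frame of the first half with the lowest hip-centre *y*;
`re` = last frame of the second half at which either wrist attains its own
maximum *y*.  Both rules are applied to the full recording, and all
downstream analysis is restricted to `[rs, re)`.  Note that on data where
the relevant extremum is a plateau (a climber hanging motionless), the
arg-extremum under jitter is uniform over the plateau; the synthetic
generator avoids this by construction (see below), and real recordings
avoid it naturally because climbers walk in and pull on.

## Phase machine

States: preparation (feet moving, hands holding), reaching (feet set, hip
rising or a hand moving), stabilization (hands and hip still).  The
per-frame set definitions of these phases can overlap, so the machine is
state-aware and walks only the physiological cycle stabilization →
preparation → reaching → stabilization, testing the single outgoing edge
of the current state each frame.  This both resolves conflicts (foot
motion wins while stabilizing, matching how preparation begins) and
guarantees the cyclic order of the output.  The initial state is
stabilization — a climber hangs static at the start hold.  A state
persists at least `min_phase_frames` (default 5) before it may
transition, absorbing single-frame flicker at motion-interval boundaries
without ever skipping a cycle step.  Hip-*y* motion alone (without hand
motion) does trigger reaching, implementing the disjunction literally.

On the noiseless synthetic suite the frame-level agreement with the
scripted phases is ≈99 % (bound asserted: 90 %); boundary errors are 2–3
frames per transition.

## Hand roles

The holding hand is the higher wrist, resolved *per frame* with ties
keeping the previous assignment.  Per-frame resolution matters for the
supporting-hand timer: during a reach the moving hand starts below the
other wrist (supporting) and stops counting the moment it passes it
(holding).  A decisive 1.5 s reach therefore accumulates only ≈0.75 s of
supporting-hand motion and is not an error; a hesitant reach that stays
below the other wrist beyond `Kt = 1 s` is.  Under the alternative
(per-phase) resolution every normal reach longer than 1 s would be
flagged, which contradicts the defaults.

## Error rules

| rule | phase | condition (flag when) | defaults |
|---|---|---|---|
| decoupling | preparation | holding-arm φ < Kϕ or ϑ < Kθ | 130°, 120° |
| reaching hand supports | reaching | supporting hand in motion > Kt | 1 s |
| weight shift | reaching (middle half) | signed knee−ankle x < Kdknee | 200 mm |
| both feet set | reaching | a foot moving or z > eps_contact | 150 mm |
| hip close to wall | reaching | hip z − coupled reference hip z ≥ Kdhip | 50 mm |
| shoulder relaxing | stabilization | holding-arm φ < Kϕ or ϑ < Kθ | 130°, 120° |

Numerical choices:

* Angle-based flags suppress runs shorter than `min_event_frames`
  (default 5) — single-frame jitter in a 300 mm limb moves the angle by a
  couple of degrees and must not produce events.
* The weight-shift x-component is signed toward the direction of hip
  travel within the phase, so "knee in front of the foot" is
  well-defined for either leg and either traverse direction.  The travel
  direction is read from medians of the first and last ~10 phase frames;
  a single corrupted boundary frame must not flip it.  Only the middle
  half of the phase is examined: at the beginning and end of a stand-up
  the knee legitimately trails the foot.
* A literal "foot off the wall plane" test is physically unusable — feet
  on bolted holds always stand several centimetres proud — so wall
  contact means z within `eps_contact` = 150 mm, configurable.
* The hip comparison requires a same-route reference climb; without one
  the type is reported as not evaluated (`null`), never silently zero.
  Where DTW couples several reference frames to one query frame the
  minimum reference hip-z is used (the strictest comparison).  A warning
  is emitted when the torso lengths of climber and reference differ by
  more than 10 %, since a fixed 50 mm allowance does not transfer across
  body sizes.
* Per-phase aggregation counts at most one error of a type per phase
  instance — repeated flags within one movement are one mistake.

## DTW alignment

Two climbs of one route are aligned on scalar series: the Euclidean
distance of the wall-plane-projected hip centre from the wall origin.
The coupling is the classic O(n·m) dynamic programme under |·| cost with
boundary-complete, monotone, unit-step pairs; traceback ties prefer the
diagonal, so the most synchronous optimal coupling is returned.  No
warping window is applied by default (recordings are ~20 s); the
implementation is validated against exhaustive enumeration of all legal
couplings for short series.  One caution: DTW legitimately "absorbs" a
constant offset on a monotone series by matching equal-valued earlier
frames — the accumulated distance is not offset × length, which is why
the hip-standoff rule compares z-values through the coupling rather than
using the DTW distance itself.

## Evaluation

1-D IoU between detected and labelled frame intervals, half-open
convention.  Matching is per error type, greedy one-to-one by descending
IoU.  A matched pair at IoU ≥ τ is a true positive; below τ the label
counts as a false negative and the detection is consumed; false positives
are reserved for detections with zero overlap against every label.  This
deviates from common object-detection practice (where a sub-threshold
match is also an FP) and is deliberate; TP + FN always equals the label
count.  The precision–recall sweep uses 20 equispaced thresholds in
(0, 1]; the reported operating point maximises F1 with ties resolved
toward the stricter threshold.  Precision–recall is used rather than ROC
because error frames are rare relative to non-error frames.  When several
recordings are evaluated together, TP/FP/FN are pooled before the ratios
are taken.

## The synthetic rig

The generator keyframe-animates the 13 joints through repeating cycles
— preparation 150 frames (two overlapping 100-frame foot steps of
+500 mm), reaching 100 frames (the lower hand rises 1000 mm in 90 frames
at ≈670 mm/s while the hip rises 500 mm and drifts 30 mm laterally),
stabilization 90 frames — on a 3 × 4 m wall, 60 fps, with a 60-frame
lead-in and 90-frame tail.  Elbows are placed to realise a scripted
interior angle (default 172°); knees lead their ankles by 300 mm in the
travel direction; feet and hands sit 30 mm off the wall, the hip 200 mm.
Three details exist to make the route extrema scripted events rather than
plateaus: the hip starts 40 mm low and rises as the climber pulls on; the
final reach overshoots its hold by 30 mm and settles (a deadpoint catch);
and both wrists sag 20 mm through the final stabilization at a rate far
below the motion floor.

Injected errors violate exactly one rule inside a known window: elbow at
110° well inside a preparation or stabilization (25-frame margins so
detected phase boundaries cannot leak flagged frames into a neighbouring
phase), knee lead reduced to 100 mm in the middle half of a reach, one
foot raised to 300 mm, hip pushed 100 mm farther from the wall, or a
slowed reach — a 10-frame downward regrip followed by a 493 mm/s rise
over 150 frames, keeping the hand below the other wrist for ≈1.4 s.  The
slowed reach is deliberately *not* modelled as a uniformly slow creep:
at 375 mm/s it would sit at exactly half the same wrist's fast-reach
envelope, i.e. at the detection rule's own floor, and no detector could
see it; the regrip-then-steady-rise profile keeps the movement above the
floor while still exceeding Kt.

Noise is i.i.d. Gaussian jitter per joint per axis (default σ = 5 mm)
plus 5-frame spike artifacts of 40 mm in a random direction with
probability 0.01 per joint-frame.  Everything is deterministic given the
script seed, and the pre-noise geometry is identical across seeds.

The validation suite pairs every error type (two scripts each, varying
the injected cycle) with clean climbs at σ = 0 and σ = 5 mm;
hip-standoff cases carry their noiseless clean counterpart as the
reference climb.

**What passing shows — and does not.**  On this suite the pipeline
achieves zero clean-climb events, ≥ 0.66 IoU recovery of every injection,
a diagonal cross-talk matrix, and per-type max-F1 operating points at
precision = recall = 1.0.  This demonstrates that the rules, thresholds
and segmentation are mutually consistent and robust to the modelled noise
— not field performance.  Real recordings add what the rig deliberately
omits: occlusion-induced keypoint dropouts and biases (not zero-mean),
depth-sensor range limits, body-proportion variation, camera motion, and
genuinely ambiguous technique.  Synthetic results should therefore be
read as an upper bound and a correctness check, not a performance claim
for real video.

## Known limitations

* The global-Ok threshold can miss slow movements on joints that also
  move fast (warned, not fixed); a per-segment or adaptive threshold is
  the natural extension.
* The phase machine cannot revisit preparation directly from reaching;
  a climber who re-sets their feet mid-reach is segmented as an extended
  reach until the hands come to rest.
* The hip-standoff rule inherits every limitation of the reference climb,
  including its body proportions.
* 2-D→3-D lifting takes the mean of the three nearest depth nodes; depth
  discontinuities at the climber's silhouette can still bleed wall depth
  into limb joints, which is an upstream data problem, not addressed
  here.
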