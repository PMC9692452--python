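# Methods

## Scope and model

`ergorula` scores upper-limb posture risk per fused frame using the RULA
worksheet: segment scores for upper arm (1–6), lower arm (1–3), wrist
position (1–4), wrist twist (1–2), neck (1–6), trunk (1–6) and legs
(1–2); table-A and table-B lookups for the section scores; table-C for
the grand score (1–7); and the four risk levels (1–2 negligible, 3–4
low, 5–6 medium, 7 high).  Muscle-use and force/load inputs exist in the
engine interfaces but default to 0, and the neck-twist adjustment is not
computed: the assessment protocol this package implements excludes them.
The legs score defaults to 2 (standing, legs and feet unsupported).

The three lookup matrices are fixed published constants, transcribed
once into `rula_tables.py` and audited at import: exhaustive
monotonicity along every argument, codomain bounds, and a SHA-256
checksum printed by `ergorula --version`.

## Geometry conventions

All angles are degrees (every scoring threshold is printed in degrees).
`vector_angle` is computed as atan2(|a×b|, a·b) — identical in value to
the clamped-arccos cosine formula but numerically accurate near 0° and
180°, where the cosine saturates; this matters because fixtures and
neutral postures sit exactly at those ends.  `three_point_angle(a, b, c)`
is the angle between the segment vectors b−a and c−b: 0° for a straight
chain, i.e. the *supplement* of the interior angle at b.  This is the
convention under which the printed lower-arm band (60°, 100°) → score 1
reads as elbow flexion from a straight arm.  Collinearity tolerance for
plane normals is 1e-9 relative to operand scale.

Signed angles (upper arm, neck) take their sign from the projection of
the distal joint onto the anterior normal of the frontal plane,
estimated as (hip_R − neck) × (hip_L − neck); with a y-forward,
right-hip-first skeleton this points anterior.  The trunk position is
180° − angle(head→waist vector, vertical axis), so an upright trunk
reads 0° and a 40° forward flexion reads 40°.

Band boundaries are lower-inclusive / upper-exclusive, except where the
worksheet prints a strict ">" (e.g. shoulder raised at >90°, abducted at
>20°, wrist bands ">15° up/down").  Bands printed as exactly "0°" (trunk
position, wrist flexion–extension) use a neutral half-band of 1°
(config key `neutral_band_deg`), shared between trunk and wrist.

## Wrist kinematics

Calibration captures, per side, the palm-plane normal through (middle
proximal-phalanx endpoint, thumb metacarpal endpoint, pinky metacarpal
endpoint) and the neutral radial–ulnar chain angle, from the first frame
in which all scoring joints are present (policy `first_valid`; a fixed
frame index can be pinned instead).

- *Flexion–extension*: the two-point cosine formula is origin-dependent
  as printed; the default `literal` mode applies it to position vectors
  from the sensor origin, the `recentered` mode first translates both
  points so a configurable wrist-reference joint (default joint 00) is
  the origin, making the measure translation-invariant.  Both are
  implemented and tested; `literal` is the default because it is the
  formula as stated.
- *Radial–ulnar deviation* is measured relative to the calibration pose:
  the raw chain angle of a neutral wrist is far from 0° (≈106° on the
  synthetic hand), so only a calibration-relative reading makes the 15°
  threshold meaningful.
- *Pronation–supination* is the angle between current and calibration
  palm normals, in [0°, 180°] (rotations beyond 180° fold back).  The
  end-of-range adjustment reuses the same plane angle; the twist score
  is 2 whenever it exceeds 105° (values above the printed 165° band edge
  map to the nearest band, i.e. still 2), otherwise 1.

Because the lifted middle-finger joint both defines flexion–extension
and spans the palm plane, a non-zero flexion necessarily tilts the
measured palm normal (≈41° at 25° of flexion on the synthetic hand).
The two measures are therefore not independent; the fixture generator
treats the pronation–supination target as optional and verifies joint
realisability, raising a feasibility error for inconsistent pairs such
as (flexion 25°, pronation 0°).

## Formula couplings (properties of the printed formulas)

Several worksheet formulas share joints, which couples segments in ways
any implementation inherits.  These were verified numerically and are
asserted in the tests rather than hidden:

- The lower-arm "out to the side" joints coincide with the upper-arm
  position joints, so that adjustment fires exactly when the upper-arm
  position angle exceeds 30°.
- A small upper-arm position angle forces the elbow direction close to
  the hip→shoulder line; with the shoulder-raise chain angle held ≤90°
  the abduction chain angle is then confined to ≳45° (right side) or
  ≈70° (left side, where the neck side-bending formula pins the left
  shoulder laterally).  A fully adjustment-free arm consequently does
  not exist for every position band; segment scores expose `base` and
  per-adjustment `components` separately so the band mapping is always
  observable.
- The trunk-twist metric (departure of the hip-to-waist vector from the
  frontal-plane normal, 90° at neutral) is bounded by the hip chain
  angles: it can exceed the 20° threshold only when both trunk
  side-bending chain angles are ≈30° or more, so a twisted trunk always
  carries the side-bending adjustment too.
- The left shoulder-raise token "19" has no published identity.  Mapped
  to the left shoulder, the chain 04→10→02 doubles back (~160°) for any
  lateral shoulder, i.e. the adjustment would always fire; the default
  registry therefore maps "19" to the torso joint "03", under which the
  formula measures the torso joint's departure from the waist–neck line
  (≈0° upright, a spine-bend proxy).  The mapping is provisional and
  config-overridable (`alias_19`).

## Preprocessing

PAA segments are the half-open index windows [⌈(i−1)n/N⌉, ⌈i n/N⌉),
which reduce to n/N equal windows whenever N divides n (then the global
mean is preserved exactly).  N = round(duration × 20 Hz); output
timestamps are segment centres on the grid anchored at the stream start.
Nulls are excluded from segment means; a fully-null segment propagates
null so the row-dropping stage still sees it.  Fusion joins by nearest
grid timestamp with a maximum offset of half a grid step; labels attach
by interval containment (each label row spans until the next).  A fused
frame is dropped only when a joint referenced by some scoring formula is
null — a missing knee keeps the frame.

## Evaluation statistics

Similarity between one expert and one system score is
1 − |es−ss|/(es+ss) ∈ (0, 1]; strata are (segment, side, high-level
activity) with the mean over the expert-labelled rows (stride default
10 fused rows = 0.5 s; labels apply to their own row only, no forward
fill).  The subject comparison runs a one-way ANOVA over per-frame grand
scores grouped by subject and all pairwise two-sample t-tests —
Student's equal-variance by default (the classical ANOVA companion),
Welch optional; no multiple-testing correction by default, Bonferroni
and Holm available.  Identical samples are reported as p = 1 rather than
NaN.  Subjects with fewer than two frames are excluded with a warning.
All frames are pooled per subject (per-activity aggregation is a
caller-side groupby away).

## Synthetic data generator

The generator inverts the scoring geometry.  Hand poses are constructed
in closed form from a flat 25-joint template (millimetre scale, palm
normal +z, the calibration pose): the index joint is repositioned
in-plane for the radial–ulnar target, the middle proximal endpoint is
lifted for flexion–extension, and the whole hand is rigidly rotated
about an origin axis for pronation–supination (origin-axis rotations
preserve the other two measures); every constructed hand is re-measured
with the scoring functions and must match its targets to 1e-6°.

Body poses cannot be constructed limb-by-limb because of the formula
couplings above, so they are solved: the trunk/neck pair analytically in
the sagittal plane, hip side-bends exactly by construction with an
antisymmetric twist rotation found by root-finding, and each arm by
scanning the shoulder cone (raise angle about the trunk axis on the
right; the 90°+side-bend cone about the head direction on the left,
which is what the neck side-bending formula pins) for a configuration
whose elbow two-cone intersection has the anterior sign the signed
position target requires and whose wrist azimuth admits the
across-midline root.  A damped least-squares polish over 18 direction
parameters is the fallback; any targeted formula left >1e-6° raises a
feasibility error naming the residuals.  Targets set to None are
unconstrained and their achieved values are reported in the ground
truth.

Limb lengths are fixed arbitrary constants (trunk 0.45, shoulder 0.20,
arm segments 0.25, hip 0.12 in nominal metres) — every scored quantity
is an angle, so scale cancels.  Jitter is applied as small random
rotations of each joint about the skeleton root (waist / sensor origin),
which perturbs angles at the requested standard deviation while
preserving root distances; dropouts null whole joints per frame with the
given probability.  All randomness flows from one seed.

What the generator does **not** emulate: real sensor noise spectra,
occlusion-correlated dropouts (e.g. a drawer blocking the camera),
biomechanically realistic motion dynamics between postures, or
anatomically plausible proportions in poses that realise extreme formula
targets (a "formula-neutral" arm points up along the hip–shoulder line).
Passing round-trip tests therefore demonstrates correctness of the
geometry→score mapping, not robustness to real capture artefacts.

## Problem sizes

The default test and acceptance runs use the built-in five-activity
session: 10 s, 300 body frames (30 Hz), 640 hand frames (64 Hz), 200
fused frames (20 Hz), expert labels every 10th row.  The type-I-error
check simulates 1,000 replicates of 4 subjects × 40 frames from a common
score distribution and verifies the ANOVA rejection rate is within two
Monte-Carlo standard errors of α = 0.05.  Pose solving is cached per
target set; the full suite runs in well under a minute on one CPU.

## Known limitations

- The anatomical identity of body tokens is a documented convention
  (Orbbec-style indices are not published with the formulas); scoring a
  real recording requires checking the registry mapping first.
- The literal flexion–extension mode depends on the sensor origin; use
  `recentered` when absolute hand position varies during a session.
- Sign conventions for flexion vs extension rest on the hip-based
  anterior normal; strongly twisted hips rotate that normal, which can
  flip the neck/upper-arm sign relative to intuition.
- Expert-agreement numbers on synthetic sessions are self-referential
  (labels derive from ground truth or system output); they validate the
  pipeline's internal consistency, not human-rater agreement.
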