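# Methods

This note records the models behind `tracheoguide`, the defaults and
why they were chosen, the numerical conventions, and what the simulated
results do and do not say about real percutaneous dilatational
tracheostomy (PDT).

## Coordinate conventions and pose geometry

All quantities are in millimetres, degrees and seconds.  Frames are
right-handed with +Z the anterior direction (the coronal-plane normal,
i.e. the ideal needle insertion direction), +Y cranial, +X
patient-left.  Euler angles compose intrinsically as Z-Y-X — yaw about
+Z, pitch about the new +Y, roll about the new +X — and are normalized
to (−180°, 180°].  The tracker vendor's convention is not recoverable
from public documentation, so this order is simply fixed and
documented; every derived quantity is defined through the rotation
matrix, so any consistent convention would give the same guidance
parameters.  The needle sensor's local +Z is taken as the shaft
direction (the sensor is secured at the needle tip along the cannula).

Registration between the EM transmitter frame and the anatomical frame
is an explicit proper rigid transform supplied in configuration,
defaulting to identity (transmitter frame ≡ anatomical frame, as on a
bench where the transmitter is aligned with the phantom).

Two readings of the guidance parameters needed a decision:

* **R** (radial distance to target).  Live guidance uses the
  perpendicular distance of the target from the needle's axis line —
  the quantity that predicts whether continued insertion hits or
  misses.  The completion outcome metric ("radius from target" at the
  end of an attempt) is the Euclidean tip-to-target distance.  Both are
  always computed and reported (`radial_distance_R` vs
  `euclidean_distance`).
* **α**.  Defined as the 3-D cone angle between the shaft and the
  anatomical +Z, folded into [0°, 90°].  The alternative literal
  reading — the angle between the shaft and the coronal plane itself —
  is 90° minus this and cannot be reconciled with a "< ±10°"
  green criterion for a needle inserted anteriorly, so
  deviation-from-ideal is the only self-consistent definition.  A
  signed transverse-plane projection (`alpha_transverse_deg`, positive
  toward patient-left, matching the clock-face reading of the safe
  entry window) is computed for reporting but drives no feedback.

Numerical tolerances: rotation matrices are validated orthonormal with
det = +1 to 1e−9; the Pythagorean identity R² + DTT² = ‖t − p‖² holds
to 1e−6 mm² and is asserted in tests together with invariance of
(R, DTT, Euclidean) under common rigid transforms.

## Feedback mappings

Defaults (all configurable in `FeedbackConfig`):

| parameter | default | meaning |
|---|---|---|
| `red_R_threshold` | 4.0 mm | red for R strictly above this |
| `green_R_threshold` | 2.0 mm | green at or below this (angle in limit) |
| `amber_R_lower` | 2.6 mm | documentation: printed lower edge of the amber band |
| `alpha_limit` | 10° | inclusive angle limit outside red |
| `audio_base_hz` / `audio_step_hz` | 470 / 25 Hz | beep base pitch and step |
| `audio_start_radius` / `audio_step_mm` | 20 / 1 mm | where audio starts; distance per step |
| `haptic_max_pct` / `haptic_floor_pct` | 80 / 5 % | vibration at start radius; minimum outside green |

Decisions where the device's printed margins were incomplete:

* The printed bands (red > 4.0 mm, amber 2.6–4.0 mm, green ≤ 2 mm)
  leave R ∈ (2.0, 2.6] unassigned.  The classifier must be total, so
  amber covers the whole gap (2.0, 4.0]; the 2.6 mm figure is retained
  in the config purely as documentation.
* Boundary closure: red is open at 4.0 mm (strictly greater), green
  closed at 2.0 mm, and α = 10° exactly is in-limit (the printed
  "< ±10°" vs "> ±10°" inequalities leave the boundary itself
  unstated).
* The audio spec gives base and step but not the distance-to-step
  rule; the mapping here is one 25 Hz step per 1 mm of approach from a
  20 mm start radius, capped at the green boundary (maximum
  470 + 25·18 = 920 Hz), monotone non-increasing in R.
* The haptic channel is a linear ramp (the device description says only
  that intensity decreases on approach) from 80% at ≥ 20 mm to zero at
  the green boundary.  Vibration is exactly 0% **iff** the zone is
  green: when the angle alone is out of limit at small R, a pure
  R-ramp would go silent while the light shows red, so intensity is
  floored at a configurable 5% whenever the state is not green.
* No hysteresis by default; an optional debounce (a new zone must
  persist N consecutive samples) is available for streaming, default
  off.

Streaming pairs needle and target samples by nearest timestamp within a
tolerance defaulting to half the log's nominal sample interval;
unpairable samples are skipped with a warning.

## Tracker-log dialect

The vendor's wire format is proprietary, so the package defines its own
plain-text stand-in: CSV with header
`timestamp,sensor_id,x,y,z,roll,pitch,yaw,quality` and an equivalent
JSONL, UTF-8, '.' decimal separator, numerics written with 6 decimal
places so that write→read is the identity for values carrying at most
6 decimals.  Timestamps are seconds from log start — simulation and
testing need relative time only.  Parsing is strict by default
(malformed lines and per-sensor timestamp regressions are errors naming
the line); lenient mode skips/sorts with warnings.  The nominal rate
metadata defaults to the hardware's 255 Hz; simulated logs carry one
record pair per operator update instead, at their own nominal rate.

## Insertion simulator

The simulator stands in for the bench experiment: an anatomical neck
model with 25.0 mm of simulated soft tissue over a 10 mm-diameter
trachea (an impalpable, "difficult" neck), target sensor on the
tracheal axis at 30 mm depth, with the trachea re-randomized before
every attempt — lateral offset uniform within ±15 mm per axis and
long-axis tilt uniform within ±15°, both configurable.

The operator is a discrete-time behavioural model, **entirely invented**
(the original experiment measured humans); its defaults are a
calibration chosen so the simulated unguided arm has a per-axis lateral
aiming SD of 10 mm at the 25 mm tissue depth and attempt durations on
the scale of tens of seconds, i.e. the qualitative pattern of the bench
data, not ground truth:

* Unguided (palpation): one aim draw (per-axis SD 10 mm, insertion-axis
  tilt SD 4°), straight insertion at 0.7 mm/s, no correction.  A pass
  that reaches target depth outside the trachea is noticed (no air
  aspirated) and re-inserted with probability 0.25 (10 s penalty, at
  most 3 passes).
* Guided: every reaction interval (1.5 s, scaled per modality) the
  operator re-evaluates the feedback and applies two proportional
  corrections with motor noise (gain 0.25, noise SD 0.4 mm/update):
  re-aiming the shaft toward the target — never steeper than 0.8× the
  angle limit, with a hard physical clamp at 1.2× — and walking the
  puncture site toward the target, attenuated linearly with depth (deep
  tissue does not permit lateral repositioning).  The needle advances
  at half the unguided speed (cautious advancement under guidance) and
  only while the zone is not red; blocked deep, the operator partially
  withdraws along the shaft to re-correct where the tissue permits.
  Modality time factors 1.0 (visual), 0.95 (audio-visual) and 1.35
  (haptic-visual) reproduce the observed ordering of durations with
  haptic-visual slowest.
* An attempt succeeds when the tip crosses the tracheal wall (distance
  to the tracheal long axis ≤ 5 mm); entry is then confirmed on the
  bronchoscope view and the needle advances to the target depth plane
  without further feedback corrections.  Attempts are abandoned at the
  pre-determined 300 s cutoff.  Time to target is the update count ×
  interval plus re-insertion penalties, mirroring a stopwatch from
  first puncture to visualized entry.

The trial layer reproduces the crossover design exactly: 10 + 10
participants (laboratory / hospital), 8 attempts each (2 × 4
modalities) in per-participant randomized order, phantom re-randomized
per attempt.  Participant heterogeneity is a lognormal (SD 0.15)
multiplier on accuracy and tempo; hospital staff get a small
deterministic advantage (aim ×0.95, tempo ×0.82), matching the small
and non-significant group differences observed.  Randomness derives
from a single master seed through `numpy.random.SeedSequence` keyed by
(master, participant index, attempt index, purpose), so every output is
bit-reproducible, and each emitted tracker log replays through the
feedback engine to exactly the zone sequence that drove the attempt
(records are rounded to the dialect's 6 decimals before the zones are
evaluated, so a disk round trip cannot flip a boundary decision).

**What the simulator does not model:** EM field distortion and sensor
noise, target-sensor placement error within the trachea, tissue
deformation and needle bending, bleeding or cuff puncture, and
learning effects across attempts.  One visible consequence: simulated
guided attempts finish ~0.7 mm from the target, tighter than the
~3.5 mm of real guided operators, because those unmodelled error
sources dominate real completion accuracy.  Passing tests therefore
show that the geometry, feedback contracts, design arithmetic and
direction of the guidance effect are correct — not that the simulator
predicts human performance magnitudes.

## Statistics

The analysis pipeline mirrors the trial's reporting plan.  Summaries
are count / mean / SD / median / IQR per group with the mean difference
between two named groups; quantiles (hence IQR) use linear
interpolation between order statistics.  The omnibus test is a one-way
ANOVA on balanced single-factor data (where type I and III coincide;
computed classically) and otherwise a type-III sum-of-squares
decomposition with sum-to-zero contrasts, chosen automatically from the
observed group sizes.  Pairwise comparisons are Tukey HSD — the
Tukey-Kramer extension applies on unbalanced data — with
Benjamini-Hochberg adjustment across the family of all pairwise
comparisons within one outcome.  Robustness checks run Shapiro-Wilk per
group (skipped with a note below n = 3), Levene's test gating a Welch
one-way ANOVA at p < 0.05, Kruskal-Wallis always, and a Wilcoxon
rank-sum test for two-group factors, with a plain-text decision trace
of the branches taken.  Two-tailed α = 0.05 throughout.  Abandoned
attempts are excluded from time-to-target summaries (their value is the
censoring cutoff, not a completion time) and reported as a separate
count.

A note on Benjamini-Hochberg: the step-up operator p(i) → min over
j ≥ i of p(j)·m/j is monotone and order-preserving with adjusted
p ∈ [p, 1], but it is **not** idempotent — re-adjusting already
adjusted values inflates them further (e.g. [0.25, 1.0] → [0.5, 1.0] →
[1.0, 1.0]) — so adjusted p values must be computed once from raw p
values, which is what `pairwise` does.

## Problem sizes in the test suite

The suite verifies the direction of the guidance effect (guided more
accurate, guided slower) across 200 independently seeded trials using a
reduced 2 + 2-participant design per seed — the effect is an order of
magnitude larger than its standard error at that size, so sign
stability is informative — while design-count checks use the full
20-participant × 8-attempt trial.  Geometric invariants are asserted
over 1,000 random configurations and rigid transforms; the Monte-Carlo
type-I error of the omnibus ANOVA uses 1,000 null replicates of 3 × 10
observations.

## Known limitations

* The operator model is behavioural, not biomechanical; its parameters
  are calibration constants, not estimates.
* The feedback engine implements numeric contracts only — no audio
  synthesis, UI rendering, or motor driving.
* The log dialect is a documented stand-in; real tracker streams would
  need a converter and would add quality/visibility flags this package
  only carries as an optional [0, 1] column.
* Type-III decompositions are reported with sum-to-zero contrasts; with
  other coding schemes type-III sums of squares are not meaningful, and
  no attempt is made to reproduce any particular software's default
  contrast choice beyond that.
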