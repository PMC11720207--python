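# Methods

## Soft-body model

The stomach is a J-shaped tube of particles (default 14 per ring × 16 rings
= 224, ≥ the 200-particle floor the config enforces) built on a circular-arc
centerline (radius 8 cm, span 200°, arc length ≈ 27.9 cm) with an axially
varying tube radius: narrow antrum (1.2 cm) distally, 2.0 cm body, bulged
fundus (2.8 cm) proximally. Both end rings are pinned. The lattice carries
rigid-ish ring and longitudinal edge constraints (compliance 1e-4 cm/N),
softer shear diagonals (1e-3), and one shape-matching group per pair of
adjacent rings (stiffness 0.2). Units are centimeters, seconds, grams;
gravity is off by default because a gas-insufflated lumen at this scale is
quasi-static and the organ is suspended by its attachments.

Integration is XPBD: symplectic Euler prediction per substep, a fixed number
of constraint-projection iterations, velocity recovery from the position
change, and a per-substep velocity damping factor (0.995) for stability.
Defaults: dt = 1/60 s, 10 substeps, 8 iterations — all configurable; the
published description of the original trainer gives no values, so these are
this package's own choices in the usual range for interactive PBD cloth/soft
tissue.

Integrator convention: after one frame of `S` substeps from rest under
constant acceleration `a`, the displacement is `a·dt²·(S+1)/(2S)`, which
approaches the ballistic `a·dt²/2` as `S → ∞`. This exact form is what the
unit tests assert.

### Solver

Constraints are projected simultaneously (Jacobi style) in vectorized form
with a uniform under-relaxation factor (default 0.3), and Lagrange
multipliers accumulate the relaxed increments. Two consequences drove this
choice over sequential Gauss–Seidel:

* uniform scaling keeps every pairwise correction equal and opposite, so the
  center of mass of free equal-mass particles is conserved to machine
  precision per step;
* it vectorizes, which keeps a 1,000-frame stability run of the default
  stomach in the tens of seconds on one core.

The relaxation factor trades per-iteration convergence for stability on
high-valence lattices; on a two-particle system it contracts the residual by
(1 − ω) per iteration, reaching < 1e-6 from a 1 cm violation within 50
iterations at ω = 0.3.

Substeps vs. residual: with zero compliance the end-of-frame residual is
pure solver error and never increases when substeps double (this is the
stiffness/frequency decoupling XPBD exists for, and is asserted as a
property test). With positive compliance the "residual" includes the
physically correct compliant stretch of an oscillating spring, which is not
monotone in substep count — more substeps integrate the true dynamics more
accurately rather than projecting harder toward zero stretch. The property
is therefore stated and tested at compliance 0.

Degenerate inputs: coincident constraint endpoints are skipped with a
warning (the gradient direction is undefined); a shape group whose moment
matrix drops below rank 2 raises a degenerate-group error; non-finite
positions after a step raise a divergence error naming the step index.
Tie-break for a particle exactly on a capsule axis: the contact normal is
world +z, or +x when the axis itself is near-parallel to +z.

## Anatomy and the gastric axis

Region labels partition the surface totally and disjointly: angular sectors
(anterior = +y side, posterior = −y, greater curvature = outside of the
bend, lesser = inside) overridden by axial bands (fundus above s = 0.80,
antrum below s = 0.15) and an incisura band (lesser-curvature vertices
within ±0.05 of s = 0.45). The axial coordinate s runs 0 at the pylorus to
1 at the cardia; "distal to proximal" means increasing s, matching the way
an ESG suture line runs from the incisura toward the fundus. Region queries
use the deformed surface (nearest labeled vertex, gated at 3 cm); the axis
is a rest-frame reference sampled at 200 polyline nodes, so axial
coordinates are smooth in space and unaffected by deformation.

## Procedure layer

Tool kinematics are scripted poses; the simulator is a state machine that
validates tool/target preconditions and appends typed events with strictly
increasing timestamps. Values the original system does not publish are
explicit config: marking range 0.5 cm, helix reach 1 cm, wall thickness
0.4 cm, bleeding probability 0.1 per bite (a seeded Bernoulli hazard — the
adverse event is described qualitatively in the source material, so a
memoryless per-bite trigger is the simplest faithful model). A bite is full
thickness iff the helix is engaged with retraction depth ≥ the wall
thickness — a stated proxy, since the internal detection rule of the
original trainer is unpublished.

## Scoring decisions

* **Parallelism** (M1–M3): best-fit line direction of the mark points vs.
  the axis tangent at their mean axial station, tolerance 15° (no published
  angle; exposed in config).
* **Grasp proximity**: Euclidean distance in world coordinates at grasp
  time, threshold 0.5 cm.
* **Exchange metrics** (M6/M8/M10) are wall-aggregate: every bite on the
  wall must have a correct exchange.
* **Pattern slots** (M14a/b): default `applicable_only` — only the detected
  pattern's slot is applicable (0), the other is excluded from the total; an
  unrecognized pattern scores 5 on one slot. The `both` mode (own pattern 0,
  other 5, NONE → 5/5) always scores both slots, which is the arithmetic
  needed to aggregate per-metric group means over cohorts that mix patterns.
  Maximum totals are 99 (`both`) and 94 (`applicable_only`), asserted as
  constants.
* **Premature cinch** (M17): not applicable without bleeding; scored 0 when
  the first cinch after the bleed onset precedes any further bite, i.e. the
  operator stopped suturing and cinched.
* **Time quartiles** (M18): cohort 25/50/75 percentiles with inclusive lower
  edges; ties take the lower (better) quartile. Needs a cohort of ≥ 4.
* **Expertise thresholds** are implemented as ≥ (60 months, 1500 cases, 10
  suturing cases): the published roster labels a participant with exactly
  1,500 cases and 10 suturing procedures as an expert, which strict
  inequalities would contradict.

## Synthetic operators

Policies execute mark → suture set (U-pattern wall order, six bites
advancing 1.05–1.45 cm per bite from just proximal of the incisura) → cinch,
drawing each rubric violation from its own probability. Trajectories are
minimum-jerk position profiles between the visited waypoints at the
operator's nominal speed, plus a seeded-phase sinusoidal tremor and smoothed
white noise. Presets: experts move at 1.5 cm/s with 0.02 cm tremor at 8 Hz
and ≤ 10% error rates; novices at 2.5 cm/s with 0.12 cm tremor at 9 Hz and
15–50% error rates. Cohort generation jitters each participant's parameters
lognormally (σ ≈ 0.1–0.3) so groups have within-group variance.

What this emulates — and does not: the generator reproduces the *direction*
of the published group differences (novice totals higher; novice speed,
acceleration, and jerk all higher; novices faster to finish, hence experts
scoring worse on the time metric), with group-mean totals (~23 vs ~50 at the
shipped presets) in the plausible range. It does not model learning within
a session, correlated error bursts, instrument slippage, or individual human
idiosyncrasies, so passing separation tests demonstrates that the pipeline
detects differences of this kind and size — not that it would detect any
particular human cohort's.

## Problem sizes

The shipped checks use the default 224-particle stomach; 1,000 frames for
the stability run; 20 experts + 20 novices (one session each, ~60–100
simulated seconds at 60 Hz sampling) for the group-separation property; and
the published 19-row metric-means table and 12-row roster for the worked
examples. These sizes make the whole suite reproducible on a single core in
a few minutes.

## Known limitations

No self-collision of the stomach wall; no fluid or blood model (bleeding is
an event, not a simulation); plication is a geometric rest-shape contraction
rather than a suture-force model; jerk estimates on noisy trajectories are
dominated by the noise floor at high sampling rates (mitigated, optionally,
by the moving-average smoother — off by default); Welch degrees of freedom
are real-valued by construction and will not match integer df conventions
used elsewhere.
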