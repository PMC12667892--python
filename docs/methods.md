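# Methods

`reachmix` simulates goal-directed reaching in cluttered scenes as a
competition between simultaneously prepared motor plans.  Every target and
every obstacle gets its own stochastic optimal controller; the executed
command is their mixture, weighted by each plan's *relative desirability*.
This note records the model, its parameters, the numerical choices, and the
limits of what the bundled synthetic experiments can show.

## Plant

The hand is a unit point mass in the 2-D task plane, Euler-discretised:

    p_{t+1} = p_t + v_t dt
    v_{t+1} = v_t + (u_t - b v_t) dt

with `dt = 0.01 s` and viscous damping `b = 0.1 /s`.  Motor noise is
signal-dependent: the applied command is `u (1 + sigma eps)` with
independent standard-normal `eps` per component and `sigma = 0.2` by
default, so noise vanishes at rest and scales with effort — the standard
account of trial-to-trial kinematic variability in reaching.  An optional
additive velocity noise term (default 0) is available for completeness.
The task geometry is dimensionless "task units"; the canonical reach runs
from (0,0) to (30,30) past an obstacle at (15,15).

## Per-option controllers

Each option is served by a finite-horizon LQG regulator synthesised by a
backward Riccati recursion over the option's time-to-contact horizon `T`:
terminal cost `z' Q_T z` on the residual `z = x - [goal, 0]` and running
effort cost `u' R u`, with no state running cost.  Target controllers
penalise terminal position *and* velocity (arrive and stop; both weights
1e4); obstacle *approach* controllers penalise position only (1e4 / 0) —
hitting an obstacle at speed is still hitting it.  `R = 1e-4 I` puts the
model in the accuracy-dominant regime typical of reach models.  All weights
are configurable.

The avoidance policy is the *negation* of the obstacle-approach policy: it
emits exactly the opposite command at every state, while retaining the
approach policy's cost-to-go as its action cost.  This is an approximation,
not an optimal avoidance law — avoidance has no well-defined endpoint to
optimise toward — and it is what creates the "anti-target" structure in the
action-cost landscape (avoidance is *cheapest*, hence most "desirable" in
action terms, where approach would be cheapest: near the obstacle).

Horizons follow a distance-proportional time-to-contact rule:
`T = clamp(round(d / v_ref / dt), 10, 500)` with `v_ref` the canonical
reach distance per second (42.43 units/s).  Policies are re-synthesised
every step with the updated horizon (receding-horizon control); because the
residual dynamics are goal-independent, gain and value arrays are cached
per (plant, horizon, weights) and shared across goals, making the refresh
cheap.  Gains are certainty-equivalent: signal-dependent noise perturbs
execution, not synthesis.

## Collision model

Each obstacle carries two concentric circles: the inner one its physical
diameter `d_inner`, the outer one a tolerance boundary `d_outer` (canonical
4 and 8 units).  The positional collision probability at effective diameter
`d = 2 |hand - centre|` is 1 for `d <= d_inner`, decays linearly to 0 at
`d_outer`, and is 0 beyond.  Direction gates position: the probability only
counts when the velocity lies inside the *collision cone*, the sector
bounded by the tangents from the hand to the outer circle (half-angle
`arcsin(r_outer / distance)`).  Inside the outer circle the tangent
construction degenerates; membership then means moving toward the centre,
and at the centre itself any motion counts.  Zero velocity is never in the
cone.

Risk along a plan is the mean of this indicator over an `N = 50`-step
noise-free rollout of the plan (clamped to the plan's horizon), which keeps
the value in [0,1] without a normalising constant.  The rollout is driven
by the *target-approach* policy being vetted: the resulting probability is
the risk of the reach the agent is contemplating, and it enters the model
twice — as `1 - P` in the target's goods term and as `P` in the obstacle's.
Driving the risk rollout with the avoidance policy instead would make the
obstacle's goods term identically zero (a plan that flees never collides),
so avoidance would never gain mixture weight; treating risk as a property
of the contemplated reach is the reading that makes the architecture
function.  In target-free scenes the prediction falls back to a ballistic
zero-control rollout.

## Desirability and the mixture

The action-related component of each option is a softmax over that
category's action costs (cost-to-go values) with inverse temperature
`lambda` (default 1): the probability that this option is the cheapest to
serve.  It is computed in the algebraically cancelled, max-shifted form, so
extreme costs cannot underflow to NaN.  Single-option categories give 1 by
construction.  The goods-related component is `(1 - P) x reward
probability` for targets (reward alone in the obstacle-free mode) and `P`
for obstacles.  Desirability is the product of the two components; with
several obstacles a target's `P` is the worst case over obstacles, and an
obstacle's `P` the worst case over reach plans — conservative and
order-independent.

Risk aversion `alpha` in [0,1] splits the mixture between categories:

    w_target_j   = alpha v_j / D,   w_obstacle_k = (1-alpha) v_k / D,
    D = alpha sum_j v_j + (1-alpha) sum_k v_k

and the executed command is the weight-weighted sum of the per-option
policy outputs (avoidance outputs already negated).  When `D = 0` (all
desirabilities vanish — e.g. pure avoidance far from any risk) the pure
function raises a degenerate-scene diagnostic; the closed-loop simulator
instead falls back to a uniform alpha-split so trials continue, flags the
breakdown, and logs an event.

**Default `alpha = 0.1`.**  Risk aversion is a free parameter of the model
(individual differences are expected); the package pins a strongly
risk-averse default because it is the regime that produces the canonical
avoidance morphology with the canonical geometry: lateral deviation growing
monotonically with obstacle size, clearance beyond the physical boundary
for small and medium obstacles, and the away-bias next to laterally offset
obstacles.  At `alpha >= 0.15` the rollout-mean risk (bounded well below 1
for small zones, since only a minority of lookahead steps are threatened)
is too weak a weight to deflect the reach, and the model shears through
small obstacles while still avoiding big ones — inverted relative to
observed behaviour.  `alpha` is a config key and every experiment accepts
an override.

## Closed-loop simulation

Each step: fire any scheduled target jumps, refresh horizons and policies,
evaluate the desirability breakdown, mix the commands, and step the noisy
plant.  Trials end at target attainment (within 1 task unit at under 1
unit/s — small relative to the 42-unit reach), at the step cap (600 steps =
6 s), or, if configured, at collision; by default a collision (hand inside
the physical radius) is logged and the trial continues, since contacted
reaches still proceed to the goal.  Per-trial seeds derive from the
experiment seed by a counter-based spawn-key scheme so conditions pair
trial-by-trial.  A fixed seed reproduces a trial bit-for-bit.

Mirror-symmetry checks exploit the canonical diagonal chord: reflecting the
scene across y = x is a coordinate swap, and `mirror_noise=True` swaps the
per-component noise draws, so the mirrored run consumes identical entropy
and reflects the original trajectory exactly.

### Experiment presets

* **Size ladder** — obstacle centred on the chord midpoint, inner diameters
  {0, 4, 8, 12} with `d_outer = 2 d_inner`; spans the no-deviation to
  wide-avoidance regimes.
* **Lateral obstacle** — canonical zone displaced 4 units perpendicular to
  the chord, left or right: near, tangent to the straight path, but not
  blocking it.
* **Target jump** — the goal jumps at 40% of the nominal movement duration
  to a laterally displaced location (10 units), with no obstacle, an
  obstacle blocking the new path, or an obstacle near it.

Summaries resample each trajectory to 100 points equally spaced in arc
length (trials differ in duration), then report mean and pointwise-SE
paths, collision rate, per-trial signed maximal lateral deviation from the
start-to-target chord, and the chord side occupied at 25% of the path
(the "initial deviation" statistic).  Trials that curve *around* the
obstacle — approach within the outer radius followed by a chord crossing —
are partitioned out before averaging and summarised separately; the rule is
a convention, exposed in code, not a fitted criterion.

## Desirability maps

The 4-D (position x velocity) landscape is projected to the plane with the
circular-sampling convention: each probed state's velocity points radially
outward from the start through the probe, at the speed of the unobstructed
optimal reach at 75% completion (measured by arc length from a noise-free
rollout of the single-target policy); 359 states on a target-centred circle
of radius 75% of the reach distance are kept alongside the rectangular
grid (default 101 x 101 over [-10, 50]^2).  Map desirability fields pool
target and obstacle action costs into a single softmax — cross-option
competition — so in the action-only mode the two fields sum to 1 at every
grid point; the per-category normalisation of the controller path would
render single-pair maps constant and hide the landscape.  The
comprehensive mode adds the rollout collision probability per grid state
(noise-free by default; `trials_per_state > 1` averages noisy rollouts,
seeded) and folds it into the goods terms.  The vector field is the
normalised direction of the mixed command under the scene's `alpha`.

A structural note on the action-only landscape: for any monotone pooled
softmax the avoidance field's argmax sits where `V_target - V_obstacle` is
largest, and under the radial-velocity convention that is *next to the
target*, not next to the obstacle — stopping at the target while moving
outward at the reference speed is far more expensive (terminal velocity
penalty) than swinging back to a velocity-unconstrained obstacle.  The map
therefore reproduces the known rim of spuriously high avoidance
desirability surrounding the target, which is exactly the artifact that
motivates the comprehensive mode; the obstacle's own anti-target signature
appears in the *cost* field (a low-cost corridor along the approach axis),
not as the global argmax of the desirability field.

## What the synthetic experiments do and do not show

The bundled experiments are simulations of the model under its own noise
assumptions, at desk scale (up to a few hundred trials).  Passing checks
show the architecture produces the qualitative morphology reported for
human reaching — graded deviation with obstacle size, transient initial
deviation toward nearby obstacles with a net away-bias, re-planning after
target jumps — under one fixed parameterisation.  They do not fit human
data, do not identify `alpha` or `lambda` for any subject, and do not test
multi-joint dynamics, sensory delays, state estimation, moving obstacles,
or non-circular geometry, all of which are outside the model's scope.

## Numerical choices

* Riccati recursion in the symmetric `(A-BK)' P (A-BK) + K' R K` form with
  explicit re-symmetrisation each stage; a singular `R + B'PB` is reported
  as a numerical failure (unreachable for the shipped plants).
* Softmaxes are max-shifted; probabilities are validated into [0,1] at
  module boundaries.
* The rollout risk includes the current state and spans
  `min(N, horizon)` steps.
* Double negation of a policy is rejected rather than silently restoring
  the approach policy.
* Exported CSV fields use `%.17g`, which round-trips float64 exactly; the
  CSV reader parses with round-trip precision.
* All stochastic paths take a seed or a `numpy` Generator; derived seeds
  stay below 2^31.
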