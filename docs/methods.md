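# Methods

## Model overview

`homeoforage` simulates an embodied forager whose only source of reward is
homeostasis of a two-dimensional internal nutrient state
`s = (s_red, s_blue)`, measured relative to a setpoint at the origin. The
package couples four components:

1. **Metabolic dynamics** that advance `s` each decision tick,
2. a **drive** `d(s)` (a possibly weighted squared distance to the setpoint)
   whose temporal difference defines the reward,
3. a **2D foraging arena** with red and blue food balls and an embodied
   agent sensing proprioception, an egocentric rangefinder, and its own
   internal state, and
4. a **nutritional-geometry analysis** (NGF) that measures long-term intake
   as points in nutrient space and compares them to the canonical "rules of
   compromise": closest distance (CD), equal distance (ED) and no
   interaction (NI).

## Metabolic rules

Each tick, with consumption indicators `I_red, I_blue ∈ {0,1}`:

- **CD**: `s_x ← s_x − δ + (gain from consumed foods)` for both nutrients,
  with training gains `a_red = b_blue = 0.1`, cross-gains zero, and decay
  `δ = 0.00015` per tick. No clamping is applied inside the metabolism; the
  arena tests the survival box `[−1, 1]²` after each update.
- **NI**: one nutrient (red by default; parameterizable) is frozen — its
  level never changes and ingested amounts of it are discarded. The other
  nutrient follows CD.
- **ED**: a CD step followed by a substitution step. If the two components
  have strictly opposite signs, the amount `m = min(|s_red|, |s_blue|)` is
  transferred from the surplus to the deficit nutrient, zeroing the
  smaller-magnitude component; the component sum is conserved exactly. A
  component exactly at 0 triggers no transfer. The substitution is
  idempotent and never leaves strictly opposite-signed components — all
  three facts are enforced by property tests.

Rail test foods share a single composition
`a_red = b_red = 0.1β`, `a_blue = b_blue = 0.1(1−β)`, `β ∈ (0,1)`, so
cumulative intake moves along the ray with direction `(β, 1−β)`.

Simultaneous consumption of one red and one blue food in the same tick is
allowed and additive; the arena consumes at most one food per color per
tick (the nearest in radius), preserving indicator semantics.

## Drive and reward

The unweighted drive is `d = s_red² + s_blue²`. The weighted drive is
`d = c_red·s_red² + c_blue·s_blue²` with normalized coefficients
`c_x = 2w_x/(w_red + w_blue)`, so `c_red + c_blue = 2` always and
`c_blue/c_red = w_blue/w_red`; equal weights recover the unweighted drive
exactly. The per-tick reward is

    R = α(d_t − d_{t+1}) − (k_p‖p_t − p*‖² + k_u‖u_t‖²)

with `α = 100`, `k_p = 0.005`, `k_u = 0.0005`. The homeostatic term
telescopes: its episode sum is exactly `α(d_0 − d_T)`. For the default
kinematic body there is no articulated torso, so the posture vectors are
empty and only the action cost applies; the posture term exists to
stabilize a physics-engine body, which this package treats as an optional
backend concern rather than a tested surface.

The drive used for the reward and the drive used in analysis are the same
configured function (unweighted or weighted), so the weighting experiment
changes exactly one thing.

## The arena

A 10 m × 10 m walled square (walls at ±5 m) containing ten red and ten blue
food balls with consumption radius 0.5 m. These geometric values are
package choices: they make the rangefinder's 5 m maximum range cover half
the arena, so the exteroceptive signal is informative. Consumed food
respawns immediately at a uniform random location clear of the agent, so
per-type counts stay constant over sessions of up to 60,000 steps.

The default body is a kinematic point with action
`u = (speed command ∈ [−1, 1] m/s, turn-rate command ∈ [−2π, 2π] rad/s)`,
integrated over the 0.05 s decision interval and clipped at the walls (no
bounce). The rangefinder has 20 bins of 18° per food color spanning ±180°;
bin reading `1 − min(d_k, d_max)/d_max` for the nearest food of the color
in the bin, 0 if empty; a food exactly on a bin boundary belongs to the
lower-index bin. Observations are (proprio: normalized position plus
heading cosine/sine; extero: 40 rangefinder values; intero:
`(s_blue, s_red)` verbatim).

Episodes start with `s ~ Uniform[−1/6, 1/6]²`, terminate when either
component leaves `[−1, 1]` (death), and truncate at the step cap (60,000 by
default). Tick order: body moves → consumption → metabolism → reward from
the drive before/after the metabolic update → termination tests. One
seeded generator per environment instance; session seed = base seed +
session index, so full trajectories are bit-reproducible.

## Policies

**Greedy oracle.** A deterministic one-step-lookahead forager with
privileged state: it compares the drive after eating a red food, after a
blue food, and after a decay-only step (all one metabolism step ahead,
under the configured rule and drive weights). If the best meal beats
decay it steers toward the nearest food of that color at full speed,
otherwise it stays still. Ties between colors go to the nearer food, then
to red. The oracle is the desk-scale stand-in for a converged
drive-reducing agent: it lets the compromise-curve predictions be tested
in minutes instead of the days a full policy optimization would need.

**PPO.** A self-contained numpy implementation of clipped-objective PPO:
separate policy and value networks (fully connected 256–64, tanh), the
policy head emitting per-dimension Beta shape parameters (softplus + 1, so
shapes ≥ 1) mapped linearly onto the action interval — sampled actions
respect the bounds by construction. Generalized advantage estimation
(λ = 0.95), advantage normalization per batch, entropy bonus 0.01, Adam at
3·10⁻⁴, discount γ = 0.99. Clipping 0.3, and the full-scale schedule (500
iterations × 3·10⁵ samples, minibatch 5·10⁴, 30 epochs) are configurable;
the exercised *scaled profile* is 20 iterations × 3·10⁴ samples, minibatch
3·10³, 10 epochs, 4,000-step training episodes — sized so a complete
training run, paired evaluation against a random policy, and the feeding
selectivity analysis complete on a single CPU. Backpropagation is written
out explicitly; the analytic gradients of the clipped surrogate, the Beta
log-density and the Beta entropy are verified against central finite
differences in the test suite. Mid-batch truncations bootstrap with the
state's own value (the drive changes negligibly in one tick); the trailing
cut uses the true successor value.

## NGF analysis

Axis convention: red intake on x, blue on y, everywhere. A rail for test
condition β is the unit ray along `(β, 1−β)` — derived from the food
compositions, which are taken as authoritative for the rail geometry. The
intake target (IT) is estimated as the mean cumulative intake over 20
surviving ad-libitum sessions on training foods, with the same session
length as the test sessions (8,000 steps).

Closed-form expected rail points, each validated against a brute-force
grid search over densely sampled rail points:

- **CD**: orthogonal projection of the IT onto the rail, clipped to the
  nonnegative ray.
- **ED**: the point `t·û` solving `t·û_red − IT_red = −(t·û_blue − IT_blue)`,
  i.e. equal absolute deviations of opposite sign;
  `t = (IT_red + IT_blue)/(û_red + û_blue)`.
- **NI**: the point matching the IT in the regulated nutrient (blue by
  default, matching the NI metabolism that freezes red).

For a rail through the IT, all three reduce to the IT itself.

Session statistics are computed *along the rail*: each surviving session's
intake point is projected to a scalar coordinate; the per-rail mean point
is the mean scalar times the rail direction, the SD is the sample (n−1) SD
of the scalars, and the error against an expected point is the signed
percent error of the scalars, `(v − t)/t × 100`. Rails with fewer than 10
surviving sessions are dropped from cross-rail aggregates (kept iff
survivors ≥ 10). No significance testing is applied to the curves.

The standard sweep uses β ∈ {0.2, 0.3, …, 0.8} (seven rails; the endpoints
are fixed by the protocol and step 0.1 gives a visually and statistically
adequate density), 20 sessions × 8,000 steps per rail.

The drive-weighting spectrum runs the CD metabolism with weighted drives
at ratios `w_blue:w_red ∈ {1, 2, 4, 8, 16}`. Per ratio it measures
10,000-step time-averaged interoceptive errors (the per-step mean of
`s_red²` and `s_blue²`) over 20 training-environment sessions, and runs
the rail sweep. With the oracle forager the rail-sweep half of the
interpolation holds: at 16:1 the rail means lie closer (along-rail) to the
NI expected curve than to the CD one — NI emerges as the large-ratio limit
of CD. The training-environment interoceptive errors, by contrast, are
*insensitive* to the weights under the oracle, and the suite's
monotonicity check on the red error documents this as an expected failure
of the stand-in: with pure single-nutrient training foods, the weighted
coefficient factors out of the oracle's per-color consumption condition
(eat red iff `s_red < −0.05 + δ`, for any positive weights), so weighting
only reorders which deficit is served first — a travel-time effect an
order of magnitude below the session-to-session noise. Shifting the error
balance in the training environment requires a policy whose approach
behavior itself changes with the weights, i.e. a trained agent; on rail
(mixed-composition) foods the weights do enter the oracle's consumption
condition, which is why the NGF interpolation still shows.

## What the simulations do and do not show

The arena emulates the statistical structure of a foraging experiment —
random food layouts, random initial states, rail-restricted diets — but
not animal physiology: metabolism is linear with constant decay, there is
no digestion lag, satiation, gut capacity, nutrient interdependence or
memory effect, and the kinematic body cannot fall, tire or collide.
Passing tests therefore certify the *control-and-geometry* claims (which
metabolic rule produces which compromise curve, and how drive weighting
moves between them), not predictions about any real species. The oracle
results additionally assume one-step lookahead is close to optimal for
this reward, which holds here because meals are the only controllable
drive change and their effect is immediate.

## Numerical choices and edge cases

- All state arithmetic in double precision; no rounding of the decay rate.
- ED substitution uses strict sign tests; an exact zero component triggers
  no transfer (equivalently m = 0).
- Rail directions are unit vectors; β outside (0,1) is a domain error, as
  is a non-positive drive weight or a zero percent-error target.
- `estimate_intake_target` raises if no session survives, rather than
  returning a silent NaN.
- Beta samples are clipped to [1e−6, 1 − 1e−6] before log-densities.
- The brute-force expected-point oracles relax the opposite-sign
  constraint by the grid resolution so the IT-on-rail case (where the
  crossing is a single point) remains solvable.

## Known limitations

- The physics-engine quadruped backend is an interface hook, not a tested
  implementation; posture costs are exercised only through their algebra.
- The scaled PPO profile demonstrates learning direction (better than
  random, deficit-directed feeding), not convergence; compromise-curve
  reproduction is established with the oracle, and full-scale training is
  configuration only.
- Interoceptive-error averages are taken over the steps an agent actually
  lived; with the oracle this is the full session, but a dying policy's
  error is not extrapolated.
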