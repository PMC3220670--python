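# Methods

## Model overview

`troopsim` is an individual-based model of a non-traveling,
dominance-structured animal group in a featureless social environment.
The world is a continuous square torus of side `L` = 300 m (one grid
unit = 1 m, one time step = 1 "second"), so no border effects exist and
every distance or direction is the shortest-path version.  A group of
`N` = 30 agents carries a stable hierarchy: agent *i* has dominance
strength `D_i = i/N` (equally spaced, top rank exactly `MAX_DOM` = 1).
The endpoints of this range are the modeling commitment; equal spacing
is the simplest assignment consistent with them, and none of the
reported measures depend on the absolute scale.  Dominance is never
updated — no winner/loser effects, births, deaths or migration.

The simulation is event-driven and asynchronous.  Every agent holds a
continuous next-activation time; the lowest time acts next, and each
participant of the resulting action (actor, plus contest partner) is
rescheduled by a fresh waiting time — exponential with mean
`MEAN_INTERVAL` = 10 steps, or uniform on (0, 20) under the robustness
regime (same mean).  A run lasts 72,000 steps (~2.2 × 10⁵ activations);
observers sample every 900 steps during the last 36,000, giving 40
snapshots per run, and encounters are counted on every occurrence in
that window.

## Behavior rules

On activation an agent executes one action, the first applicable of:

1. **Interact.**  If any other agent is within `PERS_DIST` = 4 m and
   inside the 120° view cone, the nearest is engaged (exact distance
   ties broken uniformly).  The encounter is scored directed,
   ego → partner.
2. **Cohesion override.**  If the furthest group member (no view
   limit; agents know their group) is beyond `FAR_DIST` = 110 m, ego
   turns toward a uniformly random member and approaches one step.
   This prevents permanent group fission while leaving spread and
   subgrouping free; switching it off (`fission_restricted = false`)
   lets the group split.
3. **Group.**  If fewer than `MIN_OTHERS` = 3 others are within
   `NEAR_DIST` = 20 m in the view cone, ego approaches (one step) a
   member chosen uniformly from the first non-empty tier: in-cone
   within `MAX_DIST` = 50 m; full circle within 50 m; full circle at
   any range.  The last tier is this package's deadlock guard for
   strayed agents and fission-off runs, where everyone may be out of
   perception range.
4. **Avoid** (avoidance variants).  If a potential aggressor —
   dominance gap strictly above `AV_DOM_DIFF` — is in the view cone
   within `AV_DIST`, ego turns directly away from the nearest one and
   walks `AvoidD` = 2 m.
5. **Random walk.**  Move one step forward, then with chance 0.5 turn
   by a uniform angle up to ±`MAX_TURN_ANGLE` (default 180°; 45/90/135
   probe movement persistence).

The priority order encodes urgency (contact > cohesion > grouping >
avoidance > walking), not temporal order.  The voluntary step length is
`WalkD` = 1 m except in the velocity variant (below); the reactive
displacements `FleeD` = 2 m, `ChaseD` = 1 m and `AvoidD` = 2 m are
fixed distances in every variant.

## Contests

The chance that A beats B is the logistic in the dominance difference,
`w_AB = 1 / (1 + exp(-beta * (D_A - D_B)))` with
`beta = 6 / MAX_DOM`: it depends only on the difference, satisfies
`w_AB + w_BA = 1`, and spans ≈ 0.003–0.997 over the extreme pairs of a
30-agent hierarchy.  An encounter resolves by a two-sided decision
tree: ego challenges iff `w` exceeds a uniform draw (else it flees
`FleeD` away — "unprovoked fleeing"); the challenged opponent agrees to
fight iff `1 - w` exceeds a fresh draw (else it flees — "fleeing after
threat"); a fight's winner is drawn with probability `w`, the loser
flees `FleeD` and the winner chases `ChaseD` toward the loser's
post-flee position (net separation after a fight: 1 m).  Closed form:
P(initiator flees) = 1 − w, P(target flees) = w², P(fight) = w(1 − w) —
maximal at even odds, so escalated fights between distant ranks are
rare.  After either settlement (not after fights) the non-fleeing
opponent reorients to a uniform random heading with chance 0.5, which
prevents repeated back-to-back interactions; no post-chase "wiggling"
turn is used.  In the fleeing-control and velocity variants every
pairwise `w` is forced to 0.5, removing rank dependence from fleeing
while leaving the mechanics intact.

## Variants

| variant | fleeing rates | avoidance | step length |
|---|---|---|---|
| `fleeing` | rank-dependent | — | 1 m |
| `avoidance` | rank-dependent | yes | 1 m |
| `avoidance_fleeing_control` | equalized (w = 0.5) | yes | 1 m |
| `velocity` | equalized (w = 0.5) | — | `v_i` |

The velocity variant's step length is
`v_i = MAX_VELOCITY * (1 - D_i + 1/N)`: linear and inverse in rank,
`MAX_VELOCITY` at the bottom rank, `MAX_VELOCITY / N` at the top.  The
exact published functional form is not recoverable from the source
material; this realization satisfies every stated constraint and is the
package's fixed choice.  The same applies to `FAR_DIST`, which is kept
as a plain configuration value (110 m for N = 30) rather than a
function of N.  The `equal_velocities` flag sets every step length to
the across-rank mean of `v_i` — the null control under which the
centrality gradient must vanish.

Probabilistic avoidance (`avoidance_mode = "probabilistic"`) replaces
the hard threshold with a sigmoid avoidance chance
`1 / (1 + exp(-slope * (gap - inflection)))` evaluated per perceived
candidate (one draw each, id order); `inflection` reuses
`av_dom_diff` and `slope` ∈ {5, …, 120} interpolates between "avoid
everyone a bit" and the discrete rule.

## Observers

* **Group center**: arithmetic mean with a wrap correction.  Per axis
  the coordinates are treated circularly: the largest empty arc in
  their sorted circular order is taken as where the group is not;
  coordinates below that arc are shifted up by `L`; the plain mean is
  wrapped back.  For a group straddling at most one border per axis
  this coincides with "shift the low end up by the field length", and
  for an interior group with the naive mean.
* **Distance to center**: torus distance to that point; small values =
  central.
* **Centrality–peripherality index**: mean resultant length of the
  unit bearing vectors from an agent to all others (circular
  statistics): 0 = surrounded (central), 1 = everyone on one side
  (peripheral).  Reported alongside, never instead of, the distance
  measure; coincident others contribute a null vector.
* **Group spread**: the maximum pairwise torus distance (furthest
  neighbor distance) per snapshot.
* **Dyadic matrix**: all pairwise torus distances (symmetric, zero
  diagonal), time-averaged over the 40 snapshots.
* **Encounter matrix**: directed counts, initiator row → target
  column, accumulated continuously over the recording window.
* Rank-band statistics: agents partition into bands of width
  `AV_DOM_DIFF` anchored at the top (`(0.8, 1.0]` is the alpha band for
  width 0.2); `cross_band_fraction` is the share of encounters crossing
  band boundaries and `uniform_mixing_cross_fraction` its expectation
  under uniform partner choice.

## Randomness and reproducibility

All randomness of a run flows through a single Mersenne-Twister stream
seeded once from the config seed (the simulation kernels are
numba-compiled; the stream is numba's global generator).  Draw order:
per agent in id order its initial x, y, heading; then per agent its
initial waiting time; thereafter per activation the draws of the
selection protocol and chosen action, in protocol order.  Identical
seed and config give bit-identical trajectories.  Exact scheduling or
distance ties are broken uniformly at random; with continuous draws
they have probability zero and the rule only guards floating-point
coincidences.  Replicate r of a batch uses seed `base + r`, so any
single run of a sweep is reproducible in isolation.  Initial positions
are Normal(field center, σ = 10 m) per axis and headings uniform; by
torus symmetry the anchor point is irrelevant.

## Numerical and design notes

* View-cone membership is boundary-inclusive (≤ half the view angle),
  making a 360° angle exactly equivalent to no angular filter.
  Encounter detection respects the cone by default
  (`encounter_full_circle` exposes the alternative; it inflates the
  fleeing-model spread by ~7 m and is off in all study conditions).
* The aggressor scan applies the view cone and `AV_DIST` but no
  additional 50 m cap, so the probabilistic-avoidance settings with
  `AV_DIST` up to 70 m are expressible.
* The burn-in gates only the observers; trajectories are identical for
  any burn-in given the same seed.
* Undefined bearings (coincident agents) fall back to a uniform random
  heading.
* Snapshots record the state at the first activation time at or past
  each scheduled sampling instant, before that action executes.

## Scale of the shipped experiments

The test suite and the acceptance script run the full-length study
conditions (72,000 steps, N = 30) but with 3–10 replicates per setting
instead of 50, chosen so the whole battery runs in minutes on one CPU:
replicate means of the headline summaries are compared with the
published means within three published SDs, and ordering claims are
tested on setting means.  With 10 replicates the standard error of the
fleeing-model spread is ≈ 0.2 m, so the reduced replicate count is not
the limiting factor in those comparisons.

## Known limitations

* Against the published summaries, every group-spread setting
  reproduces ~5–7 % high (e.g. fleeing 38.9 m vs 36.4 ± 1.0; control
  corner 32.3 m vs 30.7 ± 0.4).  The offset is uniform across variants
  — including the rank-free fleeing control — indicating a small
  difference in the shared cohesion/diffusion balance relative to the
  original implementation, whose exact cohesion and velocity equations
  are not recoverable.  Qualitative results (centrality gradients,
  encounter bands, all sweep orderings) are unaffected.
* At the subgroup setting (`AV_DIST` = 35 m, `AV_DOM_DIFF` = 0.2) the
  agents self-sort into the described rank-band arrangement, but the
  equilibrium presses against the `FAR_DIST` cap and grouping
  approaches keep adjacent bands in contact: cross-band encounters
  remain ~55 % rather than near zero.  The corresponding test is left
  failing rather than loosened; see the spread offset above for the
  likely root cause.
* The AV_DOM_DIFF trend of group spread is tested on row means
  (averaged over `AV_DIST`): near the `FAR_DIST` cap the per-distance
  contrasts between adjacent thresholds fall below replicate noise at
  desk-scale replicate counts.
* The model omits, by design, dominance updating, ecology/foraging and
  travel, coalitions, post-conflict affiliation, formal submission
  signals, and attention/vigilance variation.  Subgroups here assort
  purely by rank; real fission-fusion also tracks kinship and
  affiliation.
* Synthetic dynamics only: the simulator *is* the data source.  What
  passing tests show is internal consistency with the stated rules and
  published summaries — not fidelity to any empirical animal group.
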