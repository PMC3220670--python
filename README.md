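# troopsim

Event-driven agent-based model of socio-spatial structure in
dominance-structured animal groups.

In many group-living animals — macaques, capuchins and baboons are the
classic examples — dominant individuals are found near the spatial
center of the group and subordinates at its periphery.  `troopsim`
simulates a group of agents with a fixed dominance hierarchy on a
continuous torus and shows how this central-peripheral pattern, the
group's spread, its encounter network and even spatially distinct
subgroups can self-organize from purely local movement rules, with no
agent preferring any location.  It is aimed at behavioral ecologists
and modelers studying self-organized social structure.

## The model

Thirty agents (configurable) live on a 300 m × 300 m torus.  Agent *i*
carries a fixed dominance strength *D<sub>i</sub>* = *i*/*N*.  Agents
activate asynchronously: each waits an exponentially distributed time
(mean 10 steps) between actions, and the agent with the lowest
scheduled time acts next.  On activation an agent runs a strict
priority protocol:

1. **Interact** — if another agent is within the 4 m personal distance
   (in the 120° view cone), resolve a contest with the nearest one.
2. **Cohesion override** — if the furthest group member is beyond
   `FAR_DIST` (110 m), approach a randomly chosen member.
3. **Group** — if fewer than 3 others are within 20 m in view,
   approach a visible member (1 m).
4. **Avoid** (avoidance variants) — if a *potential aggressor*
   (dominance gap > `AV_DOM_DIFF`) is seen within `AV_DIST`, step 2 m
   directly away from the nearest one.
5. **Random walk** — step 1 m forward; with chance 0.5 turn by a
   uniform angle up to ±180°.

Contests follow a sigmoid win chance in the dominance difference,

&nbsp;&nbsp;&nbsp;&nbsp;*w<sub>AB</sub>* = 1 / (1 + e^(−β (*D_A* − *D_B*))),&nbsp;&nbsp;β = 6,

with a challenge/decline/fight decision tree: the initiator flees
outright with probability 1 − *w*, the challenged opponent flees with
probability *w*², and a fight (probability *w*(1 − *w*)) makes the
loser flee 2 m while the winner chases 1 m.  Dominance values never
change (stable hierarchy).

Four model variants isolate different mechanisms: **fleeing** (contests
only), **avoidance** (contests + proactive avoidance), **avoidance
with fleeing control** (avoidance with every win chance forced to 0.5)
and **velocity** (no avoidance, even win chances, step length inversely
related to rank: *v<sub>i</sub>* = `MAX_VELOCITY` · (1 − *D<sub>i</sub>* + 1/*N*)).

Observers sample every 900 steps over the last 36,000 of 72,000 steps:
distance to the wrap-corrected group center, a circular
centrality-peripherality index (mean resultant length of bearings to
all others), the furthest-neighbor distance (group spread), the dyadic
distance matrix, and the directed encounter matrix (all occurrences).

## Worked example

```python
from troopsim import ModelConfig, run, centrality_gradient

summary = run(ModelConfig(variant="fleeing", seed=1))
print(f"group spread: {summary.mean_spread:.1f} m")
print(f"encounters recorded: {summary.encounters.sum()}")

slope, rho, p = centrality_gradient([summary])
print(f"dominance vs distance-to-center: slope {slope:.1f} m, "
      f"Spearman rho {rho:.2f} (p = {p:.1e})")
```

prints

```
group spread: 39.1 m
encounters recorded: 28082
dominance vs distance-to-center: slope -4.7 m, Spearman rho -0.87 (p = 3.9e-10)
```

The group settles at a spread of about 39 m, and the negative gradient
says that high-ranking agents sit several meters closer to the group
center than low-ranking ones — the central-peripheral pattern, emerging
with no spatial preference anywhere in the rules.  The same object
exposes the per-agent averages (`summary.agent_frame()`), the dyadic
matrix and the encounter matrix.

From a shell:

```bash
troopsim run --variant avoidance --seed 1 -p av_dist=35 -p av_dom_diff=0.2 --out out/
troopsim sweep --config sweep.yaml --out sweep_out/
troopsim report sweep_out/
```

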