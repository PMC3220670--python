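"""Hierarchical action selection.

On activation an agent runs a fixed-priority decision protocol and
performs exactly one action:

1. interact  — another agent sits within the personal distance: resolve
   a dyadic encounter with the nearest one;
2. far_approach — the furthest group member exceeds FAR_DIST (cohesion
   override, only while fission is restricted): approach a random
   member;
3. group_approach — fewer than MIN_OTHERS neighbors within NEAR_DIST in
   view: approach a visible member (widening the search to the full
   circle and then to any range if needed);
4. avoid — a potential aggressor is within AV_DIST (avoidance variants
   only): step directly away from the nearest one;
5. random_walk — step forward, then with chance 0.5 turn by a uniform
   angle up to the maximum turning angle.

The priorities encode urgency, not temporal order: reacting to a
contact always wins, staying with the group beats avoiding, and
avoidance beats undirected movement.
"""

import numpy as np
from numba import njit

from .geometry import (angle_difference, bearing, displace, torus_distance,
                       within_view)
from .interaction import avoidance_chance, is_potential_aggressor

# action kind codes
INTERACT = 0
FAR_APPROACH = 1
GROUP_APPROACH = 2
AVOID = 3
RANDOM_WALK = 4

ACTION_NAMES = ("interact", "far_approach", "group_approach", "avoid",
                "random_walk")

__all__ = [
    "INTERACT", "FAR_APPROACH", "GROUP_APPROACH", "AVOID", "RANDOM_WALK",
    "ACTION_NAMES", "select_action", "needs_grouping", "find_aggressor",
    "random_walk", "turn_and_step", "avoid_move", "agent_step_lengths",
]


@njit(cache=True)
def _in_cone(i, j, pos, heading, L, view_angle):
    """Angular part of the visibility test (no range check)."""
    if view_angle >= 360.0:
        return True
    b = bearing(pos[i, 0], pos[i, 1], pos[j, 0], pos[j, 1], L)
    if np.isnan(b):
        return True
    return angle_difference(b, heading[i]) <= 0.5 * view_angle


@njit(cache=True)
def needs_grouping(i, pos, heading, L, near_dist, view_angle, min_others):
    """True iff fewer than min_others others are within near_dist in view."""
    n = pos.shape[0]
    count = 0
    for j in range(n):
        if j == i:
            continue
        if within_view(pos[i, 0], pos[i, 1], heading[i],
                       pos[j, 0], pos[j, 1], view_angle, near_dist, L):
            count += 1
            if count >= min_others:
                return False
    return True


@njit(cache=True)
def find_aggressor(i, pos, heading, dom, L, view_angle, av_dist,
                   av_dom_diff, probabilistic, slope):
    """Nearest potential aggressor within av_dist in view, or -1.

    Discrete mode: an aggressor is any visible agent whose dominance
    exceeds ego's by strictly more than av_dom_diff.  Probabilistic
    mode: each visible candidate is treated as an aggressor with the
    sigmoid avoidance chance (one uniform draw per candidate, scanned
    in id order).  Exact distance ties are broken uniformly.
    """
    n = pos.shape[0]
    best = -1
    best_d = np.inf
    ties = 1
    for j in range(n):
        if j == i:
            continue
        d = torus_distance(pos[i, 0], pos[i, 1], pos[j, 0], pos[j, 1], L)
        if d >= av_dist:
            continue
        if not _in_cone(i, j, pos, heading, L, view_angle):
            continue
        if probabilistic:
            p = avoidance_chance(dom[j] - dom[i], av_dom_diff, slope)
            if np.random.random() >= p:
                continue
        elif not is_potential_aggressor(dom[j], dom[i], av_dom_diff):
            continue
        if d < best_d:
            best = j
            best_d = d
            ties = 1
        elif d == best_d:
            ties += 1
            if np.random.random() < 1.0 / ties:
                best = j
    return best


@njit(cache=True)
def _nearest_in_personal_distance(i, pos, heading, L, pers_dist,
                                  view_angle, full_circle):
    """Nearest other within pers_dist (view-limited unless full_circle)."""
    n = pos.shape[0]
    best = -1
    best_d = np.inf
    ties = 1
    for j in range(n):
        if j == i:
            continue
        d = torus_distance(pos[i, 0], pos[i, 1], pos[j, 0], pos[j, 1], L)
        if d > pers_dist:
            continue
        if not full_circle and not _in_cone(i, j, pos, heading, L, view_angle):
            continue
        if d < best_d:
            best = j
            best_d = d
            ties = 1
        elif d == best_d:
            ties += 1
            if np.random.random() < 1.0 / ties:
                best = j
    return best


@njit(cache=True)
def _grouping_candidate(i, pos, heading, L, max_dist, view_angle):
    """Pick the agent to approach when grouping is needed.

    Search widens in three tiers: within view and max_dist; full circle
    within max_dist; full circle at any range (fallback that prevents
    deadlock when the group has drifted beyond perception range).  One
    candidate is chosen uniformly from the first non-empty tier.
    """
    n = pos.shape[0]
    cand = np.empty(n, dtype=np.int64)
    for tier in range(3):
        k = 0
        for j in range(n):
            if j == i:
                continue
            if tier < 2:
                d = torus_distance(pos[i, 0], pos[i, 1],
                                   pos[j, 0], pos[j, 1], L)
                if d > max_dist:
                    continue
                if tier == 0 and not _in_cone(i, j, pos, heading, L,
                                              view_angle):
                    continue
            cand[k] = j
            k += 1
        if k > 0:
            return cand[int(np.random.random() * k)]
    return -1


@njit(cache=True)
def select_action(i, pos, heading, dom, L,
                  pers_dist, near_dist, max_dist, far_dist, min_others,
                  view_angle, use_avoidance, av_dom_diff, av_dist,
                  probabilistic_avoidance, avoidance_slope,
                  fission_restricted, encounter_full_circle):
    """Run the priority protocol for agent i.

    Returns (kind, target); target is -1 for random_walk and the chosen
    partner otherwise.
    """
    n = pos.shape[0]

    # 1. encounter
    j = _nearest_in_personal_distance(i, pos, heading, L, pers_dist,
                                      view_angle, encounter_full_circle)
    if j >= 0:
        return INTERACT, j

    # 2. cohesion override: furthest member too far away
    if fission_restricted:
        far = 0.0
        for k in range(n):
            if k == i:
                continue
            d = torus_distance(pos[i, 0], pos[i, 1], pos[k, 0], pos[k, 1], L)
            if d > far:
                far = d
        if far > far_dist:
            target = int(np.random.random() * (n - 1))
            if target >= i:
                target += 1
            return FAR_APPROACH, target

    # 3. grouping
    if needs_grouping(i, pos, heading, L, near_dist, view_angle, min_others):
        target = _grouping_candidate(i, pos, heading, L, max_dist, view_angle)
        if target >= 0:
            return GROUP_APPROACH, target
        return RANDOM_WALK, -1  # N == 1 degenerate world

    # 4. avoidance
    if use_avoidance:
        target = find_aggressor(i, pos, heading, dom, L, view_angle,
                                av_dist, av_dom_diff,
                                probabilistic_avoidance, avoidance_slope)
        if target >= 0:
            return AVOID, target

    # 5. random walk
    return RANDOM_WALK, -1


@njit(cache=True)
def turn_and_step(i, target, pos, heading, L, step):
    """Turn toward a target agent and approach it by `step` meters."""
    b = bearing(pos[i, 0], pos[i, 1], pos[target, 0], pos[target, 1], L)
    if np.isnan(b):
        b = np.random.random() * 360.0
    heading[i] = b
    pos[i, 0], pos[i, 1] = displace(pos[i, 0], pos[i, 1], b, step, L)


@njit(cache=True)
def avoid_move(i, target, pos, heading, L, avoid_d):
    """Turn directly away from a detected aggressor and walk avoid_d."""
    away = bearing(pos[target, 0], pos[target, 1], pos[i, 0], pos[i, 1], L)
    if np.isnan(away):
        away = np.random.random() * 360.0
    heading[i] = away
    pos[i, 0], pos[i, 1] = displace(pos[i, 0], pos[i, 1], away, avoid_d, L)


@njit(cache=True)
def random_walk(i, pos, heading, L, step, max_turn_angle):
    """Move forward, then with chance 0.5 turn by U(-max_turn, +max_turn).

    The order is move-then-turn, so the heading after the call is the
    direction of the *next* undisturbed step.
    """
    pos[i, 0], pos[i, 1] = displace(pos[i, 0], pos[i, 1], heading[i], step, L)
    if np.random.random() < 0.5:
        turn = (2.0 * np.random.random() - 1.0) * max_turn_angle
        heading[i] = (heading[i] + turn) % 360.0


def agent_step_lengths(config, dom=None):
    """Per-agent voluntary step length (random walk and grouping moves).

    Non-velocity variants use WalkD for everyone.  The velocity variant
    scales the step inversely with rank, v_i = MAX_VELOCITY * (1 - D_i
    + 1/N): the lowest rank moves MAX_VELOCITY per activation, the top
    rank MAX_VELOCITY / N.  Reactive displacements (flee, chase, avoid)
    are never scaled.  With ``equal_velocities`` every agent gets the
    across-rank mean step (null control).
    """
    from .world import assign_dominance

    n = config.n_agents
    if dom is None:
        dom = assign_dominance(n, config.max_dom)
    if config.variant != "velocity":
        return np.full(n, config.walk_d)
    v = config.max_velocity * (1.0 - dom / config.max_dom + 1.0 / n)
    if config.equal_velocities:
        v = np.full(n, v.mean())
    return v
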