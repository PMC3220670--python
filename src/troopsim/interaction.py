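"""Dyadic encounter resolution.

An activated agent that perceives another within its personal distance
selects the nearest one and either challenges it or flees.  The
decision tree is driven by the sigmoid win chance

    w_AB = 1 / (1 + exp(-beta * (D_A - D_B))),    beta = 6 / MAX_DOM,

which depends only on the dominance difference and satisfies
w_AB + w_BA = 1.  The initiator challenges when w exceeds a uniform
draw, otherwise it flees outright ("unprovoked fleeing").  A challenged
opponent agrees to fight when its own win chance 1 - w exceeds a fresh
draw, otherwise it flees ("fleeing after threat").  Only if both agree
does a fight occur; the winner is again drawn with probability w, the
loser flees FleeD away and the winner chases ChaseD after it.
Dominance values are never updated (stable hierarchy).

In the fleeing-control variants every pairwise win chance is forced to
0.5, removing all rank dependence from fleeing while leaving the
mechanics untouched.
"""

import math

import numpy as np
from numba import njit

from .geometry import bearing, displace

# outcome codes returned by resolve_encounter
INITIATOR_FLED = 0
TARGET_FLED_AFTER_THREAT = 1
FIGHT = 2

OUTCOME_NAMES = ("initiator_fled", "target_fled_after_threat", "fight")

__all__ = [
    "INITIATOR_FLED",
    "TARGET_FLED_AFTER_THREAT",
    "FIGHT",
    "OUTCOME_NAMES",
    "win_chance",
    "is_potential_aggressor",
    "avoidance_chance",
    "resolve_encounter",
    "outcome_probabilities",
    "simulate_encounters",
]


@njit(cache=True)
def win_chance(d_a, d_b, beta):
    """Chance that an agent with dominance d_a beats one with d_b."""
    return 1.0 / (1.0 + math.exp(-beta * (d_a - d_b)))


@njit(cache=True)
def is_potential_aggressor(d_other, d_ego, av_dom_diff):
    """Strict cut-off rule: avoided iff d_other - d_ego > av_dom_diff."""
    return d_other - d_ego > av_dom_diff


@njit(cache=True)
def avoidance_chance(delta, inflection, slope):
    """Sigmoid avoidance chance for the probabilistic-avoidance mode.

    Equals 0.5 at the inflection point and approaches the discrete
    cut-off as the slope grows.
    """
    return 1.0 / (1.0 + math.exp(-slope * (delta - inflection)))


@njit(cache=True)
def _flee(a, b, pos, heading, L, flee_d):
    """Agent a turns directly away from agent b and flees flee_d."""
    away = bearing(pos[b, 0], pos[b, 1], pos[a, 0], pos[a, 1], L)
    if np.isnan(away):  # coincident: direction undefined, pick random
        away = np.random.random() * 360.0
    heading[a] = away
    pos[a, 0], pos[a, 1] = displace(pos[a, 0], pos[a, 1], away, flee_d, L)


@njit(cache=True)
def _maybe_reorient(a, heading):
    """With chance 0.5 the fleer's opponent turns to a random direction.

    Applied after both settlement types (unprovoked fleeing and fleeing
    after threat); staying oriented at the fleer would cause repeated
    interactions.  Consumes one uniform draw, plus one more when the
    reorientation happens.
    """
    if np.random.random() < 0.5:
        heading[a] = np.random.random() * 360.0


@njit(cache=True)
def resolve_encounter(i, j, pos, heading, dom, L, beta,
                      flee_d, chase_d, equal_win_chance):
    """Resolve one directed encounter i -> j, updating state in place.

    Returns (outcome code, winner id) with winner = -1 unless a fight
    took place.  Draw order: u1 (challenge), u2 (opponent agrees),
    u3 (fight winner), then the flee/reorientation draws.
    """
    if equal_win_chance:
        w = 0.5
    else:
        w = win_chance(dom[i], dom[j], beta)
    if w <= np.random.random():
        # ego declines to challenge and flees at once
        _flee(i, j, pos, heading, L, flee_d)
        _maybe_reorient(j, heading)
        return INITIATOR_FLED, -1
    if (1.0 - w) <= np.random.random():
        # opponent declines the challenge and flees
        _flee(j, i, pos, heading, L, flee_d)
        _maybe_reorient(i, heading)
        return TARGET_FLED_AFTER_THREAT, -1
    # both agreed: fight; ego wins with probability w
    if w > np.random.random():
        winner, loser = i, j
    else:
        winner, loser = j, i
    _flee(loser, winner, pos, heading, L, flee_d)
    # chase: winner turns toward the loser's post-flee position
    b = bearing(pos[winner, 0], pos[winner, 1],
                pos[loser, 0], pos[loser, 1], L)
    if np.isnan(b):
        b = np.random.random() * 360.0
    heading[winner] = b
    pos[winner, 0], pos[winner, 1] = displace(
        pos[winner, 0], pos[winner, 1], b, chase_d, L)
    return FIGHT, winner


def outcome_probabilities(w):
    """Closed-form outcome distribution of the encounter decision tree.

    Returns (P(initiator flees), P(target flees after threat),
    P(fight), P(initiator wins | fight)).
    """
    return 1.0 - w, w * w, w * (1.0 - w), w


@njit(cache=True)
def _encounter_trials(n_trials, d_i, d_j, beta, L, flee_d, chase_d,
                      equal_win_chance):
    counts = np.zeros(3, dtype=np.int64)
    wins_i = 0
    pos = np.empty((2, 2))
    heading = np.empty(2)
    dom = np.empty(2)
    dom[0] = d_i
    dom[1] = d_j
    for _ in range(n_trials):
        pos[0, 0] = 100.0
        pos[0, 1] = 100.0
        pos[1, 0] = 102.0
        pos[1, 1] = 100.0
        heading[0] = 90.0
        heading[1] = 270.0
        outcome, winner = resolve_encounter(
            0, 1, pos, heading, dom, L, beta, flee_d, chase_d,
            equal_win_chance)
        counts[outcome] += 1
        if winner == 0:
            wins_i += 1
    return counts, wins_i


def simulate_encounters(w, n_trials, seed, beta=6.0, equal_win_chance=False):
    """Monte-Carlo harness: repeat a fresh two-agent encounter n times.

    The dominance gap is derived from the requested win chance w via the
    inverse logistic.  Returns (counts by outcome code, initiator fight
    wins).
    """
    from .world import seed_rng  # deferred to avoid an import cycle

    if not 0.0 < w < 1.0:
        raise ValueError("w must lie strictly between 0 and 1")
    delta = math.log(w / (1.0 - w)) / beta
    seed_rng(seed)
    counts, wins = _encounter_trials(
        int(n_trials), 0.5 + delta / 2.0, 0.5 - delta / 2.0, beta,
        300.0, 2.0, 1.0, equal_win_chance)
    return counts, wins
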