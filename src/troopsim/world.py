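"""World state, initialization, event-driven scheduling, main loop.

The simulation is event-driven and asynchronous: each agent carries a
continuous next-activation time; the agent with the lowest scheduled
time acts next, and every participant of the resulting action (the
actor, plus its partner for dyadic interactions) is rescheduled by a
fresh waiting-time draw — exponential with mean 10 steps by default,
or uniform on (0, 20) under the alternative regime (same mean).

All randomness of a run flows through one stream seeded once from the
config seed.  Draw order per run: for each agent in id order its
initial x, y, heading, then its initial waiting time; thereafter, per
activation, the draws of the action-selection protocol and of the
chosen action in protocol order.  Identical seed and config therefore
reproduce the trajectory bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from . import behavior, interaction, observers
from .config import ModelConfig

__all__ = [
    "assign_dominance",
    "seed_rng",
    "draw_interval",
    "draw_intervals",
    "init_world",
    "WorldState",
    "step",
    "run",
]


def assign_dominance(n, max_dom=1.0):
    """Equally spaced dominance strengths D_i = i * max_dom / N, i=1..N.

    The hierarchy is stable: these values never change during a run.
    """
    if n < 1:
        raise ValueError("need at least one agent")
    return np.arange(1, n + 1, dtype=float) * (max_dom / n)


@njit(cache=True)
def seed_rng(seed):
    """Seed the simulation RNG stream (numba's global generator)."""
    np.random.seed(seed)


@njit(cache=True)
def draw_interval(uniform_regime, mean_interval):
    """Waiting time until an agent's next activation (strictly > 0)."""
    t = 0.0
    while t <= 0.0:
        if uniform_regime:
            t = np.random.uniform(0.0, 2.0 * mean_interval)
        else:
            t = np.random.exponential(mean_interval)
    return t


@njit(cache=True)
def draw_intervals(uniform_regime, mean_interval, size):
    """Batch of waiting-time draws (for calibration checks)."""
    out = np.empty(size)
    for k in range(size):
        out[k] = draw_interval(uniform_regime, mean_interval)
    return out


@njit(cache=True)
def _init_state(n, L, sigma, uniform_regime, mean_interval):
    """Draw initial positions, headings and activation times.

    Positions are Normal(field center, sigma) per axis, wrapped;
    headings uniform on [0, 360).  The center is arbitrary: results
    cannot depend on it by torus symmetry.
    """
    pos = np.empty((n, 2))
    heading = np.empty(n)
    for i in range(n):
        pos[i, 0] = np.random.normal(0.5 * L, sigma) % L
        pos[i, 1] = np.random.normal(0.5 * L, sigma) % L
        heading[i] = np.random.random() * 360.0
    next_time = np.empty(n)
    for i in range(n):
        next_time[i] = draw_interval(uniform_regime, mean_interval)
    return pos, heading, next_time


@dataclass
class WorldState:
    """Mutable simulation state, advanced one activation at a time.

    ``run`` integrates the same kernels in one jitted loop; this class
    exists for inspection, debugging and contract tests.
    """

    config: ModelConfig
    dom: np.ndarray
    pos: np.ndarray
    heading: np.ndarray
    next_time: np.ndarray
    clock: float = 0.0
    encounters: np.ndarray = None
    action_counts: np.ndarray = None
    fights: np.ndarray = None
    fight_wins: np.ndarray = None

    def __post_init__(self):
        n = self.config.n_agents
        if self.encounters is None:
            self.encounters = np.zeros((n, n), dtype=np.int64)
        if self.action_counts is None:
            self.action_counts = np.zeros((n, 5), dtype=np.int64)
        if self.fights is None:
            self.fights = np.zeros(n, dtype=np.int64)
        if self.fight_wins is None:
            self.fight_wins = np.zeros(n, dtype=np.int64)


def init_world(config: ModelConfig) -> WorldState:
    """Seed the stream from config.seed and draw the initial state."""
    seed_rng(config.seed)
    pos, heading, next_time = _init_state(
        config.n_agents, config.L, config.init_sigma,
        config.timing_regime == "uniform", config.mean_interval)
    return WorldState(config=config,
                      dom=assign_dominance(config.n_agents, config.max_dom),
                      pos=pos, heading=heading, next_time=next_time)


def step(state: WorldState) -> int:
    """Advance the world by one activation; returns the acting agent id.

    The agent with the lowest scheduled time acts; the clock advances
    to that time; the agent — and its partner, if the action was an
    interaction — is rescheduled by a fresh waiting-time draw.
    Encounters are always recorded here (the recording window only
    applies inside ``run``).
    """
    config = state.config
    step_len = behavior.agent_step_lengths(config, state.dom)
    i = _next_agent(state.next_time)
    t = state.next_time[i]
    if t < state.clock:
        raise RuntimeError("scheduler clock moved backwards")
    state.clock = t
    partner = _activate(
        i, state.pos, state.heading, state.dom, step_len,
        state.encounters, True, state.action_counts, state.fights,
        state.fight_wins,
        config.L, config.pers_dist, config.near_dist, config.max_dist,
        config.far_dist, config.min_others, config.view_angle,
        config.uses_avoidance, config.av_dom_diff, config.av_dist,
        config.avoidance_mode == "probabilistic", config.avoidance_slope,
        config.fission_restricted, config.encounter_full_circle,
        config.beta, config.flee_d, config.chase_d, config.avoid_d,
        config.max_turn_angle, config.equal_win_chance)
    uniform = config.timing_regime == "uniform"
    state.next_time[i] = t + draw_interval(uniform, config.mean_interval)
    if partner >= 0:
        state.next_time[partner] = t + draw_interval(uniform,
                                                     config.mean_interval)
    return i


@njit(cache=True)
def _next_agent(next_time):
    """Index of the minimum next_time; exact ties broken uniformly."""
    n = next_time.shape[0]
    best = 0
    ties = 1
    for i in range(1, n):
        if next_time[i] < next_time[best]:
            best = i
            ties = 1
        elif next_time[i] == next_time[best]:
            ties += 1
            if np.random.random() < 1.0 / ties:
                best = i
    return best


@njit(cache=True)
def _activate(i, pos, heading, dom, step_len, encounters, record,
              action_counts, fights, fight_wins,
              L, pers_dist, near_dist, max_dist, far_dist, min_others,
              view_angle, use_avoidance, av_dom_diff, av_dist,
              probabilistic_avoidance, avoidance_slope, fission_restricted,
              encounter_full_circle, beta, flee_d, chase_d, avoid_d,
              max_turn_angle, equal_win_chance):
    """One activation of agent i.  Returns the partner id (-1 if none)."""
    kind, target = behavior.select_action(
        i, pos, heading, dom, L, pers_dist, near_dist, max_dist, far_dist,
        min_others, view_angle, use_avoidance, av_dom_diff, av_dist,
        probabilistic_avoidance, avoidance_slope, fission_restricted,
        encounter_full_circle)
    action_counts[i, kind] += 1
    if kind == behavior.INTERACT:
        if record:
            encounters[i, target] += 1
        outcome, winner = interaction.resolve_encounter(
            i, target, pos, heading, dom, L, beta, flee_d, chase_d,
            equal_win_chance)
        if outcome == interaction.FIGHT:
            fights[i] += 1
            fights[target] += 1
            fight_wins[winner] += 1
        return target
    if kind == behavior.FAR_APPROACH or kind == behavior.GROUP_APPROACH:
        behavior.turn_and_step(i, target, pos, heading, L, step_len[i])
        return -1
    if kind == behavior.AVOID:
        behavior.avoid_move(i, target, pos, heading, L, avoid_d)
        return -1
    behavior.random_walk(i, pos, heading, L, step_len[i], max_turn_angle)
    return -1


@njit(cache=True)
def _simulate(seed, n, dom, step_len,
              L, init_sigma, pers_dist, near_dist, max_dist, far_dist,
              min_others, view_angle, beta, flee_d, chase_d, avoid_d,
              av_dom_diff, av_dist, max_turn_angle, mean_interval,
              total_steps, burn_in, sample_every, n_snap,
              use_avoidance, equal_win_chance, fission_restricted,
              uniform_regime, probabilistic_avoidance, avoidance_slope,
              encounter_full_circle):
    """Full event-driven run; returns the raw observer arrays."""
    np.random.seed(seed)
    pos, heading, next_time = _init_state(n, L, init_sigma, uniform_regime,
                                          mean_interval)

    dist_center = np.zeros((n_snap, n))
    centrality = np.zeros((n_snap, n))
    spread = np.zeros(n_snap)
    snap_times = np.zeros(n_snap)
    dyadic_sum = np.zeros((n, n))
    encounters = np.zeros((n, n), dtype=np.int64)
    activations = np.zeros(n, dtype=np.int64)
    action_counts = np.zeros((n, 5), dtype=np.int64)
    fights = np.zeros(n, dtype=np.int64)
    fight_wins = np.zeros(n, dtype=np.int64)

    snap_idx = 0
    next_snap = burn_in + sample_every
    while True:
        i = _next_agent(next_time)
        t = next_time[i]
        # snapshots due before this activation: record current state
        while snap_idx < n_snap and t >= next_snap:
            observers.record_snapshot(pos, L, snap_idx, dist_center,
                                      centrality, spread, dyadic_sum)
            snap_times[snap_idx] = next_snap
            snap_idx += 1
            next_snap += sample_every
        if t >= total_steps:
            break
        activations[i] += 1
        partner = _activate(
            i, pos, heading, dom, step_len, encounters, t > burn_in,
            action_counts, fights, fight_wins,
            L, pers_dist, near_dist, max_dist, far_dist, min_others,
            view_angle, use_avoidance, av_dom_diff, av_dist,
            probabilistic_avoidance, avoidance_slope, fission_restricted,
            encounter_full_circle, beta, flee_d, chase_d, avoid_d,
            max_turn_angle, equal_win_chance)
        next_time[i] = t + draw_interval(uniform_regime, mean_interval)
        if partner >= 0:
            next_time[partner] = t + draw_interval(uniform_regime,
                                                   mean_interval)
    return (pos, heading, snap_times, dist_center, centrality, spread,
            dyadic_sum, encounters, activations, action_counts, fights,
            fight_wins)


def run(config: ModelConfig) -> observers.RunSummary:
    """Execute one full simulation run and return its RunSummary."""
    dom = assign_dominance(config.n_agents, config.max_dom)
    step_len = behavior.agent_step_lengths(config, dom)
    (_, _, snap_times, dist_center, centrality, spread, dyadic_sum,
     encounters, activations, action_counts, fights, fight_wins) = _simulate(
        int(config.seed), config.n_agents, dom, step_len,
        config.L, config.init_sigma, config.pers_dist, config.near_dist,
        config.max_dist, config.far_dist, config.min_others,
        config.view_angle, config.beta, config.flee_d, config.chase_d,
        config.avoid_d, config.av_dom_diff, config.av_dist,
        config.max_turn_angle, config.mean_interval,
        float(config.total_steps), float(config.burn_in),
        float(config.sample_every), config.n_snapshots,
        config.uses_avoidance, config.equal_win_chance,
        config.fission_restricted, config.timing_regime == "uniform",
        config.avoidance_mode == "probabilistic", config.avoidance_slope,
        config.encounter_full_circle)
    return observers.summarize_run(config, dom, snap_times, dist_center,
                                   centrality, spread, dyadic_sum,
                                   encounters, activations, action_counts,
                                   fights, fight_wins)
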