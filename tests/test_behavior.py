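"""Action-selection protocol: priorities, grouping, avoidance, walking."""

import numpy as np
import pytest

from troopsim import ModelConfig, behavior
from troopsim.geometry import torus_distance
from troopsim.world import seed_rng

L = 300.0
DEFAULTS = dict(pers_dist=4.0, near_dist=20.0, max_dist=50.0,
                far_dist=110.0, min_others=3, view_angle=120.0,
                use_avoidance=False, av_dom_diff=0.2, av_dist=5.0,
                probabilistic_avoidance=False, avoidance_slope=30.0,
                fission_restricted=True, encounter_full_circle=False)


def select(i, pos, heading, dom, **overrides):
    p = {**DEFAULTS, **overrides}
    return behavior.select_action(
        i, pos, heading, dom, L, p["pers_dist"], p["near_dist"],
        p["max_dist"], p["far_dist"], p["min_others"], p["view_angle"],
        p["use_avoidance"], p["av_dom_diff"], p["av_dist"],
        p["probabilistic_avoidance"], p["avoidance_slope"],
        p["fission_restricted"], p["encounter_full_circle"])


def _world(ego_xy, others_xy, ego_heading=0.0, doms=None):
    """Ego is agent 0, heading north by default."""
    pos = np.array([ego_xy] + list(others_xy), dtype=float)
    heading = np.zeros(len(pos))
    heading[0] = ego_heading
    dom = (np.asarray(doms, dtype=float) if doms is not None
           else np.linspace(1.0, 0.1, len(pos)))
    return pos, heading, dom


class TestPriorities:
    def test_encounter_beats_everything(self):
        seed_rng(0)
        # an agent dead ahead at 3 m, nothing else nearby
        pos, heading, dom = _world((150, 150), [(150, 153)])
        kind, target = select(0, pos, heading, dom, use_avoidance=True)
        assert (kind, target) == (behavior.INTERACT, 1)

    def test_nearest_agent_is_the_partner(self):
        seed_rng(0)
        pos, heading, dom = _world((150, 150), [(150, 153), (150, 152)])
        kind, target = select(0, pos, heading, dom)
        assert (kind, target) == (behavior.INTERACT, 2)

    def test_agent_behind_is_not_encountered_by_default(self):
        seed_rng(0)
        pos, heading, dom = _world((150, 150), [(150, 147)])
        kind, _ = select(0, pos, heading, dom)
        assert kind != behavior.INTERACT
        kind, _ = select(0, pos, heading, dom, encounter_full_circle=True)
        assert kind == behavior.INTERACT

    def test_far_override_beats_grouping(self):
        seed_rng(0)
        # three neighbors ahead satisfy grouping, one member beyond 110 m
        others = [(150, 160), (148, 162), (152, 161), (150, 265)]
        pos, heading, dom = _world((150, 150), others)
        kind, target = select(0, pos, heading, dom)
        assert kind == behavior.FAR_APPROACH
        kind, _ = select(0, pos, heading, dom, fission_restricted=False)
        assert kind != behavior.FAR_APPROACH

    def test_far_not_triggered_within_tolerance(self):
        seed_rng(0)
        others = [(150, 160), (148, 162), (152, 161), (150, 250)]  # 100 m
        pos, heading, dom = _world((150, 150), others)
        assert select(0, pos, heading, dom)[0] == behavior.RANDOM_WALK

    def test_avoidance_after_grouping_satisfied(self):
        seed_rng(0)
        # grouping satisfied; dominant agent at 10 m triggers avoidance
        others = [(150, 160), (148, 162), (152, 161), (150, 140)]
        doms = [0.3, 0.2, 0.25, 0.1, 0.9]
        pos, heading, dom = _world((150, 150), others, doms=doms)
        kind, target = select(0, pos, heading, dom, use_avoidance=True,
                              av_dist=15.0, encounter_full_circle=False)
        # aggressor is behind ego (south), outside the view cone
        assert kind == behavior.RANDOM_WALK
        pos2 = pos.copy()
        pos2[4] = (150, 160 + 0)  # put the dominant ahead instead
        pos2[0] = (150, 150)
        doms2 = [0.3, 0.9, 0.25, 0.1, 0.2]
        dom2 = np.array(doms2)
        kind, target = select(0, pos2, heading, dom2, use_avoidance=True,
                              av_dist=15.0)
        assert (kind, target) == (behavior.AVOID, 1)

    def test_walk_when_nothing_else_applies(self):
        seed_rng(0)
        others = [(150, 160), (148, 162), (152, 161)]
        pos, heading, dom = _world((150, 150), others)
        assert select(0, pos, heading, dom)[0] == behavior.RANDOM_WALK


class TestGrouping:
    def test_needs_grouping_counts_only_in_view(self):
        pos, heading, dom = _world((150, 150),
                                   [(150, 165), (149, 164), (151, 166)])
        assert not behavior.needs_grouping(0, pos, heading, L, 20.0,
                                           120.0, 3)
        # same three members behind ego
        pos, heading, dom = _world((150, 150),
                                   [(150, 135), (149, 136), (151, 134)])
        assert behavior.needs_grouping(0, pos, heading, L, 20.0, 120.0, 3)

    def test_single_member_ahead_is_approached_by_one_step(self):
        seed_rng(0)
        pos, heading, dom = _world((150, 150), [(150, 180)])
        kind, target = select(0, pos, heading, dom)
        assert (kind, target) == (behavior.GROUP_APPROACH, 1)
        behavior.turn_and_step(0, 1, pos, heading, L, 1.0)
        assert heading[0] == pytest.approx(0.0)
        assert torus_distance(*pos[0], *pos[1], L) == pytest.approx(29.0)

    def test_members_behind_found_via_full_circle_fallback(self):
        seed_rng(0)
        pos, heading, dom = _world((150, 150), [(150, 120), (152, 118)])
        kind, target = select(0, pos, heading, dom)
        assert kind == behavior.GROUP_APPROACH
        assert target in (1, 2)

    def test_distant_members_found_via_any_range_fallback(self):
        seed_rng(0)
        pos, heading, dom = _world((150, 150), [(150, 230)])  # 80 m away
        kind, target = select(0, pos, heading, dom,
                              fission_restricted=False)
        assert (kind, target) == (behavior.GROUP_APPROACH, 1)

    def test_equidistant_candidates_chosen_evenly(self):
        seed_rng(1)
        pos, heading, dom = _world((150, 150), [(140, 150), (160, 150)])
        picks = [select(0, pos, heading, dom)[1] for _ in range(400)]
        frac = np.mean(np.array(picks) == 1)
        assert 0.4 < frac < 0.6


class TestAvoidance:
    def test_nearest_aggressor_selected(self):
        seed_rng(0)
        pos, heading, dom = _world((150, 150), [(150, 158), (150, 162)],
                                   doms=[0.2, 0.8, 0.9])
        target = behavior.find_aggressor(0, pos, heading, dom, L, 120.0,
                                         15.0, 0.2, False, 30.0)
        assert target == 1

    def test_out_of_range_or_small_gap_ignored(self):
        seed_rng(0)
        pos, heading, dom = _world((150, 150), [(150, 170)],
                                   doms=[0.2, 0.9])
        assert behavior.find_aggressor(0, pos, heading, dom, L, 120.0,
                                       15.0, 0.2, False, 30.0) == -1
        pos, heading, dom = _world((150, 150), [(150, 155)],
                                   doms=[0.3, 0.4])
        assert behavior.find_aggressor(0, pos, heading, dom, L, 120.0,
                                       15.0, 0.2, False, 30.0) == -1

    def test_avoid_move_is_directly_away(self):
        seed_rng(0)
        pos, heading, dom = _world((150, 150), [(150, 160)])
        behavior.avoid_move(0, 1, pos, heading, L, 2.0)
        assert heading[0] == pytest.approx(180.0)
        assert pos[0] == pytest.approx((150.0, 148.0))

    def test_probabilistic_mode_soft_cutoff(self):
        seed_rng(2)
        pos, heading, dom = _world((150, 150), [(150, 158)],
                                   doms=[0.2, 0.9])
        hits = sum(
            behavior.find_aggressor(0, pos, heading, dom, L, 120.0, 15.0,
                                    0.4, True, 5.0) == 1
            for _ in range(2000))
        # sigmoid chance at delta 0.7, inflection 0.4, slope 5: 0.818
        assert abs(hits / 2000 - 0.818) < 0.04


class TestRandomWalk:
    def test_moves_forward_then_sometimes_turns(self):
        seed_rng(3)
        turns = 0
        n = 2000
        for _ in range(n):
            pos = np.array([[150.0, 150.0]])
            heading = np.array([37.0])
            behavior.random_walk(0, pos, heading, L, 1.0, 180.0)
            d = torus_distance(150.0, 150.0, *pos[0], L)
            assert d == pytest.approx(1.0)
            turns += heading[0] != 37.0
        assert abs(turns / n - 0.5) < 0.04

    def test_turn_bounded_by_max_turn_angle(self):
        seed_rng(4)
        for _ in range(500):
            pos = np.array([[150.0, 150.0]])
            heading = np.array([0.0])
            behavior.random_walk(0, pos, heading, L, 1.0, 45.0)
            h = heading[0]
            assert h <= 45.0 or h >= 315.0

    def test_smaller_turn_angle_gives_more_persistent_paths(self):
        """Correlated-random-walk property: restricting the turning
        angle increases net displacement over a fixed number of steps."""
        seed_rng(5)

        def net_displacement(max_turn, n_steps=60, trials=150):
            total = 0.0
            for _ in range(trials):
                pos = np.array([[150.0, 150.0]])
                heading = np.array([0.0])
                for _ in range(n_steps):
                    behavior.random_walk(0, pos, heading, L, 1.0, max_turn)
                total += torus_distance(150.0, 150.0, *pos[0], L)
            return total / trials

        assert net_displacement(45.0) > net_displacement(180.0) * 1.5


class TestStepLengths:
    def test_non_velocity_variants_use_walk_d(self):
        v = behavior.agent_step_lengths(ModelConfig())
        assert np.all(v == 1.0)

    def test_velocity_variant_inverse_in_rank(self):
        cfg = ModelConfig(variant="velocity", max_velocity=30.0)
        v = behavior.agent_step_lengths(cfg)
        assert v[0] == pytest.approx(30.0)   # lowest rank is fastest
        assert v[-1] == pytest.approx(1.0)   # top rank: max_velocity / N
        assert np.all(np.diff(v) < 0)

    def test_equal_velocities_null_control(self):
        cfg = ModelConfig(variant="velocity", max_velocity=30.0,
                          equal_velocities=True)
        v = behavior.agent_step_lengths(cfg)
        assert np.allclose(v, v[0])
        assert v[0] == pytest.approx(
            behavior.agent_step_lengths(
                cfg.replace(equal_velocities=False)).mean())
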