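"""Unit tests of the six sub-models against worked examples and oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from antdrip.lattice import (STABLE, UNSTABLE, UNDEFINED, World,
                             compute_weights, compute_weights_bruteforce)
from antdrip.params import SimParams
from antdrip import submodels as sm

from conftest import make_world


# ---------------------------------------------------------------- spawning

class TestSpawn:
    def test_single_entry_spawns_phi_agents(self, rng):
        w = World()
        sm.spawn_agents(w, SimParams(), rng)
        assert len(w.active) == 1
        assert w.active[0].pos == (500, 500)

    def test_multi_entry_frequencies_uniform(self, rng):
        # 3000 spawns over three entry heights: each within 3 sigma of 1/3
        p = SimParams(entry_positions=((500, 500), (500, 499), (500, 498)),
                      phi=1)
        w = World()
        for _ in range(3000):
            sm.spawn_agents(w, p, rng)
        counts = {pos: 0 for pos in p.entry_positions}
        for a in w.active:
            counts[a.pos] += 1
        n, q = 3000, 1 / 3
        sigma = (n * q * (1 - q)) ** 0.5
        for pos in p.entry_positions:
            assert abs(counts[pos] - n * q) < 3 * sigma


# ---------------------------------------------------------------- movement

class TestMoveDown:
    def test_agent_settles_on_first_empty_site_below_rod(self, rng):
        p = SimParams(prob_y_minus=1.0, prob_x_plus=0.0, prob_x_minus=0.0)
        w = make_world(active=[(500, 500)])
        sm.move_down_step(w, p, rng)
        assert (500, 499) in w.inactive
        agent = w.inactive[(500, 499)]
        assert not agent.active and agent.threshold == p.threshold0

    def test_deterministic_descent_settles_below_column(self, rng):
        # straight-down mover passes over the existing chain tip one site per
        # step and attaches at the first empty site beneath it
        p = SimParams(prob_y_minus=1.0, prob_x_plus=0.0, prob_x_minus=0.0)
        w = make_world(inactive=[(500, 499), (500, 498)], active=[(500, 500)])
        for _ in range(3):
            sm.move_down_step(w, p, rng)
        assert (500, 497) in w.inactive
        assert not w.active

    def test_never_settles_on_rod_row(self, rng):
        # the rod row is the entry corridor: a lateral move there keeps the
        # agent active
        p = SimParams(prob_y_minus=0.0, prob_x_plus=1.0, prob_x_minus=0.0)
        w = make_world(active=[(500, 500)])
        sm.move_down_step(w, p, rng)
        assert not w.inactive
        assert w.active[0].pos == (501, 500)

    def test_conflicting_settlers_resolve_to_one_inactive(self):
        # two actives target the same empty site: exactly one settles, the
        # other stays active on that site, nobody is lost
        p = SimParams(prob_y_minus=1.0, prob_x_plus=0.0, prob_x_minus=0.0)
        winners = set()
        for seed in range(20):
            rng = np.random.default_rng(seed)
            w = make_world(active=[(499, 499), (499, 499)])
            ids = [a.id for a in w.active]
            sm.move_down_step(w, p, rng)
            assert len(w.inactive) == 1 and len(w.active) == 1
            assert (499, 498) in w.inactive
            assert w.active[0].pos == (499, 498)
            assert w.n_agents() == 2
            winners.add(w.inactive[(499, 498)].id)
            assert set([w.inactive[(499, 498)].id, w.active[0].id]) == set(ids)
        assert winners == set(ids)  # both can win across seeds

    def test_move_onto_inactive_keeps_agent_active(self, rng):
        p = SimParams(prob_y_minus=1.0, prob_x_plus=0.0, prob_x_minus=0.0)
        w = make_world(inactive=[(500, 499)], active=[(500, 500)])
        sm.move_down_step(w, p, rng)
        assert w.active[0].pos == (500, 499)
        assert w.active[0].active


# ---------------------------------------------------------------- weights

class TestWeights:
    def test_three_supporter_sharing_example(self):
        """The worked weight-sharing example: three supporters on one row
        over a 3/2/1 load split yield exactly (2.5, 2.0, 1.5)."""
        k, L, R = (500, 495), (499, 495), (501, 495)
        loads = [(500, 494), (500, 493), (500, 492),   # shared by k, L, R
                 (499, 494), (499, 493),               # shared by k, L
                 (501, 494)]                           # shared by k, R
        w = make_world(inactive=[k, L, R] + loads)
        wa = compute_weights(w)
        get = lambda site: wa.weights[w.inactive[site].id]
        assert get(k) == pytest.approx(2.5)
        assert get(L) == pytest.approx(2.0)
        assert get(R) == pytest.approx(1.5)

    def test_empty_area_weighs_nothing(self):
        w = make_world(inactive=[(500, 495)])
        wa = compute_weights(w)
        assert wa.weights[w.inactive[(500, 495)].id] == 0.0

    def test_single_link_bears_total_set_weight(self):
        # a lone supporter over a chain carries every agent below it
        chain = [(500, 495 - i) for i in range(1, 5)]
        w = make_world(inactive=[(500, 495)] + chain)
        wa = compute_weights(w)
        assert wa.weights[w.inactive[(500, 495)].id] == pytest.approx(4.0)

    def test_active_agents_count_toward_burden(self):
        w = make_world(inactive=[(500, 495)], active=[(500, 494), (500, 494)])
        wa = compute_weights(w)
        assert wa.weights[w.inactive[(500, 495)].id] == pytest.approx(2.0)

    @given(data=st.data())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_bruteforce_and_conserves_mass(self, data):
        """Random 20-agent configurations: fast pass equals the enumeration
        oracle and total weight equals the number of supported agents."""
        sites = st.tuples(st.integers(495, 505), st.integers(480, 499))
        inactive = data.draw(st.sets(sites, min_size=1, max_size=14))
        active = data.draw(st.lists(sites, min_size=0, max_size=6))
        w = make_world(inactive=sorted(inactive), active=active)
        wa = compute_weights(w)
        oracle = compute_weights_bruteforce(w)
        for aid, val in wa.weights.items():
            assert val == pytest.approx(oracle[aid], abs=1e-9)
        assert sum(wa.weights.values()) == pytest.approx(wa.n_supported_agents)


# ------------------------------------------------------- structural removal

class TestRemoveUnsupported:
    def test_rod_supports_agents_directly_beneath(self):
        w = make_world(inactive=[(500, 499), (501, 499), (499, 499)])
        removed = sm.remove_unsupported(w)
        assert removed == []

    def test_isolated_agent_removed(self):
        w = make_world(inactive=[(505, 499)])
        removed = sm.remove_unsupported(w)
        assert len(removed) == 1 and not w.inactive

    def test_horizontal_pair_removed_in_one_pass(self):
        # both fail the support test against the start-of-pass state
        w = make_world(inactive=[(505, 499), (506, 499)])
        removed = sm.remove_unsupported(w)
        assert len(removed) == 2

    def test_supported_agent_survives(self):
        w = make_world(inactive=[(500, 499), (501, 498)])
        removed = sm.remove_unsupported(w)
        assert removed == []

    def test_removals_logged_not_droplets(self):
        w = make_world(inactive=[(505, 499)])
        w.t = 7
        sm.remove_unsupported(w)
        assert w.removed_log and w.removed_log[0][0] == 7
        assert not w.droplet_events


# ---------------------------------------------------------- warning signal

class TestWarningSignal:
    def _world_with_signaller(self, weight, threshold=5.0):
        w = make_world(inactive=[(500, 495), (500, 496)],
                       active=[(500, 494)], threshold=threshold)
        for a in w.inactive.values():
            a.weight = 0.0
        w.inactive[(500, 495)].weight = weight
        return w

    def test_signal_at_threshold_minus_one_forces_climb(self, rng):
        w = self._world_with_signaller(4.0)
        sm.warning_signal_step(w, rng)
        climber = w.active[0]
        assert climber.pos == (500, 495)   # sole occupied up-site
        assert climber.moved_up

    def test_below_signal_boundary_nobody_moves(self, rng):
        w = self._world_with_signaller(3.9)
        sm.warning_signal_step(w, rng)
        assert w.active[0].pos == (500, 494)
        assert not w.active[0].moved_up

    def test_climb_onto_signaller_always_available(self, rng):
        # the straight-up candidate of a direct-below active is the
        # signaller itself, so a climb always succeeds
        w = make_world(inactive=[(505, 491)], active=[(505, 490)])
        w.inactive[(505, 491)].weight = 4.5
        sm.warning_signal_step(w, rng)
        assert w.active[0].pos == (505, 491)
        assert w.active[0].moved_up

    def test_uniform_choice_among_three_occupied_up_sites(self):
        counts = {(-1): 0, 0: 0, 1: 0}
        n = 3000
        rng = np.random.default_rng(7)
        for _ in range(n):
            w = make_world(
                inactive=[(500, 495), (499, 495), (501, 495), (500, 496)],
                active=[(500, 494)])
            w.inactive[(500, 495)].weight = 4.5
            sm.warning_signal_step(w, rng)
            counts[w.active[0].x - 500] += 1
        q = 1 / 3
        sigma = (n * q * (1 - q)) ** 0.5
        for dx in counts:
            assert abs(counts[dx] - n * q) < 3 * sigma


# ----------------------------------------------------- threshold coordination

def _coordination_world(pattern, weight=4.2, threshold=5.0):
    w = make_world(inactive=[(500, 495)], active=[(501, 495)],
                   threshold=threshold)
    k = w.inactive[(500, 495)]
    k.weight = weight
    k.last_pattern = pattern
    w.active[0].moved_up = True
    return w, k


class TestThresholdCoordination:
    def test_unstable_collapses_threshold_to_weight_then_falls(self, rng):
        w, k = _coordination_world(UNSTABLE)
        sm.threshold_coordination_step(w, SimParams())
        assert k.threshold == pytest.approx(4.2)
        # at the same step's fall check the breach fires
        assert k.threshold <= k.weight

    def test_stable_raises_threshold_by_one(self):
        w, k = _coordination_world(STABLE, threshold=5.0)
        sm.threshold_coordination_step(w, SimParams())
        assert k.threshold == pytest.approx(6.0)

    def test_undefined_pattern_skipped(self):
        w, k = _coordination_world(UNDEFINED)
        sm.threshold_coordination_step(w, SimParams())
        assert k.threshold == pytest.approx(5.0)

    def test_no_adjacent_climber_no_change(self):
        w, k = _coordination_world(UNSTABLE)
        w.active[0].moved_up = False
        sm.threshold_coordination_step(w, SimParams())
        assert k.threshold == pytest.approx(5.0)

    @pytest.mark.parametrize("variant,pattern,expected", [
        ("TM", UNSTABLE, 4.2), ("TM", STABLE, 6.0),
        ("TM_STABLE", UNSTABLE, 5.0), ("TM_STABLE", STABLE, 6.0),
        ("TM_UNSTABLE", UNSTABLE, 4.2), ("TM_UNSTABLE", STABLE, 5.0),
        ("NTM", UNSTABLE, 5.0), ("NTM", STABLE, 5.0),
    ])
    def test_variant_gating(self, variant, pattern, expected):
        w, k = _coordination_world(pattern)
        sm.threshold_coordination_step(w, SimParams(variant=variant))
        assert k.threshold == pytest.approx(expected)


# ------------------------------------------------------------ local pattern

class TestLocalPattern:
    def test_lateral_pair_is_stable(self):
        w = make_world(inactive=[(500, 497), (501, 497)])
        sm.local_pattern_step(w)
        assert all(a.last_pattern == STABLE for a in w.inactive.values())

    def test_vertical_chain_is_unstable(self):
        w = make_world(inactive=[(500, 499 - i) for i in range(4)])
        sm.local_pattern_step(w)
        assert all(a.last_pattern == UNSTABLE for a in w.inactive.values())

    def test_diagonal_neighbour_does_not_count(self):
        w = make_world(inactive=[(500, 497), (501, 496)])
        sm.local_pattern_step(w)
        assert all(a.last_pattern == UNSTABLE for a in w.inactive.values())

    def test_rod_is_not_a_lateral_neighbour(self):
        # an agent on the rod row right beside the rod still reads unstable
        w = make_world(inactive=[(499, 500)])
        sm.local_pattern_step(w)
        assert w.inactive[(499, 500)].last_pattern == UNSTABLE


# ------------------------------------------------------------------- falls

class TestFall:
    def _breach_world(self, threshold, weight, n_loads=6):
        loads = [(500, 494), (500, 493), (499, 494), (501, 494),
                 (499, 493), (501, 493)][:n_loads]
        w = make_world(inactive=[(500, 495)] + loads, threshold=threshold)
        compute_weights(w)
        k = w.inactive[(500, 495)]
        k.weight = weight
        return w, k

    def test_breach_removes_supported_set_trigger_survives(self, rng):
        w, k = self._breach_world(5.0, 5.0)
        before = w.n_agents()
        events = sm.fall_step(w, rng)
        assert len(events) == 1
        assert events[0].size >= 6
        assert events[0].trigger_id == k.id
        assert (500, 495) in w.inactive           # trigger survives
        assert k.weight == 0.0
        assert w.n_agents() == before - events[0].size
        assert w.n_removed_droplet == events[0].size

    def test_strict_inequality_no_fall(self, rng):
        w, _ = self._breach_world(5.0, 4.99)
        assert sm.fall_step(w, rng) == []

    def test_actives_in_area_fall_with_droplet(self, rng):
        w, k = self._breach_world(5.0, 6.0)
        w.new_agent(500, 494)   # rider on a falling site
        compute_weights(w)
        k.weight = 7.0
        events = sm.fall_step(w, rng)
        assert not w.active
        assert events[0].size == 7

    def test_empty_area_breach_emits_no_event(self, rng):
        w = make_world(inactive=[(500, 495)])
        k = w.inactive[(500, 495)]
        k.threshold = 0.0
        k.weight = 0.0
        assert sm.fall_step(w, rng) == []
        assert not w.droplet_events

    @pytest.mark.parametrize("seed", range(5))
    def test_emptied_survivors_weigh_nothing_after_pass(self, seed):
        # survivors whose supporting areas were emptied by the pass carry
        # no weight on recomputation, and mass stays conserved
        rng = np.random.default_rng(seed)
        rnd = np.random.default_rng(seed + 100)
        sites = {(int(rnd.integers(497, 504)), int(rnd.integers(485, 499)))
                 for _ in range(25)}
        w = make_world(inactive=sorted(sites), threshold=2.0)
        compute_weights(w)
        before = w.n_agents()
        events = sm.fall_step(w, rng)
        assert w.n_agents() + w.n_removed_droplet == before
        wa = compute_weights(w)
        occupied = set(w.inactive)
        for (x, y), agent in w.inactive.items():
            area_occupied = any(s for s in occupied
                                if abs(s[0] - x) <= 1 and s[1] < y)
            if not area_occupied:
                assert wa.weights[agent.id] == 0.0
        if events:
            assert events[0].size >= 1

    def test_simultaneous_breaches_merge_into_one_event(self, rng):
        w = make_world(inactive=[(500, 495), (510, 495),
                                 (500, 494), (510, 494)], threshold=1.0)
        compute_weights(w)
        events = sm.fall_step(w, rng)
        assert len(events) == 1
        assert events[0].size == 2
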