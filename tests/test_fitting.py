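"""Alignment scoring, per-node constraint satisfaction, and model search."""

import itertools

import numpy as np
import pytest

from adherelogic.fitting import (
    alignment_error,
    fit_network,
    fit_node_csp,
    filled_state,
    node_transition_coverage,
    per_trajectory_error,
)
from adherelogic.network import (
    Domains,
    Edge,
    LogicNetwork,
    NetworkValidationError,
    NodeSpec,
    ParameterSet,
    default_parameters,
)
from adherelogic.synthetic import (
    Assessment,
    Trajectory,
    generate_ground_truth,
    random_network,
    simulate_cohort,
)

from conftest import make_params


def traj(levels_by_time, adherent=None, pid="p", profile=None):
    """Trajectory literal: list of level tuples (None = missing)."""
    assessments = tuple(
        Assessment(t, tuple(levels), True if adherent is None else adherent[t])
        for t, levels in enumerate(levels_by_time)
    )
    return Trajectory(pid, assessments, profile or {})


# -- independent single-node oracle used to cross-check the CSP ------------


def brute_force_node_solutions(net, target, trajectories, domains):
    """Filter the full local domain by literally replaying each observed
    transition with a from-scratch prediction rule."""
    in_idx = net.in_edges[target]
    tgt = net.index(target)
    per_edge = []
    for i in in_idx:
        src = net.nodes[net.edge_source_idx[i]]
        per_edge.append(
            [(t, w) for t in domains.theta_domain(src) for w in domains.weight_domain()]
        )
    transitions = []
    for tr in trajectories:
        for j in range(len(tr.assessments) - 1):
            obs = tr.assessments[j + 1].levels[tgt]
            if obs is None:
                continue
            state = filled_state(net, tr, j)
            transitions.append((state, int(obs)))
    keep = []
    for combo in itertools.product(*per_edge):
        ok = True
        for state, expected in transitions:
            a = b = 0
            for i, (theta, w) in zip(in_idx, combo):
                src_level = state[net.edge_source_idx[i]]
                if src_level >= theta:
                    if net.edges[i].mode == "activate":
                        a += w
                    else:
                        b += w
            cur = state[tgt]
            if a > b:
                pred = min(cur + 1, net.node(target).max_level)
            elif b > a:
                pred = max(cur - 1, 0)
            else:
                pred = cur
            if pred != expected:
                ok = False
                break
        if ok:
            keep.append(tuple(combo))
    return keep


class TestAlignmentError:
    def test_self_consistent_cohort_scores_zero(self, fixture_net):
        params = generate_ground_truth(fixture_net, 3)
        cohort = simulate_cohort(fixture_net, params, n_participants=10, seed=4)
        err = alignment_error(fixture_net, params, cohort, K=1)
        assert err.total == 0
        assert node_transition_coverage(fixture_net, params, cohort, K=1) == 1.0

    def test_single_discordant_node_accounts_for_all_error(self, two_node_net):
        net, params = two_node_net
        # a=0 never perceived: b should hold at 1; observed 2 once
        t = traj([(0, 1), (0, 2), (0, 2)])
        err = alignment_error(net, params, [t], K=1)
        assert err.total == 1
        assert err.by_node == {"a": 0, "b": 1}
        assert err.by_node_percent["b"] == 100.0
        assert {k: v for k, v in err.by_observation.items() if v} == {("p", 1): 1}

    def test_error_equals_hand_computed_sum_on_two_node_toy(self, two_node_net):
        net, params = two_node_net
        # hand enumeration with rule "b follows a when a >= 1, a holds":
        # t0 (2,0) -> predicted t1 (2,1); observed (1,2): |2-1| + |1-2| = 2
        # t1 (1,2) -> predicted t2 (1,2); observed (1,0): |2-0| = 2
        t = traj([(2, 0), (1, 2), (1, 0)])
        err = alignment_error(net, params, [t], K=1)
        assert err.total == 4
        assert err.by_observation == {("p", 1): 2, ("p", 2): 2}

    def test_missing_values_are_excluded_from_scoring(self, two_node_net):
        net, params = two_node_net
        t = traj([(0, 1), (0, None), (0, 1)])
        err = alignment_error(net, params, [t], K=1)
        assert err.n_scored == 3  # a at t1, and both nodes at t2

    def test_decompositions_sum_to_total_on_fuzzed_inputs(self, rng):
        for _ in range(25):
            net = random_network(
                int(rng.integers(2, 7)), int(rng.integers(1, 10)), seed=rng,
                n_inputs=int(rng.integers(0, 2)),
            )
            params = generate_ground_truth(net, seed=rng)
            cohort = simulate_cohort(
                net, params,
                n_participants=3, n_assessments=(3, 5),
                noise_rate=float(rng.uniform(0, 0.5)),
                missing_rate=float(rng.uniform(0, 0.5)),
                seed=rng,
            )
            err = alignment_error(net, params, cohort, K=int(rng.integers(1, 3)))
            assert sum(err.by_node.values()) == err.total
            assert sum(err.by_observation.values()) == err.total

    def test_per_trajectory_balance_covers_every_participant(self, fixture_net):
        params = generate_ground_truth(fixture_net, 3)
        cohort = simulate_cohort(fixture_net, params, n_participants=5, seed=4)
        balance = per_trajectory_error(fixture_net, params, cohort, K=1)
        assert set(balance) == {t.participant_id for t in cohort}
        assert all(e == 0 for e, _n in balance.values())


class TestNodeCSP:
    def test_threshold_two_forced_by_observations(self, two_node_net):
        net, _ = two_node_net
        # a=1 leaves b unchanged; a=2 drives b up: only theta=2 explains both
        t = traj([(1, 1), (2, 1), (2, 2)])
        sols = fit_node_csp(net, "b", [t])
        assert sols and all(theta == 2 for ((theta, _w),) in sols)

    def test_no_scored_transitions_returns_full_domain(self, two_node_net):
        net, _ = two_node_net
        t = traj([(1, None), (1, None), (1, None)])
        sols = fit_node_csp(net, "b", [t])
        assert len(sols) == 4  # theta in {1,2} x w in {1,2}

    def test_contradictory_observations_yield_empty_set(self, two_node_net):
        net, _ = two_node_net
        # identical context (a=2, b=1) followed by both 2 and 0
        t = traj([(2, 1), (2, 2), (2, 1), (2, 0)])
        assert fit_node_csp(net, "b", [t]) == []

    def test_requires_unit_horizon_and_dynamic_target(self, two_node_net):
        net, _ = two_node_net
        t = traj([(1, 1), (1, 1), (1, 1)])
        with pytest.raises(NetworkValidationError, match="K=1"):
            fit_node_csp(net, "b", [t], K=2)

    def test_matches_brute_force_on_random_instances(self, rng):
        domains = Domains(theta=(1, 2), weight=(1, 2))
        for _ in range(40):
            net = random_network(
                int(rng.integers(2, 6)), int(rng.integers(1, 5)), seed=rng
            )
            params = generate_ground_truth(net, seed=rng, domains=domains)
            cohort = simulate_cohort(
                net, params, n_participants=2, n_assessments=3,
                noise_rate=0.3, seed=rng,
            )
            for node in net.dynamic_nodes:
                if len(net.in_edges[node.name]) > 4:
                    continue
                assert fit_node_csp(net, node.name, cohort, domains=domains) == (
                    brute_force_node_solutions(net, node.name, cohort, domains)
                )


class TestFitNetwork:
    def _toy(self):
        net = LogicNetwork(
            [NodeSpec("a"), NodeSpec("b"), NodeSpec("c")],
            [Edge("a", "b", "activate"), Edge("b", "c", "activate")],
            adherence_node="c",
        )
        return net

    def test_recovers_the_generating_model(self, rng):
        net = random_network(5, 8, seed=1)
        truth = generate_ground_truth(net, seed=2)
        cohort = simulate_cohort(net, truth, n_participants=40, seed=3)
        cand = fit_network(net, cohort, coverage_min=1.0, max_models=500)
        assert cand.models
        assert all(c == 1.0 for c in cand.coverages)
        assert cand.admits(net, truth)
        # enumeration is complete below the cap: truth is literally present
        if not cand.truncated:
            assert truth in cand.models

    def test_cap_semantics_on_underdetermined_toy(self):
        net = self._toy()
        # no observations at all: every assignment fits, cap limits output
        t = traj([(None,) * 3, (None,) * 3, (None,) * 3])
        cand = fit_network(net, [t], coverage_min=1.0, max_models=10)
        assert cand.n_models == 10 and cand.truncated
        assert all(c == 1.0 for c in cand.coverages)
        assert cand.exact_space_size == 16  # 4 assignments per edge

    def test_unachievable_coverage_reports_best_achievable(self, two_node_net):
        net, _ = two_node_net
        t = traj([(2, 1), (2, 2), (2, 1), (2, 0)])  # contradictory for b
        cand = fit_network(net, [t], coverage_min=1.0, max_models=10)
        assert cand.models == []
        assert 0 < cand.best_coverage < 1.0

    def test_soft_threshold_admits_imperfect_models(self, two_node_net):
        net, _ = two_node_net
        t = traj([(2, 1), (2, 2), (2, 1), (2, 0)])
        cand = fit_network(net, [t], coverage_min=0.5, max_models=50)
        assert cand.models
        assert all(c >= 0.5 for c in cand.coverages)
        # best-first enumeration: the first model attains best coverage
        assert cand.coverages[0] == pytest.approx(cand.best_coverage)

    def test_candidate_space_shrinks_as_transitions_accumulate(self):
        net = random_network(5, 8, seed=11)
        truth = generate_ground_truth(net, seed=12)
        cohort = simulate_cohort(net, truth, n_participants=30, seed=13)
        sizes = []
        for n in (2, 5, 10, 30):
            cand = fit_network(net, cohort[:n], coverage_min=1.0, max_models=1)
            sizes.append(cand.exact_space_size)
        assert sizes == sorted(sizes, reverse=True)

    def test_extra_noise_on_one_node_shows_up_in_the_error_report(self):
        net = random_network(6, 10, seed=21, with_adherence=True)
        truth = generate_ground_truth(net, seed=22)
        clean = simulate_cohort(net, truth, n_participants=30, n_assessments=5, seed=23)
        # corrupt a single dynamic node's observations heavily
        noisy_node = net.dynamic_nodes[-1].name
        idx = net.index(noisy_node)
        rng = np.random.default_rng(24)
        corrupted = []
        for t in clean:
            assessments = []
            for a in t.assessments:
                levels = list(a.levels)
                if levels[idx] is not None and rng.random() < 0.8:
                    levels[idx] = int(
                        (levels[idx] + rng.integers(1, net.node(noisy_node).n_levels))
                        % net.node(noisy_node).n_levels
                    )
                adherent = a.adherent
                if idx == net.adherence_index:
                    adherent = levels[idx] == net.node(noisy_node).max_level
                assessments.append(Assessment(a.timepoint, tuple(levels), adherent))
            corrupted.append(Trajectory(t.participant_id, tuple(assessments), t.profile))
        err = alignment_error(net, truth, corrupted, K=1)
        worst = max(err.by_node, key=err.by_node.get)
        assert worst == noisy_node

    def test_noise_does_not_raise_coverage(self):
        net = random_network(5, 8, seed=31)
        truth = generate_ground_truth(net, seed=32)
        clean_cov, noisy_cov = [], []
        for seed in range(5):
            clean = simulate_cohort(
                net, truth, n_participants=20, seed=100 + seed, noise_rate=0.0
            )
            noisy = simulate_cohort(
                net, truth, n_participants=20, seed=100 + seed, noise_rate=0.3
            )
            clean_cov.append(node_transition_coverage(net, truth, clean))
            noisy_cov.append(node_transition_coverage(net, truth, noisy))
        assert np.mean(noisy_cov) <= np.mean(clean_cov)
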