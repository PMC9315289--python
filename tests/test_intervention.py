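"""Clamp interventions, minimal intervention sets, robustness, consensus."""

import itertools

import numpy as np
import pytest

from adherelogic.dynamics import (
    enumerate_attractors_exact,
    simulate,
    step_synchronous,
)
from adherelogic.intervention import (
    InterventionAction,
    apply_intervention,
    consensus_interventions,
    find_mis,
    score_robustness,
)
from adherelogic.network import (
    Edge,
    LogicNetwork,
    NetworkValidationError,
    NodeSpec,
    default_parameters,
)
from adherelogic.synthetic import generate_ground_truth, random_network

from conftest import make_params


def nonadherent_fixed_points(net, params):
    return [
        a
        for a in enumerate_attractors_exact(net, params)
        if not a.adherent and a.period == 1
    ]


def attractor_at(net, params, state):
    return next(
        a for a in enumerate_attractors_exact(net, params) if a.states == (state,)
    )


def decay_net():
    """Chain with self-inhibition: mediator and adherence decay without
    upstream support, so a released clamp can wear off.

    Structure: source self-activates; source -> mediator (activate);
    mediator self-inhibits; mediator -> adherence (activate, weight 2);
    adherence self-inhibits.
    """
    net = LogicNetwork(
        [
            NodeSpec("source", "dynamic", 3, targetable=True),
            NodeSpec("mediator", "dynamic", 3, targetable=True),
            NodeSpec("adherence", "dynamic", 3),
        ],
        [
            Edge("source", "source", "activate"),
            Edge("source", "mediator", "activate"),
            Edge("mediator", "mediator", "inhibit"),
            Edge("mediator", "adherence", "activate"),
            Edge("adherence", "adherence", "inhibit"),
        ],
        adherence_node="adherence",
    )
    params = make_params(
        net, {("source", "mediator"): (1, 2), ("mediator", "adherence"): (1, 2)}
    )
    return net, params


# -- independent MIS oracle: replays clamp/hold/release from scratch -------


def oracle_success(net, params, state, actions, hold_steps=5, max_steps=50):
    current = list(state)

    def clamp():
        for a in actions:
            i = net.index(a.node)
            current[i] = net.nodes[i].max_level if a.direction == "up" else 0

    clamp()
    for _ in range(hold_steps):
        current[:] = step_synchronous(net, params, tuple(current))
        clamp()
    res = simulate(net, params, tuple(current), max_steps=max_steps)
    return bool(res.converged and res.attractor and res.attractor.adherent)


def oracle_mis(net, params, state, max_size=2, hold_steps=5, max_steps=50):
    universe = [
        InterventionAction(n.name, d)
        for n in net.targetable_nodes
        for d in ("up", "down")
    ]
    successes = set()
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(universe, size):
            if len({a.node for a in combo}) != size:
                continue
            if oracle_success(net, params, state, combo, hold_steps, max_steps):
                successes.add(frozenset(combo))
    return {s for s in successes if not any(o < s for o in successes)}


class TestApplyIntervention:
    def test_empty_action_set_cannot_rescue_a_fixed_point(self, self_activator):
        net, params = self_activator
        out = apply_intervention(net, params, (0,), [])
        assert not out.success
        assert out.final_attractor.states == ((0,),)

    def test_chain_rescue_matches_hand_trace(self, chain3):
        net, params = chain3
        out = apply_intervention(
            net, params, (0, 0, 0), [InterventionAction("source", "up")]
        )
        assert out.success
        # clamp source=2, then (2,1,0) -> (2,2,1) -> (2,2,2)
        assert out.trajectory[:4] == ((2, 0, 0), (2, 1, 0), (2, 2, 1), (2, 2, 2))
        assert out.promptness == 3
        assert out.final_attractor.states == ((2, 2, 2),)

    def test_silent_nodes_hold_so_a_released_clamp_persists(self, chain3):
        net, params = chain3
        # with no decay pressure, the mediator keeps its clamped level
        # after release ("no perceived input" means hold, not relax)
        out = apply_intervention(
            net, params, (0, 0, 0), [InterventionAction("mediator", "up")]
        )
        assert out.success
        assert out.final_attractor.states == ((0, 2, 2),)

    def test_downstream_clamp_decays_after_release(self):
        net, params = decay_net()
        # self-inhibition erodes the mediator once the clamp is lifted,
        # and adherence follows it back down
        out = apply_intervention(
            net, params, (0, 0, 0), [InterventionAction("mediator", "up")]
        )
        assert not out.success
        assert out.final_attractor.states == ((0, 0, 0),)

    def test_success_is_insensitive_to_the_settle_budget(self, chain3):
        net, params = chain3
        for budget in (10, 50, 200):
            out = apply_intervention(
                net, params, (0, 0, 0),
                [InterventionAction("source", "up")], max_steps=budget,
            )
            assert out.success

    def test_sustained_mode_succeeds_where_release_fails(self):
        net, params = decay_net()
        actions = [InterventionAction("mediator", "up")]
        assert not apply_intervention(net, params, (0, 0, 0), actions).success
        assert apply_intervention(
            net, params, (0, 0, 0), actions, sustained=True
        ).success

    def test_rejects_untargetable_node_and_duplicate_clamp(self, chain3):
        net, params = chain3
        with pytest.raises(NetworkValidationError, match="targetable"):
            apply_intervention(
                net, params, (0, 0, 0), [InterventionAction("adherence", "up")]
            )
        with pytest.raises(NetworkValidationError, match="at most once"):
            apply_intervention(
                net, params, (0, 0, 0),
                [InterventionAction("source", "up"), InterventionAction("source", "down")],
            )


class TestFindMIS:
    def test_adherent_source_needs_no_action(self, chain3):
        net, params = chain3
        att = next(
            a for a in enumerate_attractors_exact(net, params) if a.adherent
        )
        results = find_mis(net, params, att)
        assert len(results) == 1
        assert results[0].already_adherent and results[0].actions == ()

    def test_chain_singleton_rescues_ranked_by_promptness(self, chain3):
        net, params = chain3
        att = attractor_at(net, params, (0, 0, 0))
        results = find_mis(net, params, att)
        # both clamps work; the mediator clamp reaches adherence sooner
        assert [r.actions for r in results] == [
            (InterventionAction("mediator", "up"),),
            (InterventionAction("source", "up"),),
        ]
        assert [r.promptness for r in results] == [2, 3]

    def test_decay_net_has_a_unique_singleton_mis(self):
        net, params = decay_net()
        (att,) = nonadherent_fixed_points(net, params)
        results = find_mis(net, params, att)
        assert [r.actions for r in results] == [
            (InterventionAction("source", "up"),)
        ]

    def test_results_are_minimal_by_construction(self, chain3):
        net, params = chain3
        att = attractor_at(net, params, (0, 0, 0))
        results = find_mis(net, params, att, max_size=2)
        sets = [frozenset(r.actions) for r in results]
        for s in sets:
            assert not any(o < s for o in sets)
        # in particular no pair containing the successful singleton
        assert all(r.size == 1 for r in results)

    def test_matches_independent_exhaustive_search(self, rng):
        checked = 0
        while checked < 12:
            net = random_network(
                int(rng.integers(3, 6)), int(rng.integers(3, 9)), seed=rng,
                n_targetable=int(rng.integers(1, 4)), with_adherence=True,
            )
            params = generate_ground_truth(net, seed=rng)
            for att in nonadherent_fixed_points(net, params)[:2]:
                expected = oracle_mis(net, params, att.states[0])
                got = {frozenset(r.actions) for r in find_mis(net, params, att)}
                assert got == expected
                checked += 1

    def test_ranked_by_size_then_promptness(self, rng):
        for _ in range(10):
            net = random_network(4, 7, seed=rng, n_targetable=3, with_adherence=True)
            params = generate_ground_truth(net, seed=rng)
            for att in nonadherent_fixed_points(net, params)[:1]:
                results = find_mis(net, params, att)
                keys = [(r.size, r.promptness) for r in results]
                assert keys == sorted(keys, key=lambda k: (k[0], k[1] if k[1] is not None else 10**9))


class TestRobustness:
    def _flat_net(self):
        # self-activation perceived only at the top level: every state is
        # a fixed point, so any noise kick away from the top sticks
        net = LogicNetwork(
            [NodeSpec("a", "dynamic", 3, targetable=True)],
            [Edge("a", "a", "activate")],
            adherence_node="a",
        )
        return net, make_params(net, {("a", "a"): (2, 1)})

    def test_noise_free_robustness_is_one(self, chain3):
        net, params = chain3
        att = attractor_at(net, params, (0, 0, 0))
        result = find_mis(net, params, att)[0]
        scored = score_robustness(net, params, result, noise_prob=0.0, n_replicates=5)
        assert scored.robustness == 1.0
        assert scored.actions == result.actions  # annotation, not mutation

    def test_seeded_scores_are_reproducible(self, chain3):
        net, params = chain3
        att = attractor_at(net, params, (0, 0, 0))
        result = find_mis(net, params, att)[0]
        a = score_robustness(net, params, result, noise_prob=0.3, n_replicates=50, seed=7)
        b = score_robustness(net, params, result, noise_prob=0.3, n_replicates=50, seed=7)
        assert a.robustness == b.robustness

    def test_robustness_decreases_with_noise_level(self):
        net, params = self._flat_net()
        att = next(
            a for a in enumerate_attractors_exact(net, params)
            if a.states == ((0,),)
        )
        result = find_mis(net, params, att)[0]
        scores = [
            score_robustness(
                net, params, result, noise_prob=p, n_replicates=200, seed=11
            ).robustness
            for p in (0.0, 0.05, 0.2)
        ]
        assert scores[0] == 1.0
        assert scores[0] > scores[1] > scores[2]


class TestConsensus:
    def test_single_model_table_agrees_with_direct_mis(self, chain3):
        net, params = chain3
        atts = enumerate_attractors_exact(net, params)
        res = consensus_interventions(
            net, [params], attractors_by_model=[atts]
        )
        nonadh = [a for a in atts if not a.adherent]
        assert res.n_nonadherent_states == len(nonadh)
        expected = {
            " + ".join(x.label() for x in r.actions)
            for a in nonadh
            for r in find_mis(net, params, a)
            if not r.already_adherent
        }
        assert set(res.table["strategy"]) == expected
        assert res.unanimous_strategies == sorted(expected)
        assert all(res.table["support_fraction"] == 1.0)

    def test_identical_models_are_unanimous(self, chain3):
        net, params = chain3
        atts = enumerate_attractors_exact(net, params)
        res = consensus_interventions(
            net, [params, params], attractors_by_model=[atts, atts]
        )
        assert all(res.table["n_supporting_models"] == 2)
        assert all(res.table["unanimous"])

    def test_disagreeing_models_split_the_support_column(self):
        # same structure, different fitted parameters: under model B the
        # source only pushes the mediator to a level the adherence node
        # cannot perceive, so the single source clamp stops working and a
        # two-action strategy is needed instead
        net, model_a = decay_net()
        model_b = make_params(
            net,
            {("source", "mediator"): (1, 1), ("mediator", "adherence"): (2, 2)},
        )
        atts = [
            [attractor_at(net, m, (0, 0, 0))] for m in (model_a, model_b)
        ]
        res = consensus_interventions(net, [model_a, model_b], attractors_by_model=atts)
        support = dict(zip(res.table["strategy"], res.table["n_supporting_models"]))
        assert support["up:source"] == 1
        assert support["up:mediator + up:source"] == 1
        assert res.unanimous_strategies == []

    def test_stratum_columns_cover_every_input_level(self):
        net = LogicNetwork(
            [
                NodeSpec("context", "input", 3),
                NodeSpec("driver", "dynamic", 3, targetable=True),
                NodeSpec("adherence", "dynamic", 3),
            ],
            [
                Edge("context", "driver", "activate"),
                Edge("driver", "driver", "activate"),
                Edge("driver", "adherence", "activate"),
            ],
            adherence_node="adherence",
        )
        params = default_parameters(net)
        atts = enumerate_attractors_exact(net, params)
        res = consensus_interventions(net, [params], attractors_by_model=[atts])
        for level in range(3):
            assert f"context={level}" in res.table.columns
        strata = res.table[[f"context={l}" for l in range(3)]].to_numpy()
        totals = res.table["total_rescued"].to_numpy()
        # each rescued state lives in exactly one stratum of a single input
        assert (strata.sum(axis=1) == totals).all()

    def test_seeded_sampling_path_is_deterministic(self, chain3):
        net, params = chain3
        r1 = consensus_interventions(net, [params], seed=3, n_inits=50)
        r2 = consensus_interventions(net, [params], seed=3, n_inits=50)
        assert r1.table.equals(r2.table)
        assert r1.per_model_attractors == r2.per_model_attractors

    def test_requires_at_least_one_model(self, chain3):
        net, _ = chain3
        with pytest.raises(NetworkValidationError):
            consensus_interventions(net, [])
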