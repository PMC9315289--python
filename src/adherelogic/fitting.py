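"""Fitting decisional kinetic parameters to observed trajectories.

Candidate parameter sets are scored by how well their forward
predictions reproduce the observed discretized states.  For each pair
of consecutive assessments the model starts from the observed state
(missing values imputed at the nominal level, inputs taken from the
demographic profile), advances ``K`` synchronous steps, and is compared
with the later assessment over the observed dynamic nodes.  The total
Manhattan distance between predicted and observed states is the
alignment error; it decomposes exactly by node and by observation.
Coverage is the fraction of scored node-observations predicted at the
exact observed level.

At the default horizon K = 1 a node's next level depends only on the
parameters of its own in-edges, so the search for all parameter sets
consistent with the data decomposes into independent per-node
constraint-satisfaction problems over tiny finite domains.  The
network-level candidate set is the (lazily enumerated) composition of
the per-node solutions; a soft coverage threshold admits per-node
assignments up to a total mismatch budget.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import pandas as pd

from .dynamics import step_synchronous
from .network import Domains, Edge, LogicNetwork, NetworkValidationError, ParameterSet
from .synthetic import Trajectory

__all__ = [
    "AlignmentError",
    "CandidateModels",
    "filled_state",
    "alignment_error",
    "node_transition_coverage",
    "per_trajectory_error",
    "fit_node_csp",
    "fit_network",
    "error_report_frame",
]

NodeAssignment = tuple[tuple[int, int], ...]  # (theta, w) per in-edge, edge order


def filled_state(net: LogicNetwork, traj: Trajectory, assessment_index: int) -> tuple[int, ...]:
    """Complete an observed partial state: missing input levels come from
    the demographic profile, missing dynamic levels are imputed at the
    nominal (middle) level."""
    a = traj.assessments[assessment_index]
    out: list[int] = []
    for i, spec in enumerate(net.nodes):
        level = a.levels[i]
        if level is None:
            if spec.kind == "input" and spec.name in traj.profile:
                level = traj.profile[spec.name]
            else:
                level = spec.nominal_level
        out.append(int(level))
    return tuple(out)


def _predict_pairs(
    net: LogicNetwork, params: ParameterSet, traj: Trajectory, K: int
) -> Iterator[tuple[int, tuple[int, ...], "object"]]:
    """Yield (later assessment index, predicted state, later assessment)."""
    for j in range(len(traj.assessments) - 1):
        state = filled_state(net, traj, j)
        for _ in range(K):
            state = step_synchronous(net, params, state)
        yield j + 1, state, traj.assessments[j + 1]


@dataclass(frozen=True)
class AlignmentError:
    """Manhattan distance between predicted and observed states, with
    exact decompositions by node and by (participant, timepoint)."""

    total: int
    by_node: dict[str, int]
    by_observation: dict[tuple[str, int], int]
    n_scored: int

    @property
    def by_node_percent(self) -> dict[str, float]:
        """Each node's share of the total error, in percent (zero map when
        the total error is zero)."""
        if self.total == 0:
            return {k: 0.0 for k in self.by_node}
        return {k: 100.0 * v / self.total for k, v in self.by_node.items()}


def _scored_items(
    net: LogicNetwork, params: ParameterSet, trajectories: Sequence[Trajectory], K: int
) -> Iterator[tuple[str, int, str, int, int]]:
    """Yield (participant, timepoint, node, predicted, observed) for every
    scored node-observation: dynamic nodes observed at the later
    assessment of each consecutive pair."""
    if K < 1:
        raise NetworkValidationError("K must be >= 1")
    params.validate_against(net)
    for traj in trajectories:
        for _j, predicted, later in _predict_pairs(net, params, traj, K):
            for i, spec in enumerate(net.nodes):
                if spec.kind != "dynamic":
                    continue
                obs = later.levels[i]
                if obs is None:
                    continue
                yield traj.participant_id, later.timepoint, spec.name, predicted[i], int(obs)


def alignment_error(
    net: LogicNetwork,
    params: ParameterSet,
    trajectories: Sequence[Trajectory],
    K: int = 1,
) -> AlignmentError:
    """Score a decisional logic against observed trajectories.

    Missing observations are excluded from scoring; the decompositions
    by node and by observation each sum exactly to the total.
    """
    by_node: dict[str, int] = {n.name: 0 for n in net.dynamic_nodes}
    by_obs: dict[tuple[str, int], int] = {}
    total = 0
    n_scored = 0
    for pid, t, node, pred, obs in _scored_items(net, params, trajectories, K):
        err = abs(pred - obs)
        total += err
        n_scored += 1
        by_node[node] += err
        by_obs[(pid, t)] = by_obs.get((pid, t), 0) + err
    return AlignmentError(total, by_node, by_obs, n_scored)


def node_transition_coverage(
    net: LogicNetwork,
    params: ParameterSet,
    trajectories: Sequence[Trajectory],
    K: int = 1,
) -> float:
    """Fraction of scored node-observations whose predicted level equals
    the observed level (1.0 when nothing is scored)."""
    matches = 0
    n_scored = 0
    for _pid, _t, _node, pred, obs in _scored_items(net, params, trajectories, K):
        n_scored += 1
        matches += pred == obs
    return matches / n_scored if n_scored else 1.0


def per_trajectory_error(
    net: LogicNetwork,
    params: ParameterSet,
    trajectories: Sequence[Trajectory],
    K: int = 1,
) -> dict[str, tuple[int, int]]:
    """Per-participant (error, n_scored), to check that no trajectory is
    represented more poorly than the others."""
    out: dict[str, tuple[int, int]] = {t.participant_id: (0, 0) for t in trajectories}
    for pid, _t, _node, pred, obs in _scored_items(net, params, trajectories, K):
        e, n = out[pid]
        out[pid] = (e + abs(pred - obs), n + 1)
    return out


# ---------------------------------------------------------------------------
# Per-node constraint satisfaction (K = 1)
# ---------------------------------------------------------------------------


def _node_constraints(
    net: LogicNetwork,
    target: str,
    trajectories: Sequence[Trajectory],
) -> tuple[tuple[int, ...], Counter]:
    """Observed one-step transitions of ``target``.

    Returns the target's in-edge indices and a Counter over constraints
    ``((source levels...), current level, expected next level)`` with
    their observation multiplicities.  Source levels and the current
    level come from the (imputed) earlier state; constraints exist only
    where the target is observed at the later assessment.
    """
    in_idx = net.in_edges[target]
    tgt = net.index(target)
    constraints: Counter = Counter()
    for traj in trajectories:
        for j in range(len(traj.assessments) - 1):
            later = traj.assessments[j + 1]
            obs = later.levels[tgt]
            if obs is None:
                continue
            state = filled_state(net, traj, j)
            srcs = tuple(state[net.edge_source_idx[i]] for i in in_idx)
            constraints[(srcs, state[tgt], int(obs))] += 1
    return in_idx, constraints


def _predict_node(
    net: LogicNetwork,
    target: str,
    in_idx: tuple[int, ...],
    assignment: NodeAssignment,
    source_levels: tuple[int, ...],
    current: int,
) -> int:
    """One-step update of a single node under a local (theta, w) assignment."""
    balance = 0
    for edge_i, (theta, w), lvl in zip(in_idx, assignment, source_levels):
        if lvl >= theta:
            balance += int(net.edge_sign[edge_i]) * w
    nxt = current + (balance > 0) - (balance < 0)
    return min(max(nxt, 0), net.node(target).max_level)


def _per_edge_domains(
    net: LogicNetwork, in_idx: tuple[int, ...], domains: Domains
) -> list[list[tuple[int, int]]]:
    """(theta, w) pair domain per in-edge, ordered theta-major then w."""
    per_edge = []
    for i in in_idx:
        src = net.nodes[net.edge_source_idx[i]]
        per_edge.append(
            [(t, w) for t in domains.theta_domain(src) for w in domains.weight_domain()]
        )
    return per_edge


def _assignment_at(per_edge: list[list[tuple[int, int]]], index: int) -> NodeAssignment:
    """The index-th assignment in lexicographic (itertools.product) order."""
    out = []
    for dom in reversed(per_edge):
        out.append(dom[index % len(dom)])
        index //= len(dom)
    return tuple(reversed(out))


@dataclass
class _NodeSearch:
    """Per-node CSP search space with vectorized mismatch counts."""

    in_idx: tuple[int, ...]
    per_edge: list[list[tuple[int, int]]]
    mismatch: "object"  # np.ndarray over all assignments, lexicographic order
    n_scored: int

    @property
    def n_assignments(self) -> int:
        return len(self.mismatch)

    def assignment(self, index: int) -> NodeAssignment:
        return _assignment_at(self.per_edge, index)


def _node_search(
    net: LogicNetwork,
    target: str,
    trajectories: Sequence[Trajectory],
    domains: Domains,
) -> _NodeSearch:
    """Mismatch count of every local assignment against the node's
    observed transitions, multiplicity-weighted."""
    import numpy as np

    in_idx, constraints = _node_constraints(net, target, trajectories)
    per_edge = _per_edge_domains(net, in_idx, domains)
    n_assign = 1
    for dom in per_edge:
        n_assign *= len(dom)
    n_scored = sum(constraints.values())
    if not in_idx:
        # no in-edges: the single empty assignment predicts "hold"
        mism = 0
        for (_srcs, cur, expected), mult in constraints.items():
            if cur != expected:
                mism += mult
        return _NodeSearch(in_idx, per_edge, np.array([mism]), n_scored)
    # lexicographic expansion: edge e cycles with period prod(d_{e+1:})
    theta = np.empty((n_assign, len(in_idx)), dtype=np.int64)
    weight = np.empty((n_assign, len(in_idx)), dtype=np.int64)
    idx = np.arange(n_assign)
    stride = 1
    for e in range(len(in_idx) - 1, -1, -1):
        dom = per_edge[e]
        pos = (idx // stride) % len(dom)
        pairs = np.asarray(dom, dtype=np.int64)
        theta[:, e] = pairs[pos, 0]
        weight[:, e] = pairs[pos, 1]
        stride *= len(dom)
    signs = np.array([int(net.edge_sign[i]) for i in in_idx], dtype=np.int64)
    max_level = net.node(target).max_level
    mism = np.zeros(n_assign, dtype=np.int64)
    for (srcs, cur, expected), mult in constraints.items():
        active = np.asarray(srcs, dtype=np.int64)[None, :] >= theta
        balance = (active * signs * weight).sum(axis=1)
        pred = np.clip(cur + np.sign(balance), 0, max_level)
        mism += mult * (pred != expected)
    return _NodeSearch(in_idx, per_edge, mism, n_scored)


def fit_node_csp(
    net: LogicNetwork,
    target: str,
    trajectories: Sequence[Trajectory],
    K: int = 1,
    domains: Domains = Domains(),
) -> list[NodeAssignment]:
    """All in-edge (theta, w) assignments whose one-step predictions
    reproduce every scored observed transition of ``target``.

    Exhaustive over the finite domain; an empty result means the
    observations are contradictory under the decisional rule.  With no
    scored transition every assignment is returned (vacuous
    constraints).  Only K = 1 admits this exact per-node decomposition.
    """
    if K != 1:
        raise NetworkValidationError(
            "per-node constraint satisfaction is exact only at K=1"
        )
    if net.node(target).kind != "dynamic":
        raise NetworkValidationError(f"target {target!r} is not a dynamic node")
    search = _node_search(net, target, trajectories, domains)
    return [
        search.assignment(int(i))
        for i in range(search.n_assignments)
        if search.mismatch[i] == 0
    ]


# ---------------------------------------------------------------------------
# Network-level composition
# ---------------------------------------------------------------------------


@dataclass
class CandidateModels:
    """The retained decisional logics and the search bookkeeping.

    ``models`` are enumerated deterministically (per-node assignments
    ordered by mismatch then domain order, composed depth-first), so the
    first model is always a best-coverage one.  ``exact_space_size`` is
    the number of models reproducing every scored transition exactly
    (product of per-node exact-solution counts), independent of the
    ``max_models`` cap.
    """

    models: list[ParameterSet]
    coverages: list[float]
    n_scored: int
    coverage_min: float
    best_coverage: float
    exact_space_size: int
    truncated: bool
    per_node_exact: dict[str, int]
    config: dict = field(default_factory=dict)

    @property
    def n_models(self) -> int:
        return len(self.models)

    def admits(self, net: LogicNetwork, params: ParameterSet) -> bool:
        """Would ``params`` be in the (uncapped) candidate set? True iff
        its total mismatch fits the coverage budget."""
        trajs = self.config.get("_trajectories")
        if trajs is None:
            raise NetworkValidationError("candidate set was built without trajectories")
        cov = node_transition_coverage(net, params, trajs, self.config.get("K", 1))
        return cov >= self.coverage_min or (
            self.n_scored == 0
        )


def fit_network(
    net: LogicNetwork,
    trajectories: Sequence[Trajectory],
    K: int = 1,
    domains: Domains = Domains(),
    coverage_min: float = 0.75,
    max_models: int = 1000,
) -> CandidateModels:
    """Enumerate decisional logics consistent with the observations.

    At K = 1 the candidate space is the composition of per-node CSP
    solutions: a model is retained iff its total mismatch keeps coverage
    at or above ``coverage_min`` (``coverage_min = 1`` is the strict
    mode requiring exact reproduction of every scored transition).
    Models are yielded best-first and deterministically, up to
    ``max_models``.  For K > 1 the per-node decomposition no longer
    holds and an exhaustive joint search with a mismatch-budget prune is
    used (guarded by a domain-size cap).

    An empty result reports the best achievable coverage so the caller
    can diagnose an unsatisfiable fit.
    """
    if not 0 < coverage_min <= 1:
        raise NetworkValidationError("coverage_min must lie in (0, 1]")
    if max_models < 1:
        raise NetworkValidationError("max_models must be >= 1")
    if K != 1:
        return _fit_network_global(net, trajectories, K, domains, coverage_min, max_models)

    import numpy as np

    node_names = [n.name for n in net.dynamic_nodes]
    searches: list[_NodeSearch] = []
    orders: list[np.ndarray] = []  # best-first: mismatch, then domain order
    n_scored = 0
    for name in node_names:
        search = _node_search(net, name, trajectories, domains)
        searches.append(search)
        orders.append(np.argsort(search.mismatch, kind="stable"))
        n_scored += search.n_scored

    min_mismatch = [int(s.mismatch[o[0]]) for s, o in zip(searches, orders)]
    suffix_min = [0] * (len(searches) + 1)
    for i in range(len(searches) - 1, -1, -1):
        suffix_min[i] = suffix_min[i + 1] + min_mismatch[i]
    budget = int((1.0 - coverage_min) * n_scored + 1e-9) if n_scored else 0
    best_coverage = 1.0 - (suffix_min[0] / n_scored) if n_scored else 1.0

    per_node_exact = {
        name: int((s.mismatch == 0).sum()) for name, s in zip(node_names, searches)
    }
    exact_space = 1
    for c in per_node_exact.values():
        exact_space *= c

    models: list[ParameterSet] = []
    coverages: list[float] = []
    truncated = False

    base_theta = [1] * net.n_edges
    base_weight = [domains.weight_domain()[0]] * net.n_edges

    def dfs(level: int, spent: int, chosen: list[NodeAssignment]) -> bool:
        nonlocal truncated
        if spent + suffix_min[level] > budget:
            return True
        if level == len(searches):
            theta = list(base_theta)
            weight = list(base_weight)
            for search, assignment in zip(searches, chosen):
                for edge_i, (t, w) in zip(search.in_idx, assignment):
                    theta[edge_i] = t
                    weight[edge_i] = w
            models.append(ParameterSet(net, theta, weight))
            coverages.append(1.0 - (spent / n_scored) if n_scored else 1.0)
            if len(models) >= max_models:
                truncated = True
                return False
            return True
        search = searches[level]
        for raw_i in orders[level]:
            mism = int(search.mismatch[raw_i])
            if spent + mism + suffix_min[level + 1] > budget:
                break  # entries sorted by mismatch: nothing further fits
            chosen.append(search.assignment(int(raw_i)))
            keep_going = dfs(level + 1, spent + mism, chosen)
            chosen.pop()
            if not keep_going:
                return False
        return True

    if best_coverage >= coverage_min - 1e-12:
        dfs(0, 0, [])

    return CandidateModels(
        models=models,
        coverages=coverages,
        n_scored=n_scored,
        coverage_min=coverage_min,
        best_coverage=best_coverage,
        exact_space_size=exact_space,
        truncated=truncated,
        per_node_exact=per_node_exact,
        config={
            "K": K,
            "coverage_min": coverage_min,
            "max_models": max_models,
            "domains": domains,
            "_trajectories": tuple(trajectories),
        },
    )


_GLOBAL_SEARCH_CAP = 200_000  # joint assignments tolerated for K > 1


def _fit_network_global(
    net: LogicNetwork,
    trajectories: Sequence[Trajectory],
    K: int,
    domains: Domains,
    coverage_min: float,
    max_models: int,
) -> CandidateModels:
    """Joint search over the full parameter space for multi-step horizons."""
    per_edge = []
    for e in net.edges:
        src = net.node(e.source)
        per_edge.append(
            [(t, w) for t in domains.theta_domain(src) for w in domains.weight_domain()]
        )
    space = 1
    for d in per_edge:
        space *= len(d)
        if space > _GLOBAL_SEARCH_CAP:
            raise NetworkValidationError(
                f"K={K} joint search over > {_GLOBAL_SEARCH_CAP} assignments; "
                "reduce the domains or use K=1"
            )
    models: list[ParameterSet] = []
    coverages: list[float] = []
    best = 0.0
    n_scored = 0
    truncated = False
    for combo in itertools.product(*per_edge):
        params = ParameterSet(net, [t for t, _ in combo], [w for _, w in combo])
        err = alignment_error(net, params, trajectories, K)
        n_scored = err.n_scored
        matches = node_transition_coverage(net, params, trajectories, K)
        best = max(best, matches)
        if matches >= coverage_min:
            if len(models) >= max_models:
                truncated = True
                break
            models.append(params)
            coverages.append(matches)
    return CandidateModels(
        models=models,
        coverages=coverages,
        n_scored=n_scored,
        coverage_min=coverage_min,
        best_coverage=best,
        exact_space_size=sum(1 for c in coverages if c == 1.0),
        truncated=truncated,
        per_node_exact={},
        config={
            "K": K,
            "coverage_min": coverage_min,
            "max_models": max_models,
            "domains": domains,
            "_trajectories": tuple(trajectories),
        },
    )


def error_report_frame(err: AlignmentError) -> pd.DataFrame:
    """Per-node error report (node, error, percent of total)."""
    pct = err.by_node_percent
    rows = [
        {"node": node, "error": e, "percent": pct[node]}
        for node, e in sorted(err.by_node.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["node", "error", "percent"])


def models_to_frame(net: LogicNetwork, candidates: CandidateModels) -> pd.DataFrame:
    """Long-format serialization: model_id, source, target, theta, weight."""
    rows = []
    for mid, (params, cov) in enumerate(zip(candidates.models, candidates.coverages)):
        for e, t, w in zip(net.edges, params.theta, params.weight):
            rows.append(
                {
                    "model_id": mid,
                    "coverage": cov,
                    "source": e.source,
                    "target": e.target,
                    "theta": t,
                    "weight": w,
                }
            )
    return pd.DataFrame(
        rows, columns=["model_id", "coverage", "source", "target", "theta", "weight"]
    )
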