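"""Minimal intervention sets: breaking out of persistent non-adherence.

A persistent non-adherent end-state is self-reinforcing: left alone, the
network returns to it.  An intervention clamps one or more clinically
actionable (targetable) nodes at an extreme level — ``up`` at the
maximum, ``down`` at the minimum — holds the clamp for a number of
synchronous steps, releases it, and lets the network settle.  The
intervention succeeds when the network settles into an adherent
end-state (a *sustained* mode instead requires adherence while the
clamp is held indefinitely).

A minimal intervention set (MIS) is a smallest successful clamp
combination: no strict subset of its actions succeeds from the same
state under the same model.  Interventions are ranked by size, then
promptness (steps until the adherence node first reaches its maximum),
then robustness (fraction of noisy replicates still succeeding).
Consensus analysis repeats the search under every candidate model and
tabulates, per strategy, how many distinct non-adherent states are
rescued within each demographic stratum.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    Attractor,
    sample_attractors,
    simulate,
    step_synchronous,
)
from .network import LogicNetwork, NetworkValidationError, ParameterSet

__all__ = [
    "InterventionAction",
    "InterventionOutcome",
    "InterventionResult",
    "ConsensusResult",
    "apply_intervention",
    "find_mis",
    "score_robustness",
    "consensus_interventions",
]

UP = "up"
DOWN = "down"

DEFAULT_MAX_SIZE = 2    # "one or two" actionable mediators per strategy
DEFAULT_HOLD_STEPS = 5
DEFAULT_NOISE_PROB = 0.05
DEFAULT_REPLICATES = 100


@dataclass(frozen=True, order=True)
class InterventionAction:
    """Clamp one targetable node at an extreme level."""

    node: str
    direction: str

    def __post_init__(self) -> None:
        if self.direction not in (UP, DOWN):
            raise NetworkValidationError(
                f"direction must be 'up' or 'down', got {self.direction!r}"
            )

    def label(self) -> str:
        arrow = "up" if self.direction == UP else "down"
        return f"{arrow}:{self.node}"


def _check_actions(net: LogicNetwork, actions: Iterable[InterventionAction]) -> tuple[InterventionAction, ...]:
    actions = tuple(sorted(actions))
    nodes = [a.node for a in actions]
    if len(set(nodes)) != len(nodes):
        raise NetworkValidationError("an intervention clamps each node at most once")
    for a in actions:
        spec = net.node(a.node)
        if not spec.targetable:
            raise NetworkValidationError(f"node {a.node!r} is not targetable")
    return actions


def _clamp(net: LogicNetwork, state: list[int], actions: Sequence[InterventionAction]) -> None:
    for a in actions:
        i = net.index(a.node)
        state[i] = net.nodes[i].max_level if a.direction == UP else 0


@dataclass(frozen=True)
class InterventionOutcome:
    """The full simulated course of one intervention attempt."""

    success: bool
    trajectory: tuple[tuple[int, ...], ...]
    promptness: int | None   # steps from clamp onset to adherence at maximum
    final_attractor: Attractor | None


def apply_intervention(
    net: LogicNetwork,
    params: ParameterSet,
    state: Sequence[int],
    actions: Iterable[InterventionAction],
    hold_steps: int = DEFAULT_HOLD_STEPS,
    max_steps: int = 50,
    sustained: bool = False,
    noise_prob: float = 0.0,
    rng: np.random.Generator | None = None,
) -> InterventionOutcome:
    """Clamp, hold, release, settle.

    Starting from an end-state of (net, params), the action nodes are
    clamped at their extreme levels for ``hold_steps`` synchronous
    steps, then released; the network then settles for at most
    ``max_steps`` further steps.  Success means the final end-state is
    adherent.  In ``sustained`` mode the clamp is never released and
    success means the clamped dynamics settle into adherence.

    ``noise_prob`` adds per-step, per-node one-level perturbations to
    dynamic nodes (clamps are re-applied), for robustness scoring.
    """
    if hold_steps < 1:
        raise NetworkValidationError("hold_steps must be >= 1")
    params.validate_against(net)
    actions = _check_actions(net, actions)
    if noise_prob and rng is None:
        raise NetworkValidationError("noisy runs need an explicit rng")
    adh_idx = net.adherence_index
    adh_max = net.nodes[adh_idx].max_level

    current = list(int(v) for v in state)
    _clamp(net, current, actions)
    trajectory: list[tuple[int, ...]] = [tuple(current)]

    def note_promptness(prompt: int | None, step: int, s: Sequence[int]) -> int | None:
        if prompt is None and s[adh_idx] == adh_max:
            return step
        return prompt

    def perturb(s: list[int]) -> None:
        if not noise_prob:
            return
        for i, spec in enumerate(net.nodes):
            if not net.is_dynamic[i]:
                continue
            if rng.random() < noise_prob:
                direction = 1 if rng.random() < 0.5 else -1
                s[i] = min(max(s[i] + direction, 0), spec.max_level)

    promptness = note_promptness(None, 0, current)
    step = 0
    hold_total = hold_steps if not sustained else hold_steps + max_steps
    for _ in range(hold_total):
        current = list(step_synchronous(net, params, tuple(current)))
        perturb(current)
        _clamp(net, current, actions)
        step += 1
        trajectory.append(tuple(current))
        promptness = note_promptness(promptness, step, current)

    if sustained:
        # settle the clamped dynamics deterministically to an end-state
        final = _settle_clamped(net, params, tuple(current), actions)
        success = bool(final is not None and final.adherent)
        return InterventionOutcome(success, tuple(trajectory), promptness, final)

    if noise_prob:
        for _ in range(max_steps):
            current = list(step_synchronous(net, params, tuple(current)))
            perturb(current)
            step += 1
            trajectory.append(tuple(current))
            promptness = note_promptness(promptness, step, current)
    res = simulate(net, params, tuple(current), max_steps=max_steps)
    for s in res.states[1:]:
        step += 1
        trajectory.append(s)
        promptness = note_promptness(promptness, step, s)
    success = bool(res.converged and res.attractor is not None and res.attractor.adherent)
    return InterventionOutcome(success, tuple(trajectory), promptness, res.attractor)


def _settle_clamped(
    net: LogicNetwork,
    params: ParameterSet,
    state: tuple[int, ...],
    actions: Sequence[InterventionAction],
) -> Attractor | None:
    """Attractor of the dynamics with the clamp permanently applied."""
    from .dynamics import _canonical_cycle, _is_adherent_cycle  # shared helpers

    seen: dict[tuple[int, ...], int] = {state: 0}
    path = [state]
    current = state
    for step in range(1, net.state_space_size() + 2):
        nxt = list(step_synchronous(net, params, current))
        _clamp(net, nxt, actions)
        current = tuple(nxt)
        if current in seen:
            cycle = path[seen[current]:]
            states = _canonical_cycle(cycle)
            return Attractor(states, adherent=_is_adherent_cycle(net, states))
        seen[current] = step
        path.append(current)
    return None


@dataclass(frozen=True)
class InterventionResult:
    """A (minimal) intervention with its ranking scores."""

    actions: tuple[InterventionAction, ...]
    source_state: tuple[int, ...]
    success: bool
    promptness: int | None = None
    robustness: float | None = None
    already_adherent: bool = False
    supporting_models: tuple[int, ...] = ()

    @property
    def size(self) -> int:
        return len(self.actions)

    def label(self) -> str:
        if not self.actions:
            return "(none)"
        return " + ".join(a.label() for a in self.actions)


def find_mis(
    net: LogicNetwork,
    params: ParameterSet,
    attractor: Attractor,
    max_size: int = DEFAULT_MAX_SIZE,
    hold_steps: int = DEFAULT_HOLD_STEPS,
    max_steps: int = 50,
    sustained: bool = False,
) -> list[InterventionResult]:
    """All minimal intervention sets rescuing ``attractor``, exhaustively
    over action subsets of size 1..``max_size``.

    Supersets of an already-successful set are never reported (they are
    not minimal).  An adherent source yields a single empty-set result
    marked ``already_adherent``.  An empty list means no clamp
    combination within the size bound rescues this state.
    """
    if max_size < 1:
        raise NetworkValidationError("max_size must be >= 1")
    params.validate_against(net)
    source = attractor.states[0]
    if attractor.adherent:
        return [
            InterventionResult(
                (), source, True, promptness=0, already_adherent=True
            )
        ]
    universe = [
        InterventionAction(n.name, d)
        for n in net.targetable_nodes
        for d in (UP, DOWN)
    ]
    found: list[InterventionResult] = []
    minimal_sets: list[frozenset[InterventionAction]] = []
    for size in range(1, max_size + 1):
        for combo in itertools.combinations(universe, size):
            nodes = [a.node for a in combo]
            if len(set(nodes)) != len(nodes):
                continue
            combo_set = frozenset(combo)
            if any(m < combo_set for m in minimal_sets):
                continue  # a strict subset already succeeds
            outcome = apply_intervention(
                net, params, source, combo,
                hold_steps=hold_steps, max_steps=max_steps, sustained=sustained,
            )
            if outcome.success:
                minimal_sets.append(combo_set)
                found.append(
                    InterventionResult(
                        tuple(sorted(combo)), source, True,
                        promptness=outcome.promptness,
                    )
                )
    found.sort(key=lambda r: (r.size, r.promptness if r.promptness is not None else 10**9, r.actions))
    return found


def score_robustness(
    net: LogicNetwork,
    params: ParameterSet,
    result: InterventionResult,
    noise_prob: float = DEFAULT_NOISE_PROB,
    n_replicates: int = DEFAULT_REPLICATES,
    seed: int | np.random.Generator | None = None,
    hold_steps: int = DEFAULT_HOLD_STEPS,
    max_steps: int = 50,
    sustained: bool = False,
) -> InterventionResult:
    """Fraction of noisy replicates in which the intervention still
    succeeds; returns the result annotated with that robustness."""
    if not 0 <= noise_prob < 1:
        raise NetworkValidationError("noise_prob must lie in [0, 1)")
    if n_replicates < 1:
        raise NetworkValidationError("n_replicates must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    successes = 0
    for _ in range(n_replicates):
        outcome = apply_intervention(
            net, params, result.source_state, result.actions,
            hold_steps=hold_steps, max_steps=max_steps, sustained=sustained,
            noise_prob=noise_prob, rng=rng,
        )
        successes += outcome.success
    return replace(result, robustness=successes / n_replicates)


@dataclass
class ConsensusResult:
    """Intervention strategies aggregated across candidate models.

    ``table`` mirrors an idealized-intervention-strategy layout: one row
    per strategy, rescued-state counts per demographic stratum (one
    column per input-node level), a total column, and model support.
    """

    table: pd.DataFrame
    n_models: int
    n_nonadherent_states: int
    n_rescued_states: int
    unanimous_strategies: list[str]
    per_model_attractors: list[int]


def consensus_interventions(
    net: LogicNetwork,
    models: Sequence[ParameterSet],
    seed: int | None = None,
    n_inits: int = 1000,
    max_steps: int = 50,
    max_size: int = DEFAULT_MAX_SIZE,
    hold_steps: int = DEFAULT_HOLD_STEPS,
    sustained: bool = False,
    attractors_by_model: Sequence[Sequence[Attractor]] | None = None,
) -> ConsensusResult:
    """Search for MIS under every candidate model and every persistent
    non-adherent state, then aggregate by strategy and demographic
    stratum.

    End-states per model come from a seeded random-restart census
    (``n_inits`` x ``max_steps``) unless ``attractors_by_model`` is
    supplied.  A strategy is *unanimous* when every model that has
    non-adherent end-states supports it for at least one of them.
    """
    if not models:
        raise NetworkValidationError("consensus needs at least one model")
    input_specs = net.input_nodes
    seeds = np.random.SeedSequence(seed).spawn(len(models))
    strategy_rows: dict[tuple[InterventionAction, ...], dict] = {}
    all_states: set[tuple[int, ...]] = set()
    rescued_states: set[tuple[int, ...]] = set()
    per_model_counts: list[int] = []
    models_with_states: set[int] = set()
    for m_i, params in enumerate(models):
        if attractors_by_model is not None:
            atts = list(attractors_by_model[m_i])
        else:
            rng = np.random.default_rng(seeds[m_i])
            atts = list(
                sample_attractors(
                    net, params, n_inits=n_inits, max_steps=max_steps, seed=rng
                ).attractors
            )
        nonadh = [a for a in atts if a.adherent is False]
        per_model_counts.append(len(nonadh))
        if nonadh:
            models_with_states.add(m_i)
        for att in nonadh:
            all_states.add(att.states[0])
            for res in find_mis(
                net, params, att,
                max_size=max_size, hold_steps=hold_steps, max_steps=max_steps,
                sustained=sustained,
            ):
                if not res.success or res.already_adherent:
                    continue
                rescued_states.add(att.states[0])
                row = strategy_rows.setdefault(
                    res.actions,
                    {
                        "models": set(),
                        "states": set(),
                        "by_stratum": {},
                    },
                )
                row["models"].add(m_i)
                row["states"].add(att.states[0])
                for spec in input_specs:
                    level = att.states[0][net.index(spec.name)]
                    key = (spec.name, level)
                    row["by_stratum"].setdefault(key, set()).add(att.states[0])

    stratum_cols = [
        f"{spec.name}={level}"
        for spec in input_specs
        for level in range(spec.n_levels)
    ]
    records = []
    unanimous: list[str] = []
    n_supporting_needed = len(models_with_states) or len(models)
    for actions, row in strategy_rows.items():
        label = " + ".join(a.label() for a in actions)
        rec = {
            "strategy": label,
            "n_actions": len(actions),
        }
        for spec in input_specs:
            for level in range(spec.n_levels):
                rec[f"{spec.name}={level}"] = len(
                    row["by_stratum"].get((spec.name, level), ())
                )
        rec["total_rescued"] = len(row["states"])
        rec["n_supporting_models"] = len(row["models"])
        rec["support_fraction"] = len(row["models"]) / len(models)
        rec["unanimous"] = len(row["models"]) >= n_supporting_needed
        if rec["unanimous"]:
            unanimous.append(label)
        records.append(rec)
    columns = [
        "strategy",
        "n_actions",
        *stratum_cols,
        "total_rescued",
        "n_supporting_models",
        "support_fraction",
        "unanimous",
    ]
    table = pd.DataFrame(records, columns=columns)
    if len(table):
        table = table.sort_values(
            ["n_actions", "total_rescued", "strategy"],
            ascending=[True, False, True],
        ).reset_index(drop=True)
    return ConsensusResult(
        table=table,
        n_models=len(models),
        n_nonadherent_states=len(all_states),
        n_rescued_states=len(rescued_states),
        unanimous_strategies=sorted(unanimous),
        per_model_attractors=per_model_counts,
    )
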