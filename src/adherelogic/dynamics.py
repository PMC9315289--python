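"""Synchronous multi-valued dynamics: network image, simulation, attractors.

The update rule for a dynamic node compares the summed weights of its
*perceived* activators (source level >= the edge's perception threshold)
against its perceived inhibitors:

* activators outweigh inhibitors -> level rises by one (capped at max),
* inhibitors outweigh activators -> level drops by one (floored at 0),
* balance, or no perceived in-edge -> the level holds.

Changes are step-limited (one level per step), so qualitative change is
gradual.  Input nodes are copied unchanged.  The vector of suggested next
levels for all nodes is the *network image*; synchronous update applies
it to every node simultaneously.  Because the dynamics are deterministic
on a finite state space, every trajectory ends in a fixed point or a
cycle — an attractor.  The fraction of initial states that flow into an
attractor (its basin frequency) measures the behavioral inertia of that
end-state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .network import LogicNetwork, ParameterSet

__all__ = [
    "State",
    "Attractor",
    "SimulationResult",
    "SampleResult",
    "compute_image",
    "step_synchronous",
    "step_asynchronous",
    "simulate",
    "enumerate_attractors_exact",
    "sample_attractors",
    "attractor_census_frame",
]

State = tuple[int, ...]

DEFAULT_N_INITS = 1000   # random restarts used to census end-states
DEFAULT_MAX_STEPS = 50   # iterations each restart is allowed to settle
EXACT_CAP = 3 ** 10      # largest state space the exhaustive oracle will walk


@dataclass(frozen=True)
class Attractor:
    """A persistent end-state: a fixed point (period 1) or cycle.

    ``states`` is rotated so the lexicographically smallest state comes
    first, making equal attractors compare equal.  ``adherent`` is True
    when the adherence node sits at its maximum level in every state of
    the cycle.
    """

    states: tuple[State, ...]
    basin_frequency: float = 0.0
    adherent: bool | None = None

    @property
    def period(self) -> int:
        return len(self.states)

    @property
    def is_fixed_point(self) -> bool:
        return self.period == 1

    def key(self) -> tuple[State, ...]:
        return self.states

    def with_frequency(self, freq: float) -> "Attractor":
        return Attractor(self.states, freq, self.adherent)


def _canonical_cycle(states: Sequence[State]) -> tuple[State, ...]:
    states = list(states)
    pivot = min(range(len(states)), key=lambda i: states[i])
    return tuple(states[pivot:] + states[:pivot])


def _is_adherent_cycle(net: LogicNetwork, states: Iterable[State]) -> bool | None:
    if net.adherence_node is None:
        return None
    idx = net.adherence_index
    top = net.nodes[idx].max_level
    return all(s[idx] == top for s in states)


def _batch_image(
    net: LogicNetwork, params: ParameterSet, states: np.ndarray
) -> np.ndarray:
    """Network image for a batch of states (rows)."""
    src = net.edge_source_idx
    tgt = net.edge_target_idx
    # perceived edge contributions, signed by mode and scaled by weight
    active = states[:, src] >= params.theta_arr  # (m, E)
    contrib = active * (net.edge_sign * params.weight_arr)  # (m, E)
    balance = np.zeros(states.shape, dtype=np.int64)
    np.add.at(balance.T, tgt, contrib.T)
    delta = np.sign(balance)
    delta[:, ~net.is_dynamic] = 0
    image = states + delta
    np.clip(image, 0, net.levels - 1, out=image)
    return image


def compute_image(
    net: LogicNetwork, params: ParameterSet, state: Sequence[int]
) -> State:
    """The suggested next state for all nodes given the current state."""
    params.validate_against(net)
    net.validate_state(state)
    arr = np.asarray(state, dtype=np.int64)[None, :]
    return tuple(int(v) for v in _batch_image(net, params, arr)[0])


def step_synchronous(
    net: LogicNetwork, params: ParameterSet, state: Sequence[int]
) -> State:
    """Apply the network image to all nodes simultaneously."""
    return compute_image(net, params, state)


def step_asynchronous(
    net: LogicNetwork,
    params: ParameterSet,
    state: Sequence[int],
    rng: np.random.Generator,
) -> State:
    """Apply the image to one random eligible (changing) dynamic node.

    Exploratory alternative update scheme; the analysis pipeline uses
    the synchronous scheme throughout.
    """
    image = compute_image(net, params, state)
    changing = [i for i, (a, b) in enumerate(zip(state, image)) if a != b]
    if not changing:
        return tuple(int(v) for v in state)
    pick = int(rng.choice(changing))
    out = list(int(v) for v in state)
    out[pick] = image[pick]
    return tuple(out)


@dataclass(frozen=True)
class SimulationResult:
    """A simulated trajectory with attractor bookkeeping.

    ``states`` runs from the initial state up to and including the first
    repeated state (when one occurs within ``max_steps``).
    """

    states: tuple[State, ...]
    converged: bool
    attractor: Attractor | None

    @property
    def n_steps(self) -> int:
        return len(self.states) - 1


def simulate(
    net: LogicNetwork,
    params: ParameterSet,
    initial: Sequence[int],
    max_steps: int | None = DEFAULT_MAX_STEPS,
) -> SimulationResult:
    """Iterate synchronous updates from ``initial``, stopping at the first
    repeated state (an attractor was entered) or after ``max_steps``.

    ``max_steps=None`` runs until convergence, which is guaranteed on
    the finite state space.
    """
    if max_steps is not None and max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    params.validate_against(net)
    net.validate_state(initial)
    state: State = tuple(int(v) for v in initial)
    seen: dict[State, int] = {state: 0}
    trajectory: list[State] = [state]
    arr = np.asarray(state, dtype=np.int64)[None, :]
    step = 0
    while max_steps is None or step < max_steps:
        arr = _batch_image(net, params, arr)
        state = tuple(int(v) for v in arr[0])
        trajectory.append(state)
        step += 1
        if state in seen:
            cycle = trajectory[seen[state]:-1]
            states = _canonical_cycle(cycle)
            att = Attractor(states, adherent=_is_adherent_cycle(net, states))
            return SimulationResult(tuple(trajectory), True, att)
        seen[state] = step
    return SimulationResult(tuple(trajectory), False, None)


def _all_states(net: LogicNetwork) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(l) for l in net.levels], indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1).astype(np.int64)


def _state_index(net: LogicNetwork, states: np.ndarray) -> np.ndarray:
    """Mixed-radix encoding of state rows, matching ``_all_states`` order."""
    radices = net.levels
    weights = np.ones(net.n_nodes, dtype=np.int64)
    for i in range(net.n_nodes - 2, -1, -1):
        weights[i] = weights[i + 1] * radices[i + 1]
    return states @ weights


def enumerate_attractors_exact(
    net: LogicNetwork, params: ParameterSet, cap: int = EXACT_CAP
) -> list[Attractor]:
    """Exhaustive attractor census over the full state space.

    Follows every state to its attractor, so basin fractions are exact
    and sum to one.  Refuses state spaces larger than ``cap``.
    """
    params.validate_against(net)
    n_states = net.state_space_size()
    if n_states > cap:
        raise ValueError(
            f"state space has {n_states} states, above the exact-enumeration "
            f"cap of {cap}"
        )
    all_states = _all_states(net)
    succ = _state_index(net, _batch_image(net, params, all_states))

    label = np.full(n_states, -1, dtype=np.int64)  # attractor id per state
    visiting = np.full(n_states, -1, dtype=np.int64)  # walk id while on path
    attractors: list[Attractor] = []
    for start in range(n_states):
        if label[start] >= 0:
            continue
        path: list[int] = []
        s = start
        while label[s] < 0 and visiting[s] != start:
            visiting[s] = start
            path.append(s)
            s = int(succ[s])
        if label[s] >= 0:
            att_id = int(label[s])
        else:
            # s closes a new cycle within the current path
            pos = path.index(s)
            cycle_idx = path[pos:]
            states = _canonical_cycle(
                [tuple(int(v) for v in all_states[i]) for i in cycle_idx]
            )
            att_id = len(attractors)
            attractors.append(
                Attractor(states, adherent=_is_adherent_cycle(net, states))
            )
        for i in path:
            label[i] = att_id
    counts = np.bincount(label, minlength=len(attractors))
    total = float(n_states)
    out = [a.with_frequency(int(c) / total) for a, c in zip(attractors, counts)]
    out.sort(key=lambda a: (-a.basin_frequency, a.key()))
    return out


@dataclass(frozen=True)
class SampleResult:
    """Attractors reached from random restarts.

    ``basin_frequency`` of each attractor is the fraction of *all*
    sampled initial states that reached it within ``max_steps``, so the
    frequencies sum to ``1 - unconverged_fraction``.
    """

    attractors: tuple[Attractor, ...]
    unconverged_fraction: float
    n_inits: int


def sample_attractors(
    net: LogicNetwork,
    params: ParameterSet,
    n_inits: int = DEFAULT_N_INITS,
    max_steps: int | None = DEFAULT_MAX_STEPS,
    seed: int | np.random.Generator | None = None,
    inits: Sequence[Sequence[int]] | None = None,
) -> SampleResult:
    """Monte Carlo census of end-states.

    Draws ``n_inits`` initial states uniformly over every node's levels
    (inputs included) — or uses ``inits`` verbatim when given — and
    simulates each for ``max_steps`` synchronous iterations.  The
    frequency of each reached end-state estimates its behavioral
    inertia.  Identical seeds give identical output.
    """
    params.validate_against(net)
    if inits is None:
        if n_inits < 1:
            raise ValueError("n_inits must be >= 1")
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        draws = np.stack(
            [rng.integers(0, l, size=n_inits) for l in net.levels], axis=1
        ).astype(np.int64)
    else:
        draws = np.asarray(list(inits), dtype=np.int64)
        n_inits = draws.shape[0]
    tally: dict[tuple[State, ...], tuple[Attractor, int]] = {}
    unconverged = 0
    for row in draws:
        res = simulate(net, params, tuple(int(v) for v in row), max_steps=max_steps)
        if not res.converged:
            unconverged += 1
            continue
        att = res.attractor
        key = att.key()
        if key in tally:
            prev, c = tally[key]
            tally[key] = (prev, c + 1)
        else:
            tally[key] = (att, 1)
    total = float(n_inits)
    attractors = [a.with_frequency(c / total) for a, c in tally.values()]
    attractors.sort(key=lambda a: (-a.basin_frequency, a.key()))
    return SampleResult(tuple(attractors), unconverged / total, n_inits)


def attractor_census_frame(net: LogicNetwork, attractors: Sequence[Attractor]):
    """Attractor census as a DataFrame: one row per attractor, one column
    per node; multi-state cycles serialize levels as '/'-joined values."""
    import pandas as pd

    rows = []
    for i, att in enumerate(attractors):
        row = {
            "attractor_id": i,
            "period": att.period,
            "adherent": att.adherent,
            "basin_frequency": att.basin_frequency,
        }
        for j, name in enumerate(net.node_names):
            row[name] = "/".join(str(s[j]) for s in att.states)
        rows.append(row)
    columns = ["attractor_id", "period", "adherent", "basin_frequency", *net.node_names]
    return pd.DataFrame(rows, columns=columns)
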