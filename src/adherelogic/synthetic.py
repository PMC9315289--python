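"""Synthetic longitudinal adherence cohorts and score discretization.

The generators emulate the structure of an annual-assessment adherence
study: 3-7 yearly assessments per participant, discrete low/nominal/high
node levels, four characteristic discontinuation subtypes (early-, mid-,
late-persistent, and transient with recovery), maximally contrasting
demographic profiles, observation noise, and missingness.  Ground-truth
parameter draws enable parameter-recovery experiments: a cohort
simulated from a known decisional logic can be handed to the fitting
module to check that the true logic is recovered.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .dynamics import step_synchronous
from .network import (
    ACTIVATE,
    INHIBIT,
    Domains,
    Edge,
    LogicNetwork,
    NetworkValidationError,
    NodeSpec,
    ParameterSet,
)

__all__ = [
    "Assessment",
    "Trajectory",
    "SubtypeSpec",
    "SUBTYPES",
    "tertile_cutpoints",
    "discretize_scores",
    "generate_ground_truth",
    "simulate_cohort",
    "make_characteristic_set",
    "default_subtype_specs",
    "read_trajectories",
    "write_trajectories",
    "write_sidecar",
    "validate_trajectory",
]

ADHERENT = "adherent"
DISCONTINUED = "discontinued"

SUBTYPES = ("early_persistent", "mid_persistent", "late_persistent", "transient_recovery")


@dataclass(frozen=True)
class Assessment:
    """One annual observation: a partial state plus adherence status.

    ``levels`` is ordered as the network's nodes; ``None`` marks a
    missing record.
    """

    timepoint: int
    levels: tuple[int | None, ...]
    adherent: bool


@dataclass
class Trajectory:
    """An ordered per-participant sequence of assessments.

    ``profile`` records the participant's demographic context (input
    node name -> level).  At least three assessments are required, with
    strictly increasing timepoints.
    """

    participant_id: str
    assessments: tuple[Assessment, ...]
    profile: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.assessments = tuple(self.assessments)
        if len(self.assessments) < 3:
            raise NetworkValidationError(
                f"trajectory {self.participant_id!r}: needs >= 3 assessments, "
                f"got {len(self.assessments)}"
            )
        times = [a.timepoint for a in self.assessments]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise NetworkValidationError(
                f"trajectory {self.participant_id!r}: timepoints must be "
                f"strictly increasing, got {times}"
            )

    @property
    def n_assessments(self) -> int:
        return len(self.assessments)

    @property
    def adherence_pattern(self) -> tuple[bool, ...]:
        return tuple(a.adherent for a in self.assessments)


def validate_trajectory(net: LogicNetwork, traj: Trajectory) -> None:
    """Check a trajectory against a network: level ranges, node count,
    and consistency of the adherence flag with the adherence node when
    that node is observed (adherent <=> node at its maximum level)."""
    adh_idx = net.adherence_index if net.adherence_node is not None else None
    for a in traj.assessments:
        if len(a.levels) != net.n_nodes:
            raise NetworkValidationError(
                f"trajectory {traj.participant_id!r}: assessment at t={a.timepoint} "
                f"has {len(a.levels)} levels, network has {net.n_nodes} nodes"
            )
        for spec, level in zip(net.nodes, a.levels):
            if level is not None and not 0 <= level < spec.n_levels:
                raise NetworkValidationError(
                    f"trajectory {traj.participant_id!r}: level {level} out of "
                    f"range for node {spec.name!r}"
                )
        if adh_idx is not None and a.levels[adh_idx] is not None:
            at_max = a.levels[adh_idx] == net.nodes[adh_idx].max_level
            if at_max != a.adherent:
                raise NetworkValidationError(
                    f"trajectory {traj.participant_id!r}: adherence flag at "
                    f"t={a.timepoint} contradicts the observed adherence level"
                )
    for name in traj.profile:
        if name not in net.node_names:
            raise NetworkValidationError(
                f"trajectory {traj.participant_id!r}: profile names unknown "
                f"node {name!r}"
            )


@dataclass(frozen=True)
class SubtypeSpec:
    """Timing of a characteristic discontinuation course.

    ``discontinue_at`` is the assessment index at which status flips to
    discontinued; for the transient subtype, ``recover_at`` is the index
    at which adherence resumes.
    """

    kind: str
    discontinue_at: int
    recover_at: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in SUBTYPES:
            raise NetworkValidationError(f"unknown subtype {self.kind!r}")
        if self.discontinue_at < 1:
            raise NetworkValidationError("discontinue_at must be >= 1")
        if self.kind == "transient_recovery":
            if self.recover_at is None or self.recover_at <= self.discontinue_at:
                raise NetworkValidationError(
                    "transient subtype needs recover_at > discontinue_at"
                )
        elif self.recover_at is not None:
            raise NetworkValidationError(
                f"subtype {self.kind!r} is persistent; recover_at must be None"
            )

    def pattern(self, n_assessments: int) -> tuple[bool, ...]:
        if self.discontinue_at >= n_assessments:
            raise NetworkValidationError(
                f"discontinue_at={self.discontinue_at} outside the "
                f"{n_assessments}-assessment range"
            )
        out = []
        for t in range(n_assessments):
            if t < self.discontinue_at:
                out.append(True)
            elif self.recover_at is not None and t >= self.recover_at:
                out.append(True)
            else:
                out.append(False)
        return tuple(out)


def default_subtype_specs(n_assessments: int = 7) -> tuple[SubtypeSpec, ...]:
    """Early / mid / late persistent discontinuation plus transient
    discontinuation with recovery, spread over the assessment window."""
    if n_assessments < 5:
        raise NetworkValidationError("characteristic courses need >= 5 assessments")
    mid = n_assessments // 2
    return (
        SubtypeSpec("early_persistent", 1),
        SubtypeSpec("mid_persistent", mid),
        SubtypeSpec("late_persistent", n_assessments - 2),
        SubtypeSpec("transient_recovery", 2, recover_at=min(4, n_assessments - 1)),
    )


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------


def tertile_cutpoints(values: Sequence[float], n_levels: int = 3) -> tuple[float, ...]:
    """Equal-quantile cut-points (tertiles for three levels) from the
    observed distribution of a raw score."""
    arr = np.asarray([v for v in values if v is not None and not np.isnan(v)], dtype=float)
    if arr.size == 0:
        raise NetworkValidationError("cannot derive cutpoints from an empty score vector")
    qs = np.arange(1, n_levels) / n_levels
    cuts = tuple(float(q) for q in np.quantile(arr, qs))
    if any(b <= a for a, b in zip(cuts, cuts[1:])):
        raise NetworkValidationError(
            f"degenerate score distribution: non-increasing cutpoints {cuts}"
        )
    return cuts


def _discretize_value(value: float, cuts: Sequence[float]) -> int:
    for i, c in enumerate(cuts):
        if value < c:
            return i
    return len(cuts)


def discretize_scores(
    raw: pd.DataFrame,
    net: LogicNetwork,
    cutpoints: Mapping[str, Sequence[float]],
    id_col: str = "participant_id",
    time_col: str = "timepoint",
    adherence_col: str = "adherence",
) -> list[Trajectory]:
    """Discretize a raw psychometric score table into trajectories.

    Each raw score maps to the index of the first cut-point it falls
    strictly below (the top level when it is above all cut-points);
    missing raw values become missing markers.  The adherence column
    passes through unchanged.  Cut-points must be strictly increasing
    and number ``n_levels - 1`` for their node.
    """
    for name, cuts in cutpoints.items():
        if name not in net.node_names:
            raise NetworkValidationError(f"cutpoints given for unknown node {name!r}")
        spec = net.node(name)
        cuts = list(cuts)
        if len(cuts) != spec.n_levels - 1:
            raise NetworkValidationError(
                f"node {name!r}: expected {spec.n_levels - 1} cutpoints, got {len(cuts)}"
            )
        if any(b <= a for a, b in zip(cuts, cuts[1:])):
            raise NetworkValidationError(
                f"node {name!r}: cutpoints must be strictly increasing, got {cuts}"
            )
    trajectories: list[Trajectory] = []
    for pid, group in raw.groupby(id_col, sort=True):
        group = group.sort_values(time_col)
        assessments = []
        profile: dict[str, int] = {}
        for _, row in group.iterrows():
            levels: list[int | None] = []
            for spec in net.nodes:
                if spec.name not in raw.columns:
                    levels.append(None)
                    continue
                value = row[spec.name]
                if pd.isna(value):
                    levels.append(None)
                    continue
                if spec.name in cutpoints:
                    level = _discretize_value(float(value), cutpoints[spec.name])
                else:
                    level = int(value)  # already discrete
                levels.append(level)
                if spec.kind == "input" and spec.name not in profile:
                    profile[spec.name] = level
            status = str(row[adherence_col]).strip().lower()
            assessments.append(
                Assessment(int(row[time_col]), tuple(levels), status == ADHERENT)
            )
        trajectories.append(Trajectory(str(pid), tuple(assessments), profile))
    return trajectories


# ---------------------------------------------------------------------------
# Random structures for property testing
# ---------------------------------------------------------------------------


def random_network(
    n_nodes: int,
    n_edges: int,
    seed: int | np.random.Generator | None = None,
    n_inputs: int = 0,
    n_levels: int = 3,
    n_targetable: int = 0,
    with_adherence: bool = True,
) -> LogicNetwork:
    """A random valid circuit for property tests and oracle comparisons.

    Edges are drawn without replacement over ordered node pairs with a
    dynamic target (self-loops allowed); modes are random.  The first
    dynamic node is the adherence node; targetable flags go to the first
    ``n_targetable`` dynamic nodes.
    """
    if n_inputs >= n_nodes:
        raise NetworkValidationError("need at least one dynamic node")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_dynamic = n_nodes - n_inputs
    if n_targetable > n_dynamic:
        raise NetworkValidationError("more targetable nodes than dynamic nodes")
    nodes = []
    dyn_names = [f"n{i}" for i in range(n_dynamic)]
    for i, name in enumerate(dyn_names):
        nodes.append(NodeSpec(name, "dynamic", n_levels, targetable=i < n_targetable))
    for i in range(n_inputs):
        nodes.append(NodeSpec(f"x{i}", "input", n_levels))
    all_names = [n.name for n in nodes]
    pairs = [(s, t) for s in all_names for t in dyn_names]
    n_edges = min(n_edges, len(pairs))
    picked = rng.choice(len(pairs), size=n_edges, replace=False)
    edges = [
        Edge(pairs[i][0], pairs[i][1], ACTIVATE if rng.random() < 0.5 else INHIBIT)
        for i in sorted(int(p) for p in picked)
    ]
    return LogicNetwork(
        nodes, edges, adherence_node=dyn_names[0] if with_adherence else None
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def generate_ground_truth(
    net: LogicNetwork,
    seed: int | np.random.Generator | None = None,
    domains: Domains = Domains(),
) -> ParameterSet:
    """Draw a ground-truth decisional logic: per-edge (theta, w) uniform
    over their finite domains, seeded and reproducible."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    theta, weight = [], []
    for e in net.edges:
        tdom = domains.theta_domain(net.node(e.source))
        wdom = domains.weight_domain()
        theta.append(int(rng.choice(tdom)))
        weight.append(int(rng.choice(wdom)))
    return ParameterSet(net, theta, weight)


def _corrupt(
    net: LogicNetwork,
    levels: list[int | None],
    noise_rate: float,
    missing_rate: float,
    rng: np.random.Generator,
) -> list[int | None]:
    out: list[int | None] = []
    for spec, level in zip(net.nodes, levels):
        if level is None:
            out.append(None)
            continue
        v = level
        if noise_rate > 0 and rng.random() < noise_rate:
            # +/-1 qualitative mis-rating, reflected at the scale ends
            direction = 1 if rng.random() < 0.5 else -1
            v = v + direction
            if v < 0 or v > spec.max_level:
                v = level - direction
        if missing_rate > 0 and rng.random() < missing_rate:
            out.append(None)
        else:
            out.append(v)
    return out


def simulate_cohort(
    net: LogicNetwork,
    params: ParameterSet,
    n_participants: int = 82,
    n_assessments: int | tuple[int, int] = (3, 7),
    noise_rate: float = 0.0,
    missing_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
    steps_between: int = 1,
) -> list[Trajectory]:
    """Simulate an annual-assessment cohort from a known decisional logic.

    Each participant receives a random demographic profile (uniform
    input levels) and a random dynamic starting state; consecutive
    assessments are separated by ``steps_between`` synchronous updates.
    Observation noise flips a recorded level by one (probability
    ``noise_rate`` per node-record); records go missing with probability
    ``missing_rate``.  The adherence flag follows the *recorded*
    adherence level when observed, so recorded data stay internally
    consistent even under noise.
    """
    if not (0 <= noise_rate < 1 and 0 <= missing_rate < 1):
        raise NetworkValidationError("noise_rate and missing_rate must lie in [0, 1)")
    if steps_between < 1:
        raise NetworkValidationError("steps_between must be >= 1")
    params.validate_against(net)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    adh_idx = net.adherence_index
    adh_max = net.nodes[adh_idx].max_level
    if isinstance(n_assessments, int):
        lo = hi = n_assessments
    else:
        lo, hi = n_assessments
    cohort: list[Trajectory] = []
    width = len(str(n_participants))
    for p in range(n_participants):
        n_assess = int(rng.integers(lo, hi + 1))
        state = tuple(int(rng.integers(0, l)) for l in net.levels)
        profile = {
            spec.name: state[i]
            for i, spec in enumerate(net.nodes)
            if spec.kind == "input"
        }
        assessments = []
        for t in range(n_assess):
            recorded = _corrupt(net, list(state), noise_rate, missing_rate, rng)
            if recorded[adh_idx] is not None:
                adherent = recorded[adh_idx] == adh_max
            else:
                adherent = state[adh_idx] == adh_max
            assessments.append(Assessment(t, tuple(recorded), adherent))
            for _ in range(steps_between):
                state = step_synchronous(net, params, state)
        cohort.append(Trajectory(f"P{p:0{width}d}", tuple(assessments), profile))
    return cohort


def make_characteristic_set(
    net: LogicNetwork,
    params: ParameterSet,
    seed: int | np.random.Generator | None = None,
    n_assessments: int = 7,
    subtypes: Sequence[SubtypeSpec] | None = None,
) -> list[Trajectory]:
    """The eight reference trajectories: four discontinuation subtypes,
    each realized under two maximally contrasting demographic profiles
    (all inputs low vs. all inputs high).

    The adherence column follows the subtype pattern exactly (adherence
    node clamped to its maximum while adherent, to zero while
    discontinued); the remaining dynamic nodes evolve under the supplied
    decisional logic from a random seeded start.
    """
    params.validate_against(net)
    if net.adherence_node is None:
        raise NetworkValidationError("characteristic courses need an adherence node")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if subtypes is None:
        subtypes = default_subtype_specs(n_assessments)
    adh_idx = net.adherence_index
    adh_max = net.nodes[adh_idx].max_level
    out: list[Trajectory] = []
    for profile_tag, extreme in (("low", 0), ("high", None)):
        for spec_sub in subtypes:
            pattern = spec_sub.pattern(n_assessments)
            state = [int(rng.integers(0, l)) for l in net.levels]
            profile = {}
            for i, spec in enumerate(net.nodes):
                if spec.kind == "input":
                    state[i] = 0 if extreme == 0 else spec.max_level
                    profile[spec.name] = state[i]
            assessments = []
            for t, adherent in enumerate(pattern):
                state[adh_idx] = adh_max if adherent else 0
                assessments.append(Assessment(t, tuple(state), adherent))
                state = list(step_synchronous(net, params, tuple(state)))
            out.append(
                Trajectory(f"{spec_sub.kind}_{profile_tag}", tuple(assessments), profile)
            )
    return out


# ---------------------------------------------------------------------------
# Trajectory I/O
# ---------------------------------------------------------------------------


def _status_column(net: LogicNetwork) -> str:
    # avoid a clash when a network node is itself called "adherence"
    return "adherence_status" if "adherence" in net.node_names else "adherence"


def trajectories_to_frame(trajs: Sequence[Trajectory], net: LogicNetwork) -> pd.DataFrame:
    status = _status_column(net)
    rows = []
    for traj in trajs:
        for a in traj.assessments:
            row = {
                "participant_id": traj.participant_id,
                "timepoint": a.timepoint,
                status: ADHERENT if a.adherent else DISCONTINUED,
            }
            for name, level in zip(net.node_names, a.levels):
                row[name] = "" if level is None else level
            rows.append(row)
    return pd.DataFrame(rows, columns=["participant_id", "timepoint", status, *net.node_names])


def write_trajectories(trajs: Sequence[Trajectory], net: LogicNetwork, path) -> None:
    trajectories_to_frame(trajs, net).to_csv(path, index=False)


def read_trajectories(path, net: LogicNetwork) -> list[Trajectory]:
    frame = pd.read_csv(path, dtype={"participant_id": str})
    status = _status_column(net)
    if status not in frame.columns and "adherence" in frame.columns:
        status = "adherence"
    return discretize_scores(frame, net, cutpoints={}, adherence_col=status)


def write_sidecar(path, parameters: Mapping) -> None:
    """Record generation settings (rates, seed, sizes) next to a cohort file."""
    with open(path, "wt", encoding="utf-8") as fh:
        yaml.safe_dump(dict(parameters), fh, sort_keys=True)
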