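"""Domain types for the behavioral decisional-logic circuit.

A :class:`LogicNetwork` is a directed graph of discrete-valued factors.
Each node holds one of ``n_levels`` qualitative activation levels
(0 = low, ..., n_levels-1 = high; three levels by default).  Edges are
signed: an *activating* edge pushes its target up, an *inhibiting* edge
pushes it down, but only once the source is expressed at or above the
edge's perception threshold.  Nodes are either ``dynamic`` (updated by
the logic) or ``input`` (demographic / clinical context held fixed for
the whole simulation).  A designated adherence node encodes the behavior
of interest: the patient is adherent exactly when that node sits at its
maximum level.

A :class:`ParameterSet` carries the decisional kinetic parameters — one
perception threshold ``theta`` and one integer logic weight ``w`` per
edge — and is bound to the edge list of the network it was built for.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "NodeSpec",
    "Edge",
    "LogicNetwork",
    "ParameterSet",
    "Domains",
    "NetworkValidationError",
    "NetworkParseError",
    "parse_network",
    "read_network_file",
    "write_network",
    "read_sif",
    "write_sif",
    "read_parameters",
    "write_parameters",
    "default_parameters",
    "load_adherence_fixture",
]

ACTIVATE = "activate"
INHIBIT = "inhibit"
_SIGN_TO_MODE = {"+": ACTIVATE, "-": INHIBIT}
_MODE_TO_SIGN = {ACTIVATE: "+", INHIBIT: "-"}


class NetworkValidationError(ValueError):
    """A network, parameter set, or state violates a structural invariant."""


class NetworkParseError(ValueError):
    """A network file is malformed; the message names the offending line."""


@dataclass(frozen=True)
class NodeSpec:
    """One factor in the circuit.

    Parameters
    ----------
    name:
        Unique identifier within the network.
    kind:
        ``"dynamic"`` for factors updated by the decisional logic,
        ``"input"`` for demographic/clinical context held fixed.
    n_levels:
        Number of discrete activation levels (>= 2); 3 means
        low / nominal / high.
    targetable:
        Whether the node is a clinically actionable intervention target.
    """

    name: str
    kind: str = "dynamic"
    n_levels: int = 3
    targetable: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("dynamic", "input"):
            raise NetworkValidationError(
                f"node {self.name!r}: kind must be 'dynamic' or 'input', got {self.kind!r}"
            )
        if self.n_levels < 2:
            raise NetworkValidationError(
                f"node {self.name!r}: n_levels must be >= 2, got {self.n_levels}"
            )
        if self.targetable and self.kind != "dynamic":
            raise NetworkValidationError(
                f"node {self.name!r}: only dynamic nodes can be targetable"
            )

    @property
    def max_level(self) -> int:
        return self.n_levels - 1

    @property
    def nominal_level(self) -> int:
        """The middle ("nominal") level; used to impute unobserved values."""
        return self.n_levels // 2


@dataclass(frozen=True)
class Edge:
    """A signed causal interaction from ``source`` to ``target``."""

    source: str
    target: str
    mode: str

    def __post_init__(self) -> None:
        if self.mode not in (ACTIVATE, INHIBIT):
            raise NetworkValidationError(
                f"edge {self.source}->{self.target}: mode must be "
                f"'activate' or 'inhibit', got {self.mode!r}"
            )

    @property
    def sign(self) -> int:
        return 1 if self.mode == ACTIVATE else -1


class LogicNetwork:
    """A validated decisional-logic circuit.

    Node order is significant: state vectors are ordered as ``nodes``.
    """

    def __init__(
        self,
        nodes: Iterable[NodeSpec],
        edges: Iterable[Edge],
        adherence_node: str | None = None,
    ) -> None:
        self.nodes: tuple[NodeSpec, ...] = tuple(nodes)
        self.edges: tuple[Edge, ...] = tuple(edges)
        self.adherence_node = adherence_node
        self._validate()
        self._index: dict[str, int] = {n.name: i for i, n in enumerate(self.nodes)}
        # Flat arrays used by the dynamics engine.
        self.edge_source_idx = np.array(
            [self._index[e.source] for e in self.edges], dtype=np.int64
        )
        self.edge_target_idx = np.array(
            [self._index[e.target] for e in self.edges], dtype=np.int64
        )
        self.edge_sign = np.array([e.sign for e in self.edges], dtype=np.int64)
        self.levels = np.array([n.n_levels for n in self.nodes], dtype=np.int64)
        self.is_dynamic = np.array(
            [n.kind == "dynamic" for n in self.nodes], dtype=bool
        )
        self.in_edges: dict[str, tuple[int, ...]] = {n.name: () for n in self.nodes}
        by_target: dict[str, list[int]] = {n.name: [] for n in self.nodes}
        for i, e in enumerate(self.edges):
            by_target[e.target].append(i)
        self.in_edges = {k: tuple(v) for k, v in by_target.items()}

    def _validate(self) -> None:
        names = [n.name for n in self.nodes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise NetworkValidationError(f"duplicate node names: {dupes}")
        known = set(names)
        kinds = {n.name: n.kind for n in self.nodes}
        seen_pairs: set[tuple[str, str]] = set()
        for e in self.edges:
            for endpoint in (e.source, e.target):
                if endpoint not in known:
                    raise NetworkValidationError(
                        f"edge {e.source}->{e.target} names unknown node {endpoint!r}"
                    )
            if kinds[e.target] != "dynamic":
                raise NetworkValidationError(
                    f"edge {e.source}->{e.target} targets input node {e.target!r}; "
                    "input nodes are never updated"
                )
            pair = (e.source, e.target)
            if pair in seen_pairs:
                raise NetworkValidationError(f"duplicate edge {e.source}->{e.target}")
            seen_pairs.add(pair)
        if self.adherence_node is not None:
            if self.adherence_node not in known:
                raise NetworkValidationError(
                    f"adherence node {self.adherence_node!r} is not a network node"
                )
            if kinds[self.adherence_node] != "dynamic":
                raise NetworkValidationError(
                    f"adherence node {self.adherence_node!r} must be dynamic"
                )

    # -- lookups ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def node_names(self) -> tuple[str, ...]:
        return tuple(n.name for n in self.nodes)

    def index(self, name: str) -> int:
        return self._index[name]

    def node(self, name: str) -> NodeSpec:
        return self.nodes[self._index[name]]

    @property
    def adherence_index(self) -> int:
        if self.adherence_node is None:
            raise NetworkValidationError("network declares no adherence node")
        return self._index[self.adherence_node]

    @property
    def input_nodes(self) -> tuple[NodeSpec, ...]:
        return tuple(n for n in self.nodes if n.kind == "input")

    @property
    def dynamic_nodes(self) -> tuple[NodeSpec, ...]:
        return tuple(n for n in self.nodes if n.kind == "dynamic")

    @property
    def targetable_nodes(self) -> tuple[NodeSpec, ...]:
        return tuple(n for n in self.nodes if n.targetable)

    def state_space_size(self) -> int:
        return int(np.prod(self.levels, dtype=object))

    def edge_signature(self) -> tuple[tuple[str, str, str], ...]:
        return tuple((e.source, e.target, e.mode) for e in self.edges)

    def validate_state(self, state: Sequence[int]) -> None:
        if len(state) != self.n_nodes:
            raise NetworkValidationError(
                f"state length {len(state)} != node count {self.n_nodes}"
            )
        for spec, level in zip(self.nodes, state):
            if not 0 <= int(level) < spec.n_levels:
                raise NetworkValidationError(
                    f"level {level} out of range [0, {spec.n_levels - 1}] "
                    f"for node {spec.name!r}"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LogicNetwork):
            return NotImplemented
        return (
            self.nodes == other.nodes
            and self.edges == other.edges
            and self.adherence_node == other.adherence_node
        )

    def __repr__(self) -> str:
        return (
            f"LogicNetwork({self.n_nodes} nodes, {self.n_edges} edges, "
            f"adherence_node={self.adherence_node!r})"
        )


@dataclass(frozen=True)
class Domains:
    """Finite search domains for the decisional kinetic parameters.

    ``theta`` of ``None`` means the full admissible range
    ``[1, n_levels(source) - 1]`` for each edge.  Weights default to
    {1, 2}: a "weak" and a "strong" influence.
    """

    theta: tuple[int, ...] | None = None
    weight: tuple[int, ...] = (1, 2)

    def theta_domain(self, source: NodeSpec) -> tuple[int, ...]:
        full = tuple(range(1, source.n_levels))
        if self.theta is None:
            return full
        restricted = tuple(t for t in self.theta if t in set(full))
        if not restricted:
            raise NetworkValidationError(
                f"theta domain {self.theta} has no admissible value for "
                f"source {source.name!r} with {source.n_levels} levels"
            )
        return restricted

    def weight_domain(self) -> tuple[int, ...]:
        return self.weight


class ParameterSet:
    """Per-edge (theta, w) assignment — one candidate decisional logic.

    ``theta[i]`` and ``weight[i]`` parameterize ``network.edges[i]``.
    The set remembers the edge signature of the network it was built
    from and refuses to be applied to any network with a different
    edge list.
    """

    def __init__(
        self,
        network: LogicNetwork,
        theta: Sequence[int],
        weight: Sequence[int],
    ) -> None:
        theta = tuple(int(t) for t in theta)
        weight = tuple(int(w) for w in weight)
        if len(theta) != network.n_edges or len(weight) != network.n_edges:
            raise NetworkValidationError(
                f"expected {network.n_edges} (theta, w) pairs, got "
                f"{len(theta)} thetas / {len(weight)} weights"
            )
        for e, t, w in zip(network.edges, theta, weight):
            src = network.node(e.source)
            if not 1 <= t <= src.max_level:
                raise NetworkValidationError(
                    f"edge {e.source}->{e.target}: theta={t} outside "
                    f"[1, {src.max_level}]"
                )
            if w < 1:
                raise NetworkValidationError(
                    f"edge {e.source}->{e.target}: weight={w} must be >= 1"
                )
        self.theta = theta
        self.weight = weight
        self._signature = network.edge_signature()
        self.theta_arr = np.array(theta, dtype=np.int64)
        self.weight_arr = np.array(weight, dtype=np.int64)

    def validate_against(self, network: LogicNetwork) -> None:
        """Raise unless ``network`` has the exact edge list this set was built for."""
        if network.edge_signature() != self._signature:
            raise NetworkValidationError(
                "parameter set is bound to a different edge list than this network"
            )

    def as_mapping(self) -> dict[tuple[str, str], tuple[int, int]]:
        return {
            (s, t): (th, w)
            for (s, t, _m), th, w in zip(self._signature, self.theta, self.weight)
        }

    def replace(self, network: LogicNetwork, updates: Mapping[tuple[str, str], tuple[int, int]]) -> "ParameterSet":
        """Return a copy with (theta, w) overridden for the given (source, target) edges."""
        self.validate_against(network)
        theta = list(self.theta)
        weight = list(self.weight)
        index = {(e.source, e.target): i for i, e in enumerate(network.edges)}
        for pair, (t, w) in updates.items():
            theta[index[pair]] = t
            weight[index[pair]] = w
        return ParameterSet(network, theta, weight)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ParameterSet):
            return NotImplemented
        return (
            self.theta == other.theta
            and self.weight == other.weight
            and self._signature == other._signature
        )

    def __hash__(self) -> int:
        return hash((self.theta, self.weight, self._signature))

    def __repr__(self) -> str:
        return f"ParameterSet({len(self.theta)} edges)"


def default_parameters(network: LogicNetwork) -> ParameterSet:
    """theta = 1 and w = 1 everywhere: every expressed source is perceived
    and all influences are weak."""
    n = network.n_edges
    return ParameterSet(network, [1] * n, [1] * n)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------
#
# Native TSV dialect::
#
#     # nodes
#     name<TAB>kind<TAB>n_levels<TAB>targetable
#     ...
#     # edges
#     source<TAB>target<TAB>sign[<TAB>theta[<TAB>weight]]
#
# sign is "+" (activate) or "-" (inhibit); the optional columns pin the
# decisional parameters.  Lines starting with "##" are comments.


def _parse_bool(text: str, lineno: int) -> bool:
    t = text.strip().lower()
    if t in ("1", "true", "yes"):
        return True
    if t in ("0", "false", "no"):
        return False
    raise NetworkParseError(f"line {lineno}: expected boolean, got {text!r}")


def read_network_file(path) -> tuple[LogicNetwork, ParameterSet | None]:
    """Parse the native TSV dialect; returns the network and, when the
    edge section pins (theta, w) on every edge, the pinned parameters."""
    nodes: list[NodeSpec] = []
    edge_rows: list[tuple[Edge, int | None, int | None]] = []
    adherence: str | None = None
    section = None
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("##"):
                continue
            if line.startswith("#"):
                header = line.lstrip("#").strip().lower()
                if header.startswith("nodes"):
                    section = "nodes"
                elif header.startswith("edges"):
                    section = "edges"
                elif header.startswith("adherence"):
                    parts = header.split()
                    if len(parts) != 2:
                        raise NetworkParseError(
                            f"line {lineno}: '# adherence <node>' expected"
                        )
                    adherence = parts[1]
                else:
                    raise NetworkParseError(f"line {lineno}: unknown section {line!r}")
                continue
            fields = line.split("\t")
            if section == "nodes":
                if not 1 <= len(fields) <= 4:
                    raise NetworkParseError(
                        f"line {lineno}: node row needs 1-4 tab-separated fields"
                    )
                name = fields[0].strip()
                kind = fields[1].strip() if len(fields) > 1 else "dynamic"
                try:
                    n_levels = int(fields[2]) if len(fields) > 2 else 3
                except ValueError:
                    raise NetworkParseError(
                        f"line {lineno}: n_levels must be an integer, got {fields[2]!r}"
                    ) from None
                targetable = _parse_bool(fields[3], lineno) if len(fields) > 3 else False
                try:
                    nodes.append(NodeSpec(name, kind, n_levels, targetable))
                except NetworkValidationError as exc:
                    raise NetworkParseError(f"line {lineno}: {exc}") from None
            elif section == "edges":
                if not 3 <= len(fields) <= 5:
                    raise NetworkParseError(
                        f"line {lineno}: edge row needs 3-5 tab-separated fields"
                    )
                sign = fields[2].strip()
                if sign not in _SIGN_TO_MODE:
                    raise NetworkParseError(
                        f"line {lineno}: sign must be '+' or '-', got {sign!r}"
                    )
                try:
                    theta = int(fields[3]) if len(fields) > 3 else None
                    weight = int(fields[4]) if len(fields) > 4 else None
                except ValueError:
                    raise NetworkParseError(
                        f"line {lineno}: theta/weight must be integers"
                    ) from None
                edge_rows.append(
                    (
                        Edge(fields[0].strip(), fields[1].strip(), _SIGN_TO_MODE[sign]),
                        theta,
                        weight,
                    )
                )
            else:
                raise NetworkParseError(
                    f"line {lineno}: data row before any '# nodes' / '# edges' header"
                )
    net = LogicNetwork(nodes, [row[0] for row in edge_rows], adherence_node=adherence)
    params: ParameterSet | None = None
    if edge_rows and all(t is not None and w is not None for _, t, w in edge_rows):
        params = ParameterSet(
            net, [t for _, t, _w in edge_rows], [w for _, _t, w in edge_rows]
        )
    return net, params


def parse_network(path) -> LogicNetwork:
    """Parse a network TSV file (see module docstring for the dialect)."""
    net, _params = read_network_file(path)
    return net


def write_network(network: LogicNetwork, path, params: ParameterSet | None = None) -> None:
    if params is not None:
        params.validate_against(network)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("# nodes\n")
        for n in network.nodes:
            fh.write(f"{n.name}\t{n.kind}\t{n.n_levels}\t{int(n.targetable)}\n")
        fh.write("# edges\n")
        for i, e in enumerate(network.edges):
            row = f"{e.source}\t{e.target}\t{_MODE_TO_SIGN[e.mode]}"
            if params is not None:
                row += f"\t{params.theta[i]}\t{params.weight[i]}"
            fh.write(row + "\n")
        if network.adherence_node is not None:
            fh.write(f"# adherence {network.adherence_node}\n")


def read_sif(path, adherence_node: str | None = None, **node_kwargs) -> LogicNetwork:
    """Import a plain SIF file (``source<TAB>interaction<TAB>target``).

    SIF carries no node metadata, so every node is created dynamic with
    the default level count unless overridden via ``node_kwargs`` keyed
    by node name (each value a dict of NodeSpec fields).
    """
    edges: list[Edge] = []
    order: list[str] = []
    seen: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 3:
                raise NetworkParseError(
                    f"line {lineno}: SIF row needs exactly 3 fields"
                )
            src, interaction, tgt = (f.strip() for f in fields)
            mode = {"activate": ACTIVATE, "inhibit": INHIBIT, "+": ACTIVATE, "-": INHIBIT}.get(
                interaction.lower()
            )
            if mode is None:
                raise NetworkParseError(
                    f"line {lineno}: unknown interaction {interaction!r}"
                )
            for name in (src, tgt):
                if name not in seen:
                    seen.add(name)
                    order.append(name)
            edges.append(Edge(src, tgt, mode))
    nodes = [NodeSpec(name, **node_kwargs.get(name, {})) for name in order]
    return LogicNetwork(nodes, edges, adherence_node=adherence_node)


def write_sif(network: LogicNetwork, path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for e in network.edges:
            fh.write(f"{e.source}\t{e.mode}\t{e.target}\n")


def write_parameters(network: LogicNetwork, params: ParameterSet, path) -> None:
    """Sidecar key-value parameter file: ``source<TAB>target<TAB>theta<TAB>weight``."""
    params.validate_against(network)
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("source\ttarget\ttheta\tweight\n")
        for e, t, w in zip(network.edges, params.theta, params.weight):
            fh.write(f"{e.source}\t{e.target}\t{t}\t{w}\n")


def read_parameters(network: LogicNetwork, path) -> ParameterSet:
    values: dict[tuple[str, str], tuple[int, int]] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("source"):
            raise NetworkParseError("parameter file must start with a header row")
        for lineno, raw in enumerate(fh, start=2):
            line = raw.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise NetworkParseError(
                    f"line {lineno}: parameter row needs 4 fields"
                )
            try:
                values[(fields[0], fields[1])] = (int(fields[2]), int(fields[3]))
            except ValueError:
                raise NetworkParseError(
                    f"line {lineno}: theta/weight must be integers"
                ) from None
    theta, weight = [], []
    for e in network.edges:
        if (e.source, e.target) not in values:
            raise NetworkValidationError(
                f"parameter file lacks edge {e.source}->{e.target}"
            )
        t, w = values[(e.source, e.target)]
        theta.append(t)
        weight.append(w)
    if len(values) != network.n_edges:
        extra = set(values) - {(e.source, e.target) for e in network.edges}
        raise NetworkValidationError(f"parameter file has unknown edges: {sorted(extra)}")
    return ParameterSet(network, theta, weight)


_FIXTURE_RESOURCE = "adherence_network.tsv"


def load_adherence_fixture() -> LogicNetwork:
    """The packaged 18-node / 43-edge endocrine-therapy adherence circuit.

    Four demographic/clinical context factors (age, education, household
    income, tumor stage) are inputs; the remaining fourteen behavioral
    factors are dynamic.  Eight nodes — trust in physician, treatment
    cost worry, health literacy, quality of life, coping deficit,
    general anxiety, cancer recurrence worry, and behavioral routines —
    are flagged as clinically actionable intervention targets.  The edge
    list is a synthetic transcription assembled from the study
    constructs and the qualitative findings (see the fixture file for
    the per-edge rationale); it is structurally faithful (node/edge/
    target counts) rather than a copy of an unpublished wiring diagram.
    """
    resource = importlib.resources.files("adherelogic").joinpath(
        "data", _FIXTURE_RESOURCE
    )
    with importlib.resources.as_file(resource) as path:
        net, _ = read_network_file(path)
    return net
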