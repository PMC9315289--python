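import numpy as np
import pytest

from adherelogic.network import (
    Edge,
    LogicNetwork,
    NodeSpec,
    ParameterSet,
    default_parameters,
    load_adherence_fixture,
)


@pytest.fixture(scope="session")
def fixture_net():
    return load_adherence_fixture()


@pytest.fixture
def self_activator():
    """One ternary node activating itself (theta=1): levels 0 and 2 are
    fixed points, level 1 climbs to 2."""
    net = LogicNetwork(
        [NodeSpec("a", "dynamic", 3)],
        [Edge("a", "a", "activate")],
        adherence_node="a",
    )
    return net, default_parameters(net)


@pytest.fixture
def chain3():
    """source -> mediator -> adherence activation chain, all ternary."""
    net = LogicNetwork(
        [
            NodeSpec("source", "dynamic", 3, targetable=True),
            NodeSpec("mediator", "dynamic", 3, targetable=True),
            NodeSpec("adherence", "dynamic", 3),
        ],
        [
            Edge("source", "source", "activate"),
            Edge("source", "mediator", "activate"),
            Edge("mediator", "adherence", "activate"),
        ],
        adherence_node="adherence",
    )
    return net, default_parameters(net)


@pytest.fixture
def two_node_net():
    net = LogicNetwork(
        [NodeSpec("a", "dynamic", 3), NodeSpec("b", "dynamic", 3)],
        [Edge("a", "b", "activate")],
        adherence_node="b",
    )
    return net, default_parameters(net)


def make_params(net, mapping=None):
    """ParameterSet from a {(source, target): (theta, w)} mapping, with
    (1, 1) defaults elsewhere."""
    params = default_parameters(net)
    if mapping:
        params = params.replace(net, mapping)
    return params


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
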