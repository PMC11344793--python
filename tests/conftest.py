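import numpy as np
import pytest

from assemblnet.clustering import AssemblyNetwork, Node
from assemblnet.io_model import DistanceMatrix, GenusPathwayProfile


def make_network(taxa_sets, edges=(), environment="env", seed=0):
    """Build a minimal AssemblyNetwork whose nodes carry the given taxa sets
    (presence/probability vectors are irrelevant for combining)."""
    net = AssemblyNetwork(environment, seed, ["s0"])
    ids = {}
    for t, taxa in enumerate(taxa_sets):
        key = frozenset(taxa)
        net.nodes[t] = Node(t, key, np.array([1], dtype=np.uint8), np.array([0.5]))
        ids[key] = t
    for parent, child in edges:
        net.edges.append((ids[frozenset(parent)], ids[frozenset(child)]))
    return net


@pytest.fixture
def simple_profiles():
    return {
        "A": GenusPathwayProfile("A", frozenset({"p1", "p2", "p3"})),
        "B": GenusPathwayProfile("B", frozenset({"p2", "p3", "p4"})),
        "C": GenusPathwayProfile("C", frozenset({"p1", "p2", "p3"})),
    }


@pytest.fixture
def simple_distances():
    D = np.array([[0.0, 0.3, 0.2], [0.3, 0.0, 0.4], [0.2, 0.4, 0.0]])
    return DistanceMatrix(["A", "B", "C"], D)
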