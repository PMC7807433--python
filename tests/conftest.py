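import numpy as np
import pytest

from coobnet.datatypes import AssociationNetwork, Edge, OTUTable


def make_network(edge_specs, name=""):
    """Build a network from (a, b, sign[, score]) tuples."""
    edges = []
    for spec in edge_specs:
        a, b, sign = spec[:3]
        score = spec[3] if len(spec) > 3 else 0.5
        edges.append(Edge(a, b, sign, score, 0.01, 0.01))
    return AssociationNetwork(edges=edges, name=name)


@pytest.fixture
def net_factory():
    return make_network


@pytest.fixture
def small_table():
    rng = np.random.default_rng(7)
    counts = rng.integers(0, 50, size=(8, 10))
    counts[0] += 20  # keep one row dense
    return OTUTable(
        counts,
        [f"OTU{i}" for i in range(8)],
        [f"S{j}" for j in range(10)],
        ["k__Bacteria; p__Firmicutes"] * 8,
    )
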