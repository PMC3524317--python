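from __future__ import annotations

import networkx as nx
import pytest
from hypothesis import HealthCheck, settings

from cliquesig.network_build import AnnotatedNetwork
from cliquesig.synthetic_data import generate_suite

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def net_from_edges(edges, nodes=()) -> AnnotatedNetwork:
    """Build an AnnotatedNetwork directly from an edge list (tests only)."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    for a, b in g.edges:
        g.edges[a, b].setdefault("pcc", 1.0)
    for v in g.nodes:
        g.nodes[v]["isolated"] = g.degree(v) == 0
    return AnnotatedNetwork(graph=g)


@pytest.fixture(scope="session")
def small_suite():
    """Two-population suite: 2 shared + 1 unique clique each, 120 genes."""
    return generate_suite(
        n_populations=2,
        n_genes=120,
        n_samples_per_group=8,
        n_shared_cliques=2,
        n_unique_cliques=1,
        seed=7,
    )


@pytest.fixture(scope="session")
def path_net():
    """The 3-node path a-b-c, the smallest graph with distinct centralities."""
    return net_from_edges([("a", "b"), ("b", "c")])
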