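"""Population network construction: DE genes ∩ PPI, co-expression edge filter.

Nodes are the differentially expressed genes that appear in the interaction
map. A candidate PPI edge survives only when the Pearson correlation of the
two genes' expression profiles — computed over all samples, disease and
control pooled — is strictly above the cutoff in absolute value (default
|r| > 0.6). Isolated nodes are retained (they still count for node-similarity
censuses) but flagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from cliquesig.io_formats import EdgeList, ExpressionMatrix, canonical_pair


@dataclass
class AnnotatedNetwork:
    """Undirected simple graph whose nodes/edges carry strength annotations.

    Edge attributes: ``pcc`` always; ``go_distance``, ``pathway_similarity``
    and ``edge_strength`` after edge scoring. Node attributes: ``isolated``
    always; centrality scores and ``node_strength`` after node scoring.
    """

    graph: nx.Graph
    population: str = ""

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {canonical_pair(a, b) for a, b in self.graph.edges}

    def node_strengths(self) -> dict[str, float]:
        return nx.get_node_attributes(self.graph, "node_strength")

    def edge_strengths(self) -> dict[tuple[str, str], float]:
        return {
            canonical_pair(a, b): d["edge_strength"]
            for a, b, d in self.graph.edges(data=True)
            if "edge_strength" in d
        }


def pearson_correlation(x, y) -> float:
    """Pearson r of two expression vectors over all samples.

    Raises ``ValueError`` for length < 3, unequal lengths, or a constant
    vector (undefined correlation; the candidate edge is dropped upstream).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples for a meaningful correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0.0:
        raise ValueError("constant vector: correlation undefined")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def build_network(
    de_genes: list[str],
    ppi: EdgeList,
    expr: ExpressionMatrix,
    pcc_cut: float = 0.6,
    population: str = "",
) -> AnnotatedNetwork:
    """Restrict the PPI map to DE genes and keep edges with |r| > pcc_cut."""
    missing = [g for g in de_genes if g not in expr.values.index]
    if missing:
        raise ValueError(f"DE genes absent from expression matrix: {missing[:5]}")
    if not 0.0 <= pcc_cut < 1.0:
        raise ValueError(f"pcc_cut must be in [0, 1): {pcc_cut}")
    ppi_nodes = ppi.nodes
    nodes = sorted(g for g in set(de_genes) if g in ppi_nodes)
    if not nodes:
        raise ValueError("no DE gene appears in the interaction map")
    node_set = set(nodes)

    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for a, b in sorted(ppi.pairs):
        if a not in node_set or b not in node_set:
            continue
        try:
            r = pearson_correlation(expr.gene_vector(a), expr.gene_vector(b))
        except ValueError:
            continue  # constant gene: correlation undefined, edge dropped
        if abs(r) > pcc_cut:
            graph.add_edge(a, b, pcc=r)
    for node in graph.nodes:
        graph.nodes[node]["isolated"] = graph.degree(node) == 0
    return AnnotatedNetwork(graph=graph, population=population)


@dataclass
class NetworkSummary:
    n_nodes: int
    n_interactions: int
    mean_degree: float
    diameter: float
    avg_path_length: float
    n_components: int
    largest_component_size: int
    flags: list[str] = field(default_factory=list)


def network_summary(net: AnnotatedNetwork) -> NetworkSummary:
    """Interaction count, mean degree, and largest-component path statistics.

    The networks are typically disconnected, so diameter and average path
    length (over unordered reachable pairs) are computed on the largest
    connected component. An edgeless network reports both as 0, flagged.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    flags: list[str] = []
    n, m = g.number_of_nodes(), g.number_of_edges()
    components = sorted(nx.connected_components(g), key=lambda c: (-len(c), sorted(c)))
    largest = g.subgraph(components[0])
    if len(components) > 1:
        flags.append("disconnected: path statistics on largest component")
    if m == 0:
        flags.append("edgeless: diameter undefined, reported as 0")
        diameter, avg_path = 0.0, 0.0
    else:
        diameter = float(nx.diameter(largest))
        avg_path = float(nx.average_shortest_path_length(largest))
    return NetworkSummary(
        n_nodes=n,
        n_interactions=m,
        mean_degree=2.0 * m / n,
        diameter=diameter,
        avg_path_length=avg_path,
        n_components=len(components),
        largest_component_size=len(components[0]),
        flags=flags,
    )


def node_similarity(nets: dict[str, AnnotatedNetwork]) -> dict:
    """Pairwise common-node counts across population networks (Table-1 style)."""
    if len(nets) < 2:
        raise ValueError("need at least 2 population networks")
    sizes = {pop: len(net.nodes) for pop, net in nets.items()}
    common: dict[tuple[str, str], int] = {}
    pops = sorted(nets)
    for i, a in enumerate(pops):
        for b in pops[i + 1 :]:
            common[(a, b)] = len(nets[a].nodes & nets[b].nodes)
    return {"sizes": sizes, "common": common}
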