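"""Topological node scoring: degree, eccentricity, closeness, betweenness.

All shortest paths are unweighted hop counts. The eccentricity score of a node
is the reciprocal of its greatest distance to any reachable node; the
closeness score is the reciprocal of the sum of distances within its
component. Betweenness is the unnormalized pair-dependency sum over unordered
source–target pairs, endpoints excluded. NodeStrength averages the four
features after min–max normalization across the network; when a feature is
constant across all nodes, every node attains the maximum and receives 1.0.
Isolated nodes score 0 on all three distance-based features.
"""

from __future__ import annotations

import networkx as nx
import numpy as np

from cliquesig.network_build import AnnotatedNetwork


def eccentricity_score(net: AnnotatedNetwork, v: str) -> float:
    """1 / max distance from v to any reachable node; 0 for isolated nodes."""
    g = net.graph
    lengths = nx.single_source_shortest_path_length(g, v)
    ecc = max(lengths.values())  # 0 when v is isolated
    return 1.0 / ecc if ecc > 0 else 0.0


def closeness_score(net: AnnotatedNetwork, v: str) -> float:
    """1 / sum of distances from v over its component; 0 for isolated nodes."""
    lengths = nx.single_source_shortest_path_length(net.graph, v)
    total = sum(lengths.values())
    return 1.0 / total if total > 0 else 0.0


def betweenness_score(net: AnnotatedNetwork, v: str) -> float:
    """Unnormalized shortest-path betweenness of v over unordered pairs."""
    return betweenness_all(net)[v]


def betweenness_all(net: AnnotatedNetwork) -> dict[str, float]:
    # Brandes accumulation; for undirected graphs networkx already counts each
    # unordered (s, t) pair once when normalized=False.
    return nx.betweenness_centrality(net.graph, normalized=False)


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones_like(values)  # constant feature: all nodes attain the max
    return (values - lo) / (hi - lo)


def node_strength(net: AnnotatedNetwork) -> dict[str, dict[str, float]]:
    """Score every node and store results as node attributes on the graph.

    Returns per node: raw ``degree``, ``eccentricity_score``,
    ``closeness_score``, ``betweenness``, their normalized counterparts, and
    ``node_strength`` = mean of the four normalized features, in [0, 1].
    """
    g = net.graph
    nodes = sorted(g.nodes)
    if not nodes:
        raise ValueError("empty network")
    degree = np.array([g.degree(v) for v in nodes], dtype=float)
    ecc = np.array([eccentricity_score(net, v) for v in nodes])
    clo = np.array([closeness_score(net, v) for v in nodes])
    btw_map = betweenness_all(net)
    btw = np.array([btw_map[v] for v in nodes])

    normed = {
        "degree": _minmax(degree),
        "eccentricity_score": _minmax(ecc),
        "closeness_score": _minmax(clo),
        "betweenness": _minmax(btw),
    }
    strength = (
        normed["degree"]
        + normed["eccentricity_score"]
        + normed["closeness_score"]
        + normed["betweenness"]
    ) / 4.0

    out: dict[str, dict[str, float]] = {}
    for i, v in enumerate(nodes):
        scores = {
            "degree": float(degree[i]),
            "eccentricity_score": float(ecc[i]),
            "closeness_score": float(clo[i]),
            "betweenness": float(btw[i]),
            "degree_norm": float(normed["degree"][i]),
            "eccentricity_norm": float(normed["eccentricity_score"][i]),
            "closeness_norm": float(normed["closeness_score"][i]),
            "betweenness_norm": float(normed["betweenness"][i]),
            "node_strength": float(strength[i]),
        }
        g.nodes[v].update(scores)
        out[v] = scores
    return out
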