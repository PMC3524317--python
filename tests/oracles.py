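"""Independent brute-force oracles used across the test suite.

These deliberately avoid the library code paths they check: centralities come
from a dense all-pairs-shortest-path matrix plus layer-by-layer path counting,
clique enumeration from exhaustive vertex-subset scanning, and the
hypergeometric tail from enumerating every possible draw.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path


def apsp_matrix(adj: np.ndarray) -> np.ndarray:
    """Unweighted all-pairs shortest-path distances (inf when unreachable)."""
    return shortest_path(csr_matrix(adj), method="D", unweighted=True)


def shortest_path_counts(adj: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """S[s, t] = number of distinct shortest s-t paths, by BFS-layer DP."""
    n = adj.shape[0]
    S = np.zeros((n, n))
    for s in range(n):
        S[s, s] = 1.0
        d = dist[s]
        finite = d[np.isfinite(d)]
        for level in range(1, int(finite.max()) + 1 if finite.size else 1):
            layer = d == level
            prev = (d == level - 1).astype(float) * S[s]
            S[s, layer] = prev @ adj[:, layer]
    return S


def centrality_oracle(adj: np.ndarray) -> dict[str, np.ndarray]:
    """Eccentricity score, closeness score, and betweenness for every node."""
    n = adj.shape[0]
    D = apsp_matrix(adj)
    S = shortest_path_counts(adj, D)
    off = ~np.eye(n, dtype=bool)
    ecc = np.zeros(n)
    clo = np.zeros(n)
    for v in range(n):
        d = D[v][off[v]]
        reach = d[np.isfinite(d)]
        if reach.size:
            ecc[v] = 1.0 / reach.max()
            clo[v] = 1.0 / reach.sum()
    btw = np.zeros(n)
    for v in range(n):
        on_path = np.isfinite(D) & (D[:, v][:, None] + D[v][None, :] == D)
        valid = on_path & off & (S > 0)
        valid[v, :] = False
        valid[:, v] = False
        numer = S[:, v][:, None] * S[v][None, :]
        contrib = np.where(valid, numer / np.where(S > 0, S, 1.0), 0.0)
        btw[v] = contrib.sum() / 2.0  # ordered pairs counted twice
    return {"eccentricity": ecc, "closeness": clo, "betweenness": btw}


def brute_force_cliques(adj: np.ndarray, k: int) -> set[tuple[int, ...]]:
    """All size-k vertex subsets inducing a complete subgraph."""
    n = adj.shape[0]
    out = set()
    for subset in combinations(range(n), k):
        if all(adj[a, b] for a, b in combinations(subset, 2)):
            out.add(subset)
    return out


def hypergeom_tail_by_enumeration(x: int, gg: int, g: int, G: int) -> float:
    """P(draw of gg from G contains >= x of the g marked items), enumerated."""
    hits = sum(
        1
        for draw in combinations(range(G), gg)
        if sum(1 for i in draw if i < g) >= x
    )
    return hits / comb(G, gg)


def random_graph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Symmetric 0/1 adjacency matrix of a G(n, p) graph."""
    upper = rng.random((n, n)) < p
    adj = np.triu(upper, 1)
    return (adj | adj.T).astype(float)
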