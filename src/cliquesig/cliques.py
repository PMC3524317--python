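"""k-clique enumeration and CliqueStrength scoring.

Every clique of each size k in [3, M] (default M = 7) is enumerated, not only
maximal ones: the census counts cliques per size independently and the
downstream profile walk works on fixed-size cliques. Enumeration grows
triangles into larger cliques by intersecting the common neighborhoods of all
members, extending only with nodes ordered after the current last member so
each clique is produced exactly once, canonicalized as a sorted gene tuple.

CliqueStrength of a clique is the sum of its members' NodeStrengths plus the
sum of the EdgeStrengths of its C(k, 2) internal edges, so a k-clique scores
at most k + k(k-1)/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from cliquesig.network_build import AnnotatedNetwork


@dataclass(frozen=True, order=True)
class Clique:
    """A fully connected gene set; identity is the sorted gene tuple."""

    genes: tuple[str, ...]
    strength: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        if tuple(sorted(self.genes)) != self.genes:
            raise ValueError("clique genes must be stored sorted")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene in clique")

    @property
    def size(self) -> int:
        return len(self.genes)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)

    def overlap(self, other: "Clique") -> int:
        return len(self.gene_set & other.gene_set)


def enumerate_cliques(
    net: AnnotatedNetwork,
    k_min: int = 3,
    k_max: int = 7,
    max_per_size: int = 10**6,
) -> dict[int, list[Clique]]:
    """All cliques of each size in [k_min, k_max], sorted lexicographically.

    ``max_per_size`` aborts with an error on pathologically dense graphs.
    """
    if k_min < 3:
        raise ValueError("smallest clique size is 3")
    if k_max < k_min:
        raise ValueError("k_max must be >= k_min")
    g = net.graph
    adj = {v: set(g.neighbors(v)) for v in g.nodes}

    # seed with triangles (a < b < c), then extend with common neighbors > last
    current: list[tuple[str, ...]] = []
    for a in sorted(adj):
        for b in sorted(n for n in adj[a] if n > a):
            for c in sorted(n for n in (adj[a] & adj[b]) if n > b):
                current.append((a, b, c))
    out: dict[int, list[Clique]] = {k: [] for k in range(k_min, k_max + 1)}
    size = 3
    while current and size <= k_max:
        if len(current) > max_per_size:
            raise RuntimeError(
                f"more than {max_per_size} cliques of size {size}; graph too dense"
            )
        if size >= k_min:
            out[size] = [Clique(genes=t) for t in current]
        if size == k_max:
            break
        nxt: list[tuple[str, ...]] = []
        for members in current:
            common = set.intersection(*(adj[v] for v in members))
            last = members[-1]
            for w in sorted(n for n in common if n > last):
                nxt.append(members + (w,))
        current = nxt
        size += 1
    return out


def clique_strength(clique: Clique, net: AnnotatedNetwork) -> float:
    """Sum of member NodeStrengths plus internal EdgeStrengths."""
    g = net.graph
    total = 0.0
    for v in clique.genes:
        if "node_strength" not in g.nodes[v]:
            raise KeyError(f"node {v!r} has no node_strength; score the network first")
        total += g.nodes[v]["node_strength"]
    for a, b in combinations(clique.genes, 2):
        if not g.has_edge(a, b):
            raise KeyError(f"{a!r}-{b!r} is not an edge; not a clique of this network")
        if "edge_strength" not in g.edges[a, b]:
            raise KeyError(f"edge {a!r}-{b!r} has no edge_strength; score edges first")
        total += g.edges[a, b]["edge_strength"]
    return total


def score_cliques(
    cliques: dict[int, list[Clique]], net: AnnotatedNetwork
) -> dict[int, list[Clique]]:
    """Attach CliqueStrength to every enumerated clique."""
    return {
        k: [Clique(genes=c.genes, strength=clique_strength(c, net)) for c in cs]
        for k, cs in cliques.items()
    }


def clique_census(clique_sets: dict[str, dict[int, list[Clique]]]) -> dict:
    """Per-size clique counts per population, plus pooled distinct counts."""
    per_population: dict[str, dict[int, int]] = {
        pop: {k: len(cs) for k, cs in by_size.items()}
        for pop, by_size in clique_sets.items()
    }
    sizes = sorted({k for by_size in clique_sets.values() for k in by_size})
    pooled_unique = {
        k: len(
            {
                c.gene_set
                for by_size in clique_sets.values()
                for c in by_size.get(k, [])
            }
        )
        for k in sizes
    }
    return {"per_population": per_population, "pooled_unique": pooled_unique}
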