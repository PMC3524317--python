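"""Clique Connectivity Profiles: greedy clique chains and divergence points.

A profile starts from a seed clique — the strongest clique of a given size
whose gene set forms a clique in every population — and repeatedly appends
the "closest" unvisited clique sharing at least one gene with the current
chain tail. Two linking modes:

* ``max`` (MaxCliques): largest overlap nn first, then highest CliqueStrength;
* ``min`` (MinCliques): smallest overlap first, subject to nn <= nn_cap
  (default 4), then highest CliqueStrength.

Remaining ties are broken by lexicographic gene set, so the walk is fully
deterministic. The per-link CliqueConnectivityScore is the mean of the two
member strengths. Divergence between populations' profiles from a shared seed
is the first chain position where the gene sets differ.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from cliquesig.cliques import Clique

MODE_MAX = "max"
MODE_MIN = "min"


@dataclass
class CCProfile:
    population: str
    mode: str
    chain: list[Clique]
    link_scores: list[float] = field(default_factory=list)
    link_overlaps: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        assert len(self.link_scores) == max(len(self.chain) - 1, 0)
        assert len(self.link_overlaps) == len(self.link_scores)

    @property
    def gene_sets(self) -> list[frozenset[str]]:
        return [c.gene_set for c in self.chain]

    @property
    def genes(self) -> set[str]:
        return {g for c in self.chain for g in c.genes}


def select_seed(clique_sets: dict[str, list[Clique]], size: int = 7) -> Clique:
    """The common clique of the given size maximizing summed strength.

    Candidates are gene sets present as cliques in every population;
    ties break lexicographically. Raises ``ValueError`` when no clique is
    common to all populations.
    """
    if not clique_sets:
        raise ValueError("no populations given")
    by_pop: dict[str, dict[frozenset[str], Clique]] = {}
    for pop, cliques in clique_sets.items():
        by_pop[pop] = {c.gene_set: c for c in cliques if c.size == size}
        if not by_pop[pop]:
            raise ValueError(f"population {pop!r} has no clique of size {size}")
    common = set.intersection(*(set(d) for d in by_pop.values()))
    if not common:
        raise ValueError(f"no size-{size} clique common to all populations")
    # highest summed strength; ties broken by lexicographically smallest set
    best = min(
        common,
        key=lambda gs: (
            -sum(by_pop[pop][gs].strength for pop in by_pop),
            tuple(sorted(gs)),
        ),
    )
    # return the candidate with genes in canonical order, strength = summed
    return Clique(
        genes=tuple(sorted(best)),
        strength=sum(by_pop[pop][best].strength for pop in by_pop),
    )


def clique_connectivity_score(c_i: Clique, c_j: Clique) -> float:
    """Mean of the two cliques' strengths (symmetric pairwise link score)."""
    return (c_i.strength + c_j.strength) / 2.0


def extend_profile(
    cliques: list[Clique],
    seed: Clique,
    mode: str = MODE_MAX,
    nn_cap: int = 4,
    population: str = "",
) -> CCProfile:
    """Greedy clique walk from the seed under the max or min linking rule.

    The candidate pool at each step is the set of unvisited cliques sharing
    >= 1 gene with the current chain tail; the walk stops when it is empty.
    """
    if mode not in (MODE_MAX, MODE_MIN):
        raise ValueError(f"unknown mode {mode!r}")
    pool = {c.gene_set: c for c in cliques}
    if seed.gene_set not in pool:
        raise ValueError("seed clique is not among this population's cliques")
    current = pool[seed.gene_set]
    chain = [current]
    visited = {current.gene_set}
    link_scores: list[float] = []
    link_overlaps: list[int] = []
    while True:
        candidates = [
            c
            for gs, c in pool.items()
            if gs not in visited and current.overlap(c) >= 1
        ]
        if mode == MODE_MIN:
            candidates = [c for c in candidates if current.overlap(c) <= nn_cap]
        if not candidates:
            break
        nn_sign = -1 if mode == MODE_MAX else 1
        nxt = min(
            candidates,
            key=lambda c: (nn_sign * current.overlap(c), -c.strength, c.genes),
        )
        link_overlaps.append(current.overlap(nxt))
        link_scores.append(clique_connectivity_score(current, nxt))
        visited.add(nxt.gene_set)
        chain.append(nxt)
        current = nxt
    return CCProfile(
        population=population,
        mode=mode,
        chain=chain,
        link_scores=link_scores,
        link_overlaps=link_overlaps,
    )


def divergence_points(profiles: list[CCProfile]) -> dict[tuple[str, str], int | None]:
    """First chain position at which each pair of profiles differs.

    All profiles must share chain[0] (the seed). A pair of identical chains
    maps to ``None`` ("no divergence"); chains of unequal length that agree on
    the shorter prefix diverge where the shorter one ends. Position 1 means
    the profiles part immediately after the seed.
    """
    if not profiles:
        raise ValueError("no profiles given")
    seed_sets = {p.chain[0].gene_set for p in profiles}
    if len(seed_sets) != 1:
        raise ValueError("profiles do not share a seed")
    out: dict[tuple[str, str], int | None] = {}
    for i, p in enumerate(profiles):
        for q in profiles[i + 1 :]:
            out[(p.population, q.population)] = _first_mismatch(p, q)
    return out


def _first_mismatch(p: CCProfile, q: CCProfile) -> int | None:
    a, b = p.gene_sets, q.gene_sets
    for pos in range(min(len(a), len(b))):
        if a[pos] != b[pos]:
            return pos
    if len(a) != len(b):
        return min(len(a), len(b))
    return None
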