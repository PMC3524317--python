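"""Cross-population clique comparison: common, partial, unique; gene censuses.

Cliques are matched across populations by exact gene-set identity (the
Venn-style counts require exact matching). Populations are arbitrary labels;
any number >= 2 is supported.
"""

from __future__ import annotations

from dataclasses import dataclass

from cliquesig.cliques import Clique
from cliquesig.io_formats import AnnotationMap


@dataclass
class PopulationComparison:
    """Membership of each distinct clique gene set across populations."""

    populations: list[str]
    size: int
    counts: dict[str, int]  # cliques of this size per population
    membership: dict[frozenset[str], frozenset[str]]  # gene set -> populations

    @property
    def common(self) -> set[frozenset[str]]:
        """Cliques present in every population."""
        all_pops = frozenset(self.populations)
        return {gs for gs, pops in self.membership.items() if pops == all_pops}

    @property
    def unique(self) -> dict[str, set[frozenset[str]]]:
        """Cliques present in exactly one population, keyed by population."""
        out: dict[str, set[frozenset[str]]] = {p: set() for p in self.populations}
        for gs, pops in self.membership.items():
            if len(pops) == 1:
                out[next(iter(pops))].add(gs)
        return out

    @property
    def partial(self) -> set[frozenset[str]]:
        """Cliques shared by more than one but not all populations."""
        n = len(self.populations)
        return {gs for gs, pops in self.membership.items() if 1 < len(pops) < n}

    @property
    def pooled_distinct(self) -> int:
        return len(self.membership)


def compare_cliques(
    clique_sets: dict[str, list[Clique]], size: int
) -> PopulationComparison:
    """Partition the pooled distinct cliques of one size by population membership."""
    if len(clique_sets) < 2:
        raise ValueError("need at least 2 populations to compare")
    populations = sorted(clique_sets)
    membership: dict[frozenset[str], set[str]] = {}
    counts: dict[str, int] = {}
    for pop in populations:
        sized = [c for c in clique_sets[pop] if c.size == size]
        counts[pop] = len(sized)
        for c in sized:
            membership.setdefault(c.gene_set, set()).add(pop)
    return PopulationComparison(
        populations=populations,
        size=size,
        counts=counts,
        membership={gs: frozenset(pops) for gs, pops in membership.items()},
    )


def clique_gene_summary(clique_sets: dict[str, list[Clique]]) -> dict:
    """Union of clique genes per population, their intersection, pooled union."""
    per_pop = {
        pop: {g for c in cliques for g in c.genes}
        for pop, cliques in clique_sets.items()
    }
    gene_sets = list(per_pop.values())
    return {
        "per_population": {pop: sorted(genes) for pop, genes in per_pop.items()},
        "per_population_counts": {pop: len(genes) for pop, genes in per_pop.items()},
        "common": sorted(set.intersection(*gene_sets)) if gene_sets else [],
        "pooled": sorted(set.union(*gene_sets)) if gene_sets else [],
    }


def pathway_association_counts(
    clique_sets: dict[str, list[Clique]], pathways: AnnotationMap
) -> dict[str, dict[str, int]]:
    """Per pathway, the number of clique genes annotated to it per population."""
    out: dict[str, dict[str, int]] = {}
    for pathway in sorted(pathways.all_terms()):
        row: dict[str, int] = {}
        for pop, cliques in clique_sets.items():
            clique_genes = {g for c in cliques for g in c.genes}
            row[pop] = sum(1 for g in clique_genes if pathway in pathways.terms_for(g))
        out[pathway] = row
    return out
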