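"""Multi-population synthetic fixtures with fully known ground truth.

The generator emulates the structure of a cross-population colorectal-cancer
style study: per population a normalized two-group (disease/control)
expression matrix, one shared protein-interaction map, and flat GO/pathway
annotations. Planted cliques are complete subgraphs of the interaction map
whose member genes are up-regulated in disease (shift ``effect_sd``) and share
a per-sample latent factor, so they pass both the t-test/FDR filter and the
|PCC| co-expression filter by construction. Shared cliques are planted in
every population; unique cliques receive their expression signal (shift and
factor) in exactly one population, so elsewhere their genes fail the
differential-expression filter and the clique does not form.

Expression model per gene and sample:

    value = baseline_g + effect_sd * 1[disease & planted-DE-in-population]
            + clique_factor_sd * f(clique, sample) + N(0, noise_sd)

Background interaction edges never join two planted genes of different
cliques, so the disease shift common to all planted genes cannot create
spurious cliques; background genes carry no group effect and are pruned at
the differential-expression stage.

All randomness flows from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from cliquesig.cliques import Clique
from cliquesig.io_formats import (
    CONTROL,
    DISEASE,
    AnnotationMap,
    EdgeList,
    ExpressionMatrix,
    canonical_pair,
    write_edge_list,
    write_expression,
    write_gene_sets,
    write_json,
)


@dataclass
class SyntheticSuite:
    """A generated study: inputs in pipeline formats plus serialized truth.

    ``expression``/``ppi``/annotations are populated by :func:`generate_suite`;
    :func:`generate_ccp_fixture` instead fills ``clique_sets`` (scored cliques
    per population, the inputs of the profile walk) and a PPI map consistent
    with them.
    """

    ground_truth: dict
    seed: int
    expression: dict[str, ExpressionMatrix] = field(default_factory=dict)
    ppi: EdgeList | None = None
    go_annotations: AnnotationMap | None = None
    pathway_annotations: AnnotationMap | None = None
    clique_sets: dict[str, list[Clique]] = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        for pop, expr in self.expression.items():
            e, l = out_dir / f"expr_{pop}.tsv", out_dir / f"labels_{pop}.tsv"
            write_expression(expr, e, l)
            written += [e, l]
        if self.ppi is not None:
            write_edge_list(self.ppi, out_dir / "ppi.tsv")
            written.append(out_dir / "ppi.tsv")
        if self.go_annotations is not None:
            write_gene_sets(self.go_annotations, out_dir / "go.tsv")
            written.append(out_dir / "go.tsv")
        if self.pathway_annotations is not None:
            write_gene_sets(self.pathway_annotations, out_dir / "pathways.tsv")
            written.append(out_dir / "pathways.tsv")
        written.append(write_json(self.ground_truth, out_dir / "ground_truth.json"))
        return written


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(n)]


def generate_suite(
    n_populations: int = 4,
    n_genes: int = 500,
    n_samples_per_group: int = 10,
    n_shared_cliques: int = 5,
    n_unique_cliques: int = 2,
    clique_size: int = 7,
    effect_sd: float = 5.0,
    noise_sd: float = 0.5,
    clique_factor_sd: float = 1.0,
    seed: int = 0,
    n_background_terms: int = 40,
    n_background_pathways: int = 15,
) -> SyntheticSuite:
    """Generate a multi-population study with planted cliques and annotations.

    Defaults describe a comfortable recovery regime: a 5-unit disease shift on
    log2-like data with residual noise 0.5 and a unit within-clique latent
    factor puts every planted gene far past the p < 0.05 / q < 0.1 filter and
    every within-clique pair far past |r| > 0.6 (pooled population r ≈ 0.97).
    """
    if clique_size < 3:
        raise ValueError("clique_size must be >= 3")
    if n_samples_per_group < 5:
        raise ValueError("need at least 5 samples per group")
    n_planted_cliques = n_shared_cliques + n_populations * n_unique_cliques
    n_planted_genes = n_planted_cliques * clique_size
    if n_planted_genes > n_genes:
        raise ValueError(
            f"{n_planted_genes} planted genes exceed n_genes={n_genes}"
        )
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_genes)
    populations = [f"pop{i + 1}" for i in range(n_populations)]

    # allocate disjoint gene blocks to planted cliques
    cursor = 0
    shared_cliques: list[tuple[str, ...]] = []
    for _ in range(n_shared_cliques):
        shared_cliques.append(tuple(genes[cursor : cursor + clique_size]))
        cursor += clique_size
    unique_cliques: dict[str, list[tuple[str, ...]]] = {}
    for pop in populations:
        unique_cliques[pop] = []
        for _ in range(n_unique_cliques):
            unique_cliques[pop].append(tuple(genes[cursor : cursor + clique_size]))
            cursor += clique_size
    planted_genes = set(genes[:cursor])
    background_genes = genes[cursor:]

    # shared PPI: planted clique edges plus random background edges that never
    # join two planted genes (one endpoint must be background)
    pairs: set[tuple[str, str]] = set()
    all_planted = shared_cliques + [c for cs in unique_cliques.values() for c in cs]
    for clique in all_planted:
        for a, b in combinations(clique, 2):
            pairs.add(canonical_pair(a, b))
    n_background_edges = 3 * n_genes
    attempts = 0
    while len(pairs) < n_background_edges + len(all_planted) * clique_size * (
        clique_size - 1
    ) // 2 and attempts < 50 * n_background_edges:
        attempts += 1
        a = genes[rng.integers(n_genes)]
        b = background_genes[rng.integers(len(background_genes))]
        if a != b:
            pairs.add(canonical_pair(a, b))
    ppi = EdgeList(pairs=frozenset(pairs))

    # expression matrices
    baseline = rng.normal(8.0, 1.0, size=n_genes)
    expression: dict[str, ExpressionMatrix] = {}
    n_samples = 2 * n_samples_per_group
    for pop in populations:
        sample_ids = [f"{pop}_s{j + 1}" for j in range(n_samples)]
        labels = {
            s: DISEASE if j < n_samples_per_group else CONTROL
            for j, s in enumerate(sample_ids)
        }
        active = shared_cliques + unique_cliques[pop]
        de_genes = {g for c in active for g in c}
        values = np.tile(baseline[:, None], (1, n_samples))
        values = values + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
        gene_idx = {g: i for i, g in enumerate(genes)}
        disease_cols = np.arange(n_samples_per_group)
        for g in de_genes:
            values[gene_idx[g], disease_cols] += effect_sd
        for clique in active:
            factor = rng.normal(0.0, 1.0, size=n_samples)
            for g in clique:
                values[gene_idx[g]] += clique_factor_sd * factor
        df = pd.DataFrame(values, index=genes, columns=sample_ids)
        expression[pop] = ExpressionMatrix(values=df, group_labels=labels)

    # annotations: one dedicated GO term and pathway per planted clique, plus
    # uniform background annotation
    go: dict[str, set[str]] = {g: set() for g in genes}
    pathways: dict[str, set[str]] = {g: set() for g in genes}
    planted_terms: dict[str, list[str]] = {}
    planted_pathways: dict[str, list[str]] = {}
    for idx, clique in enumerate(all_planted):
        term, pw = f"GO:PLANTED{idx:03d}", f"pw_planted{idx:03d}"
        for g in clique:
            go[g].add(term)
            pathways[g].add(pw)
        key = ";".join(clique)
        planted_terms[key] = [term]
        planted_pathways[key] = [pw]
    bg_terms = [f"GO:BG{i:03d}" for i in range(n_background_terms)]
    bg_pws = [f"pw_bg{i:03d}" for i in range(n_background_pathways)]
    for g in genes:
        for t in rng.choice(bg_terms, size=3, replace=False):
            go[g].add(str(t))
        for p in rng.choice(bg_pws, size=2, replace=False):
            pathways[g].add(str(p))

    ground_truth = {
        "populations": populations,
        "planted_de_genes": {
            pop: sorted(
                {g for c in shared_cliques + unique_cliques[pop] for g in c}
            )
            for pop in populations
        },
        "planted_de_direction": "up",
        "shared_cliques": [list(c) for c in shared_cliques],
        "unique_cliques": {
            pop: [list(c) for c in cs] for pop, cs in unique_cliques.items()
        },
        "planted_go_terms": planted_terms,
        "planted_pathways": planted_pathways,
        "background_genes": sorted(background_genes),
        "parameters": {
            "n_populations": n_populations,
            "n_genes": n_genes,
            "n_samples_per_group": n_samples_per_group,
            "n_shared_cliques": n_shared_cliques,
            "n_unique_cliques": n_unique_cliques,
            "clique_size": clique_size,
            "effect_sd": effect_sd,
            "noise_sd": noise_sd,
            "clique_factor_sd": clique_factor_sd,
        },
    }
    return SyntheticSuite(
        ground_truth=ground_truth,
        seed=seed,
        expression=expression,
        ppi=ppi,
        go_annotations=AnnotationMap(
            gene_to_terms={g: frozenset(t) for g, t in go.items()}, namespace="go_bp"
        ),
        pathway_annotations=AnnotationMap(
            gene_to_terms={g: frozenset(p) for g, p in pathways.items()},
            namespace="pathway",
        ),
    )


def generate_ccp_fixture(
    chain_length: int,
    overlap: int = 3,
    diverge_at: int = 0,
    n_populations: int = 3,
    seed: int = 0,
    clique_size: int = 7,
) -> SyntheticSuite:
    """Plant per-population clique chains that share a prefix then diverge.

    The fixture is built at the clique level (gene sets plus strengths — the
    exact inputs of the profile walk): every population gets the shared prefix
    cliques and its own continuation cliques, with strengths decreasing along
    the chain so the prefix head is the strongest common clique (the seed).
    Consecutive cliques share ``overlap`` genes; with overlap <= clique_size/2
    non-adjacent cliques are disjoint, so both the max and the min linking
    rule reproduce the planted chain exactly.

    ``diverge_at`` is the first chain position where populations differ; the
    seed is always shared, so 0 is treated as "immediately after the seed"
    (recorded divergence index max(diverge_at, 1)). With
    ``diverge_at >= chain_length`` the chains never diverge.
    """
    if chain_length < 1:
        raise ValueError("chain_length must be >= 1")
    if not 1 <= overlap < clique_size:
        raise ValueError("need 1 <= overlap < clique_size")
    if diverge_at < 0:
        raise ValueError("diverge_at must be >= 0")
    rng = np.random.default_rng(seed)  # reserved for future jitter; names are fixed
    populations = [f"pop{i + 1}" for i in range(n_populations)]
    prefix_len = min(max(diverge_at, 1), chain_length)
    new_per_step = clique_size - overlap

    counter = [0]

    def fresh(n: int, pool: str) -> list[str]:
        names = [f"{pool}_g{counter[0] + i:04d}" for i in range(n)]
        counter[0] += n
        return names

    def next_clique(
        prev: tuple[list[str], list[str]] | None, pool: str
    ) -> tuple[list[str], list[str]]:
        """Return (genes, fresh genes); the overlap block is carried from the
        previous clique's fresh genes so non-adjacent cliques stay disjoint
        whenever overlap <= clique_size - overlap."""
        if prev is None:
            new = fresh(clique_size, pool)
            return new, new
        prev_genes, prev_fresh = prev
        donors = prev_fresh + [g for g in prev_genes if g not in prev_fresh]
        carried = donors[:overlap]
        new = fresh(new_per_step, pool)
        return carried + new, new

    shared_chain: list[tuple[str, ...]] = []
    prev: tuple[list[str], list[str]] | None = None
    for _ in range(prefix_len):
        prev = next_clique(prev, "shared")
        shared_chain.append(tuple(sorted(prev[0])))

    shared_tail_state = prev
    chains: dict[str, list[tuple[str, ...]]] = {}
    clique_sets: dict[str, list[Clique]] = {}
    pairs: set[tuple[str, str]] = set()
    for pop in populations:
        chain = list(shared_chain)
        state = shared_tail_state
        for _ in range(chain_length - prefix_len):
            state = next_clique(state, pop)
            chain.append(tuple(sorted(state[0])))
        chains[pop] = chain
        # strengths decrease along the chain; the head is the strongest
        clique_sets[pop] = [
            Clique(genes=c, strength=float(chain_length - i))
            for i, c in enumerate(chain)
        ]
        for c in chain:
            for a, b in combinations(c, 2):
                pairs.add(canonical_pair(a, b))

    divergence_index = (
        max(diverge_at, 1) if prefix_len < chain_length and n_populations > 1 else None
    )
    ground_truth = {
        "populations": populations,
        "chains": {pop: [list(c) for c in chain] for pop, chain in chains.items()},
        "seed_clique": list(shared_chain[0]),
        "divergence_index": divergence_index,
        "parameters": {
            "chain_length": chain_length,
            "overlap": overlap,
            "diverge_at": diverge_at,
            "clique_size": clique_size,
            "n_populations": n_populations,
        },
    }
    return SyntheticSuite(
        ground_truth=ground_truth,
        seed=seed,
        ppi=EdgeList(pairs=frozenset(pairs)),
        clique_sets=clique_sets,
    )
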