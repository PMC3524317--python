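"""End-to-end orchestration: DE → network → scores → cliques → CCP → enrichment.

Every stage's product is written under the output directory and listed in a
manifest (relative paths, so identical runs give byte-identical trees). A run
log records every defaulted convention that fired (median fill for
unannotated edges, constant-feature normalization, tie-breaks), because the
method leaves several of those open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from cliquesig import ccp as ccp_mod
from cliquesig.cliques import clique_census, enumerate_cliques, score_cliques
from cliquesig.cross_population import (
    clique_gene_summary,
    compare_cliques,
    pathway_association_counts,
)
from cliquesig.differential_expression import (
    regulation_census,
    run_de,
    select_differential,
)
from cliquesig.edge_biology import edge_strength
from cliquesig.enrichment import enrich_gene_set
from cliquesig.io_formats import (
    read_edge_list,
    read_expression,
    read_gene_sets,
    write_json,
    write_network,
    write_table,
)
from cliquesig.network_build import build_network, network_summary, node_similarity
from cliquesig.node_topology import node_strength

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs and thresholds for a full multi-population run."""

    populations: dict[str, dict[str, str]]  # pop -> {"expr": path, "labels": path}
    ppi: str
    go: str
    pathways: str
    out_dir: str
    p_max: float = 0.05
    q_max: float = 0.1
    pcc_cut: float = 0.6
    k_min: int = 3
    k_max: int = 7
    nn_cap: int = 4
    alpha: float = 0.05
    test: str = "student"
    all_sizes: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.populations:
            raise ValueError("at least one population is required")
        if not 0 < self.p_max <= 1 or not 0 < self.q_max <= 1:
            raise ValueError("p_max and q_max must lie in (0, 1]")
        if not 0 <= self.pcc_cut < 1:
            raise ValueError("pcc_cut must lie in [0, 1)")
        if self.k_min < 3 or self.k_max < self.k_min:
            raise ValueError("need 3 <= k_min <= k_max")
        if self.nn_cap < 1:
            raise ValueError("nn_cap must be >= 1")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))


@dataclass
class PipelineResult:
    manifest: list[str]
    out_dir: Path
    networks: dict = field(default_factory=dict)
    clique_sets: dict = field(default_factory=dict)
    comparison: object = None
    profiles: dict = field(default_factory=dict)
    seed_clique: object = None


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path) -> None:
        written.append(path)

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("read inputs")
        ppi = read_edge_list(config.ppi)
        go = read_gene_sets(config.go, fmt="two_col", namespace="go_bp")
        pathways = read_gene_sets(config.pathways, fmt="two_col", namespace="pathway")
        expr = {
            pop: read_expression(paths["expr"], paths["labels"])
            for pop, paths in sorted(config.populations.items())
        }
    except Exception as exc:
        raise RuntimeError(f"stage 'read inputs' failed: {exc}") from exc

    networks = {}
    scored_flat = {}
    by_size_all = {}
    for pop in sorted(expr):
        try:
            stage(f"differential expression [{pop}]")
            results = run_de(expr[pop], test=config.test)
            de_genes = select_differential(results, config.p_max, config.q_max)
            up, down = regulation_census(results, config.p_max, config.q_max)
            emit(
                write_table(
                    [
                        {
                            "gene": r.gene,
                            "t_stat": r.t_stat,
                            "p_value": r.p_value,
                            "q_value": r.q_value,
                            "direction": r.direction,
                            "selected": r.gene in set(de_genes),
                        }
                        for r in results
                    ],
                    out_dir / f"de_{pop}.tsv",
                    columns=["gene", "t_stat", "p_value", "q_value", "direction", "selected"],
                )
            )
            emit(
                write_json(
                    {"up": up, "down": down, "selected": len(de_genes)},
                    out_dir / f"de_census_{pop}.json",
                )
            )

            stage(f"network construction [{pop}]")
            net = build_network(de_genes, ppi, expr[pop], config.pcc_cut, population=pop)
            node_strength(net)
            edge_strength(net, go, pathways)
            networks[pop] = net
            summary = network_summary(net)
            emit(write_json(vars(summary), out_dir / f"network_summary_{pop}.json"))
            for p in write_network(net.graph, out_dir / f"network_{pop}"):
                emit(p)

            stage(f"clique enumeration [{pop}]")
            by_size = score_cliques(
                enumerate_cliques(net, config.k_min, config.k_max), net
            )
            by_size_all[pop] = by_size
            scored_flat[pop] = [c for cs in by_size.values() for c in cs]
            emit(
                write_table(
                    [
                        {"size": c.size, "genes": ";".join(c.genes), "strength": c.strength}
                        for c in scored_flat[pop]
                    ],
                    out_dir / f"cliques_{pop}.tsv",
                    columns=["size", "genes", "strength"],
                )
            )
        except Exception as exc:
            raise RuntimeError(f"stage failed for population {pop!r}: {exc}") from exc

    try:
        stage("cross-population comparison")
        census = clique_census(by_size_all)
        emit(write_json(census, out_dir / "clique_census.json"))
        if len(networks) >= 2:
            sim = node_similarity(networks)
            emit(
                write_json(
                    {
                        "sizes": sim["sizes"],
                        "common": {f"{a}|{b}": n for (a, b), n in sim["common"].items()},
                    },
                    out_dir / "node_similarity.json",
                )
            )
        comparison = None
        if len(by_size_all) >= 2:
            comparison = compare_cliques(scored_flat, size=config.k_max)
            emit(
                write_table(
                    [
                        {
                            "genes": ";".join(sorted(gs)),
                            "populations": ";".join(sorted(pops)),
                            "n_populations": len(pops),
                        }
                        for gs, pops in comparison.membership.items()
                    ],
                    out_dir / "clique_membership.tsv",
                    columns=["genes", "populations", "n_populations"],
                )
            )
            emit(
                write_json(
                    {
                        "size": comparison.size,
                        "counts": comparison.counts,
                        "n_common": len(comparison.common),
                        "n_partial": len(comparison.partial),
                        "n_unique": {
                            pop: len(cs) for pop, cs in comparison.unique.items()
                        },
                        "pooled_distinct": comparison.pooled_distinct,
                    },
                    out_dir / "clique_comparison.json",
                )
            )
        emit(write_json(clique_gene_summary(scored_flat), out_dir / "clique_genes.json"))
        pw_counts = pathway_association_counts(scored_flat, pathways)
        emit(
            write_table(
                [
                    {"pathway": pw, **counts}
                    for pw, counts in pw_counts.items()
                    if any(counts.values())
                ],
                out_dir / "pathway_associations.tsv",
            )
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'cross-population comparison' failed: {exc}") from exc

    profiles: dict[str, dict[str, ccp_mod.CCProfile]] = {}
    seed_clique = None
    try:
        stage("clique connectivity profiles")
        sized = {
            pop: [c for c in cs if c.size == config.k_max]
            for pop, cs in scored_flat.items()
        }
        try:
            seed_clique = ccp_mod.select_seed(sized, size=config.k_max)
        except ValueError as exc:
            logger.warning("no shared seed clique: %s; skipping profiles", exc)
        if seed_clique is not None:
            pool_key = "all" if config.all_sizes else "sized"
            for mode in (ccp_mod.MODE_MAX, ccp_mod.MODE_MIN):
                profiles[mode] = {}
                for pop in sorted(sized):
                    pool = scored_flat[pop] if config.all_sizes else sized[pop]
                    profiles[mode][pop] = ccp_mod.extend_profile(
                        pool, seed_clique, mode=mode, nn_cap=config.nn_cap,
                        population=pop,
                    )
                div = ccp_mod.divergence_points(list(profiles[mode].values()))
                emit(
                    write_json(
                        {
                            "mode": mode,
                            "candidate_pool": pool_key,
                            "seed": list(seed_clique.genes),
                            "profiles": {
                                pop: {
                                    "chain": [list(c.genes) for c in prof.chain],
                                    "link_overlaps": prof.link_overlaps,
                                    "link_scores": prof.link_scores,
                                }
                                for pop, prof in profiles[mode].items()
                            },
                            "divergence": {
                                f"{a}|{b}": idx for (a, b), idx in div.items()
                            },
                        },
                        out_dir / f"ccp_{mode}.json",
                    )
                )
    except Exception as exc:
        raise RuntimeError(f"stage 'clique connectivity profiles' failed: {exc}") from exc

    try:
        stage("enrichment")
        rows = []
        for pop, net in networks.items():
            background = net.nodes
            for c in sized.get(pop, []):
                for res in enrich_gene_set(set(c.genes), background, go, config.alpha):
                    if res.x == 0:
                        continue
                    rows.append(
                        {
                            "population": pop,
                            "clique": ";".join(c.genes),
                            "term": res.term,
                            "x": res.x,
                            "gg": res.gg,
                            "g": res.g,
                            "G": res.G,
                            "p_value": res.p_value,
                            "q_value": res.q_value,
                            "significant": res.significant,
                        }
                    )
        emit(
            write_table(
                rows,
                out_dir / "enrichment.tsv",
                columns=[
                    "population", "clique", "term", "x", "gg", "g", "G",
                    "p_value", "q_value", "significant",
                ],
            )
        )
    except Exception as exc:
        raise RuntimeError(f"stage 'enrichment' failed: {exc}") from exc

    manifest = sorted(str(p.relative_to(out_dir)) for p in written)
    write_json({"files": manifest}, out_dir / "manifest.json")
    return PipelineResult(
        manifest=manifest,
        out_dir=out_dir,
        networks=networks,
        clique_sets=by_size_all,
        comparison=comparison,
        profiles=profiles,
        seed_clique=seed_clique,
    )
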