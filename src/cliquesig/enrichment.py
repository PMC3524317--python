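"""Hypergeometric GO-term enrichment of cliques and profiles.

For a query of gg genes drawn from a background of G genes (the population
network, not the whole genome), a term annotating g background genes of which
x fall in the query gets the upper-tail p-value

    p = sum_{i=x}^{min(gg, g)} C(g, i) * C(G-g, gg-i) / C(G, gg).

Terms with raw p < 0.05 are flagged significant, matching the filtering rule
the pipeline uses downstream; a Benjamini–Hochberg column is reported
alongside but does not drive that flag. Genes without any annotation stay in
the background count G but contribute to no term.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

from cliquesig.differential_expression import bh_fdr
from cliquesig.io_formats import AnnotationMap


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    x: int  # query genes annotated with term
    gg: int  # query size
    g: int  # background genes annotated with term
    G: int  # background size
    p_value: float
    q_value: float = 1.0
    significant: bool = False  # raw p < alpha (default 0.05)


def hypergeom_pvalue(x: int, gg: int, g: int, G: int) -> float:
    """Upper-tail hypergeometric probability P(X >= x)."""
    if not (0 <= x <= min(gg, g) and gg <= G and g <= G and gg >= 0 and g >= 0):
        raise ValueError(f"invalid counts x={x}, gg={gg}, g={g}, G={G}")
    # survival function is P(X > x-1) = P(X >= x)
    return float(min(1.0, hypergeom.sf(x - 1, G, g, gg)))


def enrich_gene_set(
    genes: set[str],
    background: set[str],
    annot: AnnotationMap,
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Enrichment of every term annotating >= 1 query gene, sorted by p-value."""
    genes = set(genes)
    background = set(background)
    if not genes:
        raise ValueError("empty query gene set")
    if not genes <= background:
        raise ValueError("query genes must be a subset of the background")
    G = len(background)
    gg = len(genes)
    terms = sorted({t for gene in genes for t in annot.terms_for(gene)})
    raw: list[tuple[str, int, int, float]] = []
    for term in terms:
        annotated = annot.genes_with_term(term, background)
        g = len(annotated)
        x = len(annotated & genes)
        raw.append((term, x, g, hypergeom_pvalue(x, gg, g, G)))
    if not raw:
        return []
    q_values = bh_fdr([p for _, _, _, p in raw])
    results = [
        EnrichmentResult(
            term=t, x=x, gg=gg, g=g, G=G, p_value=p, q_value=float(q),
            significant=p < alpha,
        )
        for (t, x, g, p), q in zip(raw, q_values)
    ]
    results.sort(key=lambda r: (r.p_value, r.term))
    return results
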