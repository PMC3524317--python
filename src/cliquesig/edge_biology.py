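"""Biological edge scoring: co-expression, GO distance, pathway similarity.

GO distance between two genes is the symmetric-difference dissimilarity of
their flat biological-process annotation sets, |AΔB| / (|A∪B| + |A∩B|): 0 for
identical non-empty sets, 1 for disjoint sets. A distance below 1 (at least
one shared term) marks the pair as functionally interacting.

Pathway similarity is (|P∩|/|P_N| + |P∩|/|P_M|) / |P_N ∪ P_M|. Note this raw
score can exceed 1 (identical singleton sets give 2); the min–max
normalization below absorbs the scale.

EdgeStrength averages three min–max-normalized features per edge: |PCC| (the
edge pre-filter already guarantees |r| above the cutoff; the sign is kept
separately), GO similarity (1 − distance, so larger = stronger, matching the
other two features; set ``go_as_similarity=False`` to enter the raw distance
instead), and the pathway score. Genes lacking GO or pathway annotation get
the network-median value for the affected feature before normalization and
the edge is flagged, rather than being discarded.
"""

from __future__ import annotations

import numpy as np

from cliquesig.io_formats import AnnotationMap, canonical_pair
from cliquesig.network_build import AnnotatedNetwork


def go_distance(terms_a: frozenset[str] | set[str], terms_b: frozenset[str] | set[str]) -> float:
    """Symmetric-difference GO dissimilarity in [0, 1]; both sets non-empty."""
    a, b = set(terms_a), set(terms_b)
    if not a or not b:
        raise ValueError("GO distance undefined for an unannotated gene")
    return len(a ^ b) / (len(a | b) + len(a & b))


def pathway_similarity(pw_a: frozenset[str] | set[str], pw_b: frozenset[str] | set[str]) -> float:
    """Shared-pathway score; 0 when either gene has no pathway annotation."""
    a, b = set(pw_a), set(pw_b)
    if not a or not b:
        return 0.0
    common = len(a & b)
    return (common / len(a) + common / len(b)) / len(a | b)


def _minmax(values: np.ndarray) -> np.ndarray:
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones_like(values)
    return (values - lo) / (hi - lo)


def _fill_median(values: list[float | None]) -> tuple[np.ndarray, list[int]]:
    """Replace None entries by the median of the observed ones; report indices."""
    missing = [i for i, v in enumerate(values) if v is None]
    observed = [v for v in values if v is not None]
    fill = float(np.median(observed)) if observed else 0.0
    out = np.array([fill if v is None else v for v in values], dtype=float)
    return out, missing


def edge_strength(
    net: AnnotatedNetwork,
    go_annot: AnnotationMap,
    pathway_annot: AnnotationMap,
    go_as_similarity: bool = True,
) -> dict[tuple[str, str], dict[str, float]]:
    """Score every edge and store the results as edge attributes.

    Returns per edge: raw ``pcc``, ``go_distance``, ``pathway_similarity``,
    the normalized triplet, ``edge_strength`` in [0, 1], and annotation flags.
    """
    g = net.graph
    edges = sorted(canonical_pair(a, b) for a, b in g.edges)
    if not edges:
        return {}

    abs_pcc = np.array([abs(g.edges[e]["pcc"]) for e in edges])
    go_raw: list[float | None] = []
    pw_raw: list[float | None] = []
    interacting: list[bool | None] = []
    for a, b in edges:
        ta, tb = go_annot.terms_for(a), go_annot.terms_for(b)
        if ta and tb:
            d = go_distance(ta, tb)
            go_raw.append(d)
            interacting.append(d < 1.0)
        else:
            go_raw.append(None)
            interacting.append(None)
        pa, pb = pathway_annot.terms_for(a), pathway_annot.terms_for(b)
        if pa and pb:
            pw_raw.append(pathway_similarity(pa, pb))
        else:
            pw_raw.append(None)

    go_filled, go_missing = _fill_median(go_raw)
    pw_filled, pw_missing = _fill_median(pw_raw)
    go_feature = 1.0 - go_filled if go_as_similarity else go_filled

    pcc_n = _minmax(abs_pcc)
    go_n = _minmax(go_feature)
    pw_n = _minmax(pw_filled)
    strength = (pcc_n + go_n + pw_n) / 3.0

    go_missing_set, pw_missing_set = set(go_missing), set(pw_missing)
    out: dict[tuple[str, str], dict[str, float]] = {}
    for i, (a, b) in enumerate(edges):
        scores = {
            "pcc": float(g.edges[a, b]["pcc"]),
            "go_distance": float(go_filled[i]),
            "pathway_similarity": float(pw_filled[i]),
            "pcc_norm": float(pcc_n[i]),
            "go_norm": float(go_n[i]),
            "pathway_norm": float(pw_n[i]),
            "edge_strength": float(strength[i]),
            "go_interacting": bool(interacting[i]) if interacting[i] is not None else False,
            "go_unannotated": i in go_missing_set,
            "pathway_unannotated": i in pw_missing_set,
        }
        g.edges[a, b].update(scores)
        out[(a, b)] = scores
    return out
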