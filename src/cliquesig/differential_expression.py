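"""Two-sample t-test differential expression with Benjamini–Hochberg FDR.

Genes pass when p < 0.05 and BH q < 0.1 (both strict). The default test is the
pooled-variance Student t; Welch is available via ``test="welch"``. Genes that
are constant in both groups with equal means carry no testable signal and are
excluded rather than assigned p = 1 (a constant gene also carries no
correlation signal downstream).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from cliquesig.io_formats import CONTROL, DISEASE, ExpressionMatrix

UP = "up"
DOWN = "down"


@dataclass(frozen=True)
class DEResult:
    gene: str
    t_stat: float
    p_value: float
    q_value: float
    direction: str  # up iff disease mean > control mean


def two_sample_t(x, y, test: str = "student") -> tuple[float, float]:
    """Two-sided two-sample t-test; t sign = sign(mean(x) - mean(y)).

    Raises ``ValueError`` if either group has fewer than 2 values, or if the
    pooled variance is zero with equal means (non-testable gene).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    if test not in ("student", "welch"):
        raise ValueError(f"unknown test {test!r}")
    diff = float(x.mean() - y.mean())
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if diff == 0.0:
            raise ValueError("zero variance in both groups with equal means: p undefined")
        # Degenerate but directional: the separation is infinitely many SDs.
        return math.copysign(math.inf, diff), 0.0
    res = stats.ttest_ind(x, y, equal_var=(test == "student"))
    return float(res.statistic), float(res.pvalue)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, aligned with the input."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_de(expr: ExpressionMatrix, test: str = "student") -> list[DEResult]:
    """Test every gene; non-testable (constant, equal-mean) genes are dropped."""
    genes, t_stats, p_values, directions = [], [], [], []
    for gene in expr.gene_ids:
        x = expr.group_values(gene, DISEASE)
        y = expr.group_values(gene, CONTROL)
        try:
            t, p = two_sample_t(x, y, test=test)
        except ValueError:
            continue
        genes.append(gene)
        t_stats.append(t)
        p_values.append(p)
        directions.append(UP if x.mean() > y.mean() else DOWN)
    if not genes:
        return []
    q_values = bh_fdr(p_values)
    return [
        DEResult(gene=g, t_stat=t, p_value=p, q_value=float(q), direction=d)
        for g, t, p, q, d in zip(genes, t_stats, p_values, q_values, directions)
    ]


def select_differential(
    results: list[DEResult], p_max: float = 0.05, q_max: float = 0.1
) -> list[str]:
    """Genes with p < p_max and q < q_max, both strict; input order preserved."""
    return [r.gene for r in results if r.p_value < p_max and r.q_value < q_max]


def regulation_census(
    results: list[DEResult], p_max: float = 0.05, q_max: float = 0.1
) -> tuple[int, int]:
    """(up, down) counts among the genes passing both thresholds."""
    selected = {r.gene for r in results if r.p_value < p_max and r.q_value < q_max}
    up = sum(1 for r in results if r.gene in selected and r.direction == UP)
    down = sum(1 for r in results if r.gene in selected and r.direction == DOWN)
    return up, down
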