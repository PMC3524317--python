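"""Readers and writers for every external file the pipeline touches.

Dialects
--------
Expression: TSV, genes in rows, first column gene symbols, header row = sample
IDs. Labels: two-column TSV ``sample<TAB>{disease|control}``. PPI: two-column
TSV of gene-symbol pairs (extra columns ignored). Annotations: two-column TSV
(``gene<TAB>term``) or GMT (``term<TAB>description<TAB>gene...``). Networks are
written as GraphML plus an edge TSV; tabular products as TSV and JSON.

Gene identity is the case-sensitive symbol string; no probe-to-gene mapping is
attempted (inputs are assumed gene-level). All collections are serialized in
lexicographic order so output diffs are stable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DISEASE = "disease"
CONTROL = "control"
VALID_GROUPS = (DISEASE, CONTROL)


class FormatError(ValueError):
    """Raised when an input file violates its documented dialect."""


@dataclass
class ExpressionMatrix:
    """Normalized expression values for one population.

    Parameters
    ----------
    values
        DataFrame of shape (genes, samples); index = unique gene symbols,
        columns = unique sample IDs.
    group_labels
        Mapping sample ID -> ``"disease"`` or ``"control"``; every sample in
        ``values`` must be labeled and both groups must be non-empty.
    """

    values: pd.DataFrame
    group_labels: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise FormatError(f"duplicate gene ids after collapse: {dupes[:5]}")
        if self.values.columns.duplicated().any():
            raise FormatError("duplicate sample ids")
        missing = [s for s in self.values.columns if s not in self.group_labels]
        if missing:
            raise FormatError(f"samples without a group label: {missing[:5]}")
        bad = {g for g in self.group_labels.values() if g not in VALID_GROUPS}
        if bad:
            raise FormatError(f"unknown group labels: {sorted(bad)}")
        for grp in VALID_GROUPS:
            if not self.samples_in_group(grp):
                raise FormatError(f"group {grp!r} has no samples")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise FormatError("non-numeric or non-finite expression values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.group_labels[s] == group]

    def gene_vector(self, gene: str) -> np.ndarray:
        """Expression of one gene across all samples, disease + control pooled."""
        return self.values.loc[gene].to_numpy(dtype=float)

    def group_values(self, gene: str, group: str) -> np.ndarray:
        return self.values.loc[gene, self.samples_in_group(group)].to_numpy(dtype=float)


@dataclass(frozen=True)
class EdgeList:
    """Undirected, deduplicated protein–protein interaction pairs."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if a == b:
                raise FormatError(f"self-pair {a!r} in edge list")
            if a > b:
                raise FormatError("edge pairs must be stored sorted")

    @property
    def nodes(self) -> set[str]:
        return {g for pair in self.pairs for g in pair}

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return (a, b) in self.pairs if a <= b else (b, a) in self.pairs


@dataclass
class AnnotationMap:
    """Flat gene -> term-set annotations (GO biological process or pathways)."""

    gene_to_terms: dict[str, frozenset[str]]
    namespace: str = "go_bp"

    def terms_for(self, gene: str) -> frozenset[str]:
        return self.gene_to_terms.get(gene, frozenset())

    def all_terms(self) -> set[str]:
        return {t for terms in self.gene_to_terms.values() for t in terms}

    def genes_with_term(self, term: str, universe: Iterable[str] | None = None) -> set[str]:
        genes = universe if universe is not None else self.gene_to_terms
        return {g for g in genes if term in self.terms_for(g)}


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


# ---------------------------------------------------------------------------
# readers


def read_expression(path: str | Path, labels_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV plus a two-column sample-label file.

    Duplicate gene rows are collapsed by their mean (logged). Raises
    :class:`FormatError` on unlabeled samples, non-numeric cells, or a group
    with fewer than 2 samples.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"empty expression matrix: {path}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric expression cell in {path}: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.index.duplicated().any():
        n_dup = int(df.index.duplicated().sum())
        logger.info("collapsing %d duplicate gene rows by mean in %s", n_dup, path)
        df = df.groupby(level=0, sort=False).mean()

    labels = _read_labels(labels_path)
    extra = [s for s in df.columns if s not in labels]
    if extra:
        raise FormatError(f"labels file {labels_path} missing samples: {extra[:5]}")
    labels = {s: labels[s] for s in df.columns}
    for grp in VALID_GROUPS:
        n = sum(1 for v in labels.values() if v == grp)
        if n < 2:
            raise FormatError(f"group {grp!r} has {n} samples; need at least 2")
    return ExpressionMatrix(values=df, group_labels=labels)


def _read_labels(path: str | Path) -> dict[str, str]:
    labels: dict[str, str] = {}
    for lineno, line in enumerate(_text_lines(path), start=1):
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 'sample<TAB>group'")
        sample, group = parts[0].strip(), parts[1].strip()
        if group not in VALID_GROUPS:
            raise FormatError(f"{path}:{lineno}: unknown group {group!r}")
        if sample in labels and labels[sample] != group:
            raise FormatError(f"{path}:{lineno}: conflicting label for {sample!r}")
        labels[sample] = group
    if not labels:
        raise FormatError(f"empty labels file: {path}")
    return labels


def read_edge_list(path: str | Path) -> EdgeList:
    """Read a two-column TSV of interactions into undirected deduplicated pairs.

    Extra columns are ignored; self-loops are dropped with a warning count.
    """
    pairs: set[tuple[str, str]] = set()
    n_self = 0
    n_lines = 0
    for lineno, line in enumerate(_text_lines(path), start=1):
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            raise FormatError(f"{path}:{lineno}: expected two gene symbols")
        a, b = parts[0].strip(), parts[1].strip()
        n_lines += 1
        if a == b:
            n_self += 1
            continue
        pairs.add(canonical_pair(a, b))
    if n_lines == 0:
        raise FormatError(f"empty edge list: {path}")
    if n_self:
        logger.warning("dropped %d self-loop line(s) from %s", n_self, path)
    return EdgeList(pairs=frozenset(pairs))


def read_gene_sets(
    path: str | Path, fmt: str = "two_col", namespace: str = "go_bp"
) -> AnnotationMap:
    """Read gene annotations from two-column TSV or GMT into an AnnotationMap."""
    mapping: dict[str, set[str]] = {}
    if fmt == "two_col":
        for lineno, line in enumerate(_text_lines(path), start=1):
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
                raise FormatError(f"{path}:{lineno}: expected 'gene<TAB>term'")
            mapping.setdefault(parts[0].strip(), set()).add(parts[1].strip())
    elif fmt == "gmt":
        for lineno, line in enumerate(_text_lines(path), start=1):
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: GMT needs term, desc, >=1 gene")
            term = parts[0].strip()
            for gene in parts[2:]:
                if gene.strip():
                    mapping.setdefault(gene.strip(), set()).add(term)
    else:
        raise FormatError(f"unknown annotation format {fmt!r}; use 'two_col' or 'gmt'")
    if not mapping:
        raise FormatError(f"no annotations read from {path}")
    return AnnotationMap(
        gene_to_terms={g: frozenset(t) for g, t in mapping.items()}, namespace=namespace
    )


def _text_lines(path: str | Path) -> Iterable[str]:
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n").rstrip("\r")
            if line and not line.startswith("#"):
                yield line


# ---------------------------------------------------------------------------
# writers


def write_expression(expr: ExpressionMatrix, path: str | Path, labels_path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene")
    with open(labels_path, "w", encoding="utf-8") as fh:
        for sample in expr.sample_ids:
            fh.write(f"{sample}\t{expr.group_labels[sample]}\n")


def write_edge_list(edges: EdgeList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(edges.pairs):
            fh.write(f"{a}\t{b}\n")


def write_gene_sets(annot: AnnotationMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(annot.gene_to_terms):
            for term in sorted(annot.gene_to_terms[gene]):
                fh.write(f"{gene}\t{term}\n")


def write_network(graph: nx.Graph, out_prefix: str | Path) -> list[Path]:
    """Write a scored network as GraphML plus an edge TSV; returns paths."""
    out_prefix = Path(out_prefix)
    graphml = out_prefix.with_suffix(".graphml")
    tsv = out_prefix.with_suffix(".edges.tsv")
    nx.write_graphml(graph, graphml)
    cols = sorted({k for _, _, d in graph.edges(data=True) for k in d})
    with open(tsv, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["gene_a", "gene_b", *cols]) + "\n")
        for a, b in sorted(canonical_pair(a, b) for a, b in graph.edges):
            d = graph.edges[a, b]
            fh.write("\t".join([a, b, *(_fmt(d.get(c)) for c in cols)]) + "\n")
    return [graphml, tsv]


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return format(value, ".10g")
    return str(value)


def write_table(rows: list[dict], path: str | Path, columns: list[str] | None = None) -> Path:
    """Write dict rows as a TSV with a deterministic row order."""
    path = Path(path)
    if columns is None:
        columns = sorted({k for row in rows for k in row}) if rows else []
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in sorted(rows, key=lambda r: tuple(_fmt(r.get(c)) for c in columns)):
            fh.write("\t".join(_fmt(row.get(c)) for c in columns) + "\n")
    return path


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")
    return path


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


@dataclass
class Manifest:
    """Record of every file a pipeline stage wrote."""

    files: list[Path] = field(default_factory=list)

    def add(self, *paths: Path) -> None:
        self.files.extend(Path(p) for p in paths)

    def to_json(self, path: str | Path) -> Path:
        return write_json({"files": sorted(str(p) for p in self.files)}, path)


def write_results(bundle: Mapping[str, object], out_dir: str | Path) -> Manifest:
    """Serialize a mapping of named pipeline products under ``out_dir``.

    Graphs become GraphML + edge TSV; lists of dict rows become TSV; everything
    else is written as JSON. Returns the manifest of written files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest()
    for name in sorted(bundle):
        obj = bundle[name]
        if isinstance(obj, nx.Graph):
            manifest.add(*write_network(obj, out_dir / name))
        elif isinstance(obj, list) and all(isinstance(r, dict) for r in obj):
            manifest.add(write_table(obj, out_dir / f"{name}.tsv"))
        else:
            manifest.add(write_json(obj, out_dir / f"{name}.json"))
    return manifest
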