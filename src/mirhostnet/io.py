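"""Readers and writers for every external file the pipeline touches.

All tabular formats are TSV with a header row, UTF-8. Gene-set collections
use the MSigDB GMT convention (name <TAB> description <TAB> gene ...).
Readers are dialect-tolerant (column names configurable) and total on the
output of the corresponding writers: read(write(x)) == x.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .errors import FormatError
from .types import (
    GeneSet,
    GeneSetCollection,
    TargetPredictionTable,
    TissueAssociationVector,
    TissueGraph,
    normalize_symbol,
)

logger = logging.getLogger(__name__)


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        # keep_default_na=False: symbols such as "NA" or "NAN" are real gene names
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    return df


def read_target_table(
    path: str | Path,
    source_label: str,
    mirna_column: str = "miRNA_id",
    gene_column: str = "gene_symbol",
    score_column: str | None = "score",
) -> TargetPredictionTable:
    """Load a miRNA->target table from one predictor or validation database.

    Gene symbols are uppercased; duplicate (miRNA, gene) rows are collapsed
    and counted in the log. Real TargetScan/miRDB dumps differ in layout, so
    the miRNA/gene/score column names are parameters rather than hard-coded.
    """
    df = _read_tsv(path, [mirna_column, gene_column])
    if df.empty:
        raise FormatError(f"{path}: no data rows")
    mirnas = df[mirna_column].dropna().unique()
    if len(mirnas) != 1:
        raise FormatError(f"{path}: expected a single miRNA id, found {sorted(mirnas)}")
    genes = df[gene_column].map(normalize_symbol)
    n_dup = int(genes.duplicated().sum())
    if n_dup:
        logger.info("%s: collapsed %d duplicate target row(s)", path, n_dup)
    scores = None
    if score_column is not None and score_column in df.columns:
        vals = pd.to_numeric(df[score_column], errors="coerce")
        scores = {}
        for g, v in zip(genes, vals):
            if pd.notna(v):
                scores[g] = float(v)
        if not scores:
            scores = None
    targets = frozenset(genes)
    logger.info("%s: %d rows, %d distinct targets", path, len(df), len(targets))
    return TargetPredictionTable(
        mirna_id=str(mirnas[0]), source=source_label, targets=targets, scores=scores
    )


def write_target_table(table: TargetPredictionTable, path: str | Path) -> None:
    rows = []
    for g in sorted(table.targets):
        score = "" if table.scores is None else table.scores.get(g, "")
        rows.append((table.mirna_id, g, table.source, score))
    df = pd.DataFrame(rows, columns=["miRNA_id", "gene_symbol", "source", "score"])
    df.to_csv(path, sep="\t", index=False)


def read_association_table(
    path: str | Path,
    host_gene: str,
    tissue: str,
    gene_column: str = "gene_symbol",
    score_column: str = "netwas_score",
) -> TissueAssociationVector:
    """Load per-gene association scores to ``host_gene`` for one tissue.

    A row for the host gene itself is dropped with a logged warning; whether
    upstream score files carry a self-score is provider-dependent.
    """
    df = _read_tsv(path, [gene_column, score_column])
    host = normalize_symbol(host_gene)
    scores: dict[str, float] = {}
    for i, (g_raw, s_raw) in enumerate(zip(df[gene_column], df[score_column])):
        line = i + 2  # 1-based, after header
        g = normalize_symbol(str(g_raw))
        try:
            s = float(s_raw)
        except (TypeError, ValueError):
            raise FormatError(f"{path}: non-numeric score {s_raw!r}", line=line) from None
        if g == host:
            logger.warning("%s: dropped host gene %s self-score row", path, host)
            continue
        scores[g] = s
    return TissueAssociationVector(host_gene=host, tissue=tissue, scores=scores)


def write_association_table(vector: TissueAssociationVector, path: str | Path) -> None:
    df = pd.DataFrame(
        sorted(vector.scores.items()), columns=["gene_symbol", "netwas_score"]
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read an MSigDB-style GMT file, preserving set order."""
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: GMT line needs >=3 tab-separated fields", line=lineno
                )
            name, desc, *genes = fields
            if name in seen:
                raise FormatError(f"{path}: duplicate set name {name!r}", line=lineno)
            seen.add(name)
            members = frozenset(normalize_symbol(g) for g in genes if g.strip())
            if not members:
                raise FormatError(f"{path}: set {name!r} has no members", line=lineno)
            sets.append(GeneSet(name=name, description=desc, members=members))
    return GeneSetCollection(sets=tuple(sets))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def read_edge_list(
    path: str | Path,
    tissue: str,
    nodes: frozenset[str] | None = None,
) -> TissueGraph:
    """Read an undirected weighted edge list (gene_a, gene_b, weight).

    Edges are canonicalized to (min, max) symbol order; a duplicate edge with
    a conflicting weight is a format error. ``nodes``, when given, fixes the
    full node universe so isolated genes are preserved.
    """
    df = _read_tsv(path, ["gene_a", "gene_b", "weight"])
    edges: dict[tuple[str, str], float] = {}
    node_set: set[str] = set(nodes) if nodes is not None else set()
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        a, b = normalize_symbol(str(row.gene_a)), normalize_symbol(str(row.gene_b))
        if a == b:
            raise FormatError(f"{path}: self-loop on {a}", line=line)
        try:
            w = float(row.weight)
        except (TypeError, ValueError):
            raise FormatError(f"{path}: non-numeric weight {row.weight!r}", line=line) from None
        key = TissueGraph.canonical_edge(a, b)
        if key in edges and edges[key] != w:
            raise FormatError(
                f"{path}: duplicate edge {key} with conflicting weight", line=line
            )
        edges[key] = w
        if nodes is None:
            node_set.update(key)
    return TissueGraph(tissue=tissue, nodes=frozenset(node_set), edges=edges)


def write_edge_list(graph: TissueGraph, path: str | Path) -> None:
    rows = [(a, b, w) for (a, b), w in sorted(graph.edges.items())]
    df = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
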