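"""Readers and writers for every file the pipeline touches.

All tabular formats are tab-delimited UTF-8 with a header row:
expression (genes x samples), annotation (gene_id, chromosome), labels
(sample_id, phenotype) and edge lists (gene_a, gene_b, mi).  Gene-set
collections arrive as standard GMT; classified networks can be exported
as GraphML for downstream visualisation.  Malformed input is rejected
with a :class:`ParseError` that names the file and line.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .core import (
    AnnotatedNetwork,
    ExpressionMatrix,
    GeneAnnotation,
    MIRankedEdgeList,
    StagenetError,
    StageLabels,
    canonical_pair,
)

__all__ = [
    "ParseError",
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_labels",
    "write_labels",
    "read_edges",
    "write_edges",
    "read_gmt",
    "export_graphml",
]


class ParseError(StagenetError):
    """Malformed input file; message carries path and 1-based line number."""

    def __init__(self, path: str | Path, line: int | None, message: str) -> None:
        loc = f"{path}" if line is None else f"{path}:{line}"
        super().__init__(f"{loc}: {message}")
        self.path = str(path)
        self.line = line


def _read_rows(path: str | Path) -> list[tuple[int, list[str]]]:
    rows: list[tuple[int, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            rows.append((lineno, line.split("\t")))
    return rows


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene ids, header = sample ids)."""
    rows = _read_rows(path)
    if not rows:
        raise ParseError(path, None, "empty expression file")
    _, header = rows[0]
    sample_ids = header[1:]
    if not sample_ids:
        raise ParseError(path, 1, "header defines no sample columns")
    if len(set(sample_ids)) != len(sample_ids):
        dup = _dup(sample_ids)
        raise ParseError(path, 1, f"duplicate sample id {dup!r}")
    gene_ids: list[str] = []
    seen: set[str] = set()
    values: list[list[float]] = []
    width = len(header)
    for lineno, cells in rows[1:]:
        if len(cells) != width:
            raise ParseError(
                path, lineno, f"expected {width} columns, found {len(cells)}"
            )
        gene = cells[0]
        if gene in seen:
            raise ParseError(path, lineno, f"duplicate gene id {gene!r}")
        seen.add(gene)
        gene_ids.append(gene)
        try:
            values.append([float(c) for c in cells[1:]])
        except ValueError:
            bad = next(c for c in cells[1:] if not _is_number(c))
            raise ParseError(path, lineno, f"non-numeric cell {bad!r}") from None
    try:
        return ExpressionMatrix(np.array(values, dtype=float).reshape(len(gene_ids), len(sample_ids)),
                                gene_ids, sample_ids)
    except StagenetError as exc:
        raise ParseError(path, None, str(exc)) from exc


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for i, gene in enumerate(matrix.gene_ids):
            row = "\t".join(_fmt(v) for v in matrix.values[i])
            fh.write(f"{gene}\t{row}\n")


def read_annotation(path: str | Path) -> GeneAnnotation:
    """Read a two-column (gene_id, chromosome) TSV with header."""
    rows = _read_rows(path)
    if not rows:
        raise ParseError(path, None, "empty annotation file")
    chrom: dict[str, str] = {}
    for lineno, cells in rows[1:]:
        if len(cells) < 2:
            raise ParseError(path, lineno, "expected 2 columns (gene_id, chromosome)")
        gene, chromosome = cells[0], cells[1]
        if gene in chrom:
            raise ParseError(path, lineno, f"duplicate gene id {gene!r}")
        chrom[gene] = chromosome
    return GeneAnnotation(chrom)


def write_annotation(annotation: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_id\tchromosome\n")
        for gene, chromosome in annotation.chromosomes.items():
            fh.write(f"{gene}\t{chromosome}\n")


def read_labels(path: str | Path, control: str) -> StageLabels:
    """Read a two-column (sample_id, phenotype) TSV with header."""
    rows = _read_rows(path)
    if not rows:
        raise ParseError(path, None, "empty labels file")
    mapping: dict[str, str] = {}
    for lineno, cells in rows[1:]:
        if len(cells) < 2:
            raise ParseError(path, lineno, "expected 2 columns (sample_id, phenotype)")
        sample, phenotype = cells[0], cells[1]
        if sample in mapping:
            raise ParseError(path, lineno, f"duplicate sample id {sample!r}")
        mapping[sample] = phenotype
    try:
        return StageLabels(mapping, control)
    except StagenetError as exc:
        raise ParseError(path, None, str(exc)) from exc


def write_labels(labels: StageLabels, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample_id\tphenotype\n")
        for sample, phenotype in labels.mapping.items():
            fh.write(f"{sample}\t{phenotype}\n")


def read_edges(path: str | Path) -> MIRankedEdgeList:
    """Read a (gene_a, gene_b, mi) TSV; canonicalises pair and sort order."""
    rows = _read_rows(path)
    if not rows:
        raise ParseError(path, None, "empty edge file")
    records: list[tuple[str, str, float]] = []
    seen: set[tuple[str, str]] = set()
    for lineno, cells in rows[1:]:
        if len(cells) < 3:
            raise ParseError(path, lineno, "expected 3 columns (gene_a, gene_b, mi)")
        a, b = cells[0], cells[1]
        if a == b:
            raise ParseError(path, lineno, f"self-loop edge on gene {a!r}")
        try:
            mi = float(cells[2])
        except ValueError:
            raise ParseError(path, lineno, f"non-numeric mi {cells[2]!r}") from None
        if not np.isfinite(mi) or mi < 0:
            raise ParseError(path, lineno, f"mi must be finite and >= 0, got {mi!r}")
        pair = canonical_pair(a, b)
        if pair in seen:
            raise ParseError(path, lineno, f"duplicate edge for pair {pair}")
        seen.add(pair)
        records.append((a, b, mi))
    try:
        return MIRankedEdgeList.from_records(records)
    except StagenetError as exc:
        raise ParseError(path, None, str(exc)) from exc


def write_edges(edges: MIRankedEdgeList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tmi\n")
        for a, b, mi in edges:
            fh.write(f"{a}\t{b}\t{_fmt(mi)}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name, description, members per line.

    Duplicate members within a set collapse; duplicate set names are an
    error.  An empty file yields an empty collection.
    """
    sets: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            cells = line.split("\t")
            if len(cells) < 3:
                raise ParseError(
                    path, lineno, f"expected >= 3 fields (name, description, members), found {len(cells)}"
                )
            name = cells[0]
            if name in sets:
                raise ParseError(path, lineno, f"duplicate gene-set name {name!r}")
            sets[name] = {g for g in cells[2:] if g}
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write(name + "\t" + name + "\t" + "\t".join(sorted(set(members))) + "\n")


def export_graphml(
    network: AnnotatedNetwork,
    node_attrs: Mapping[str, Mapping[str, str]] | None,
    path: str | Path,
) -> None:
    """Write a classified network as GraphML.

    The cis/trans flag and MI weight become edge attributes; each
    node carries its chromosome plus any caller-supplied attributes
    (e.g. differential-expression status).
    """
    nodes = network.nodes
    if node_attrs:
        unknown = [n for n in node_attrs if n not in nodes]
        if unknown:
            raise StagenetError(f"node attributes given for unknown nodes: {sorted(unknown)}")
    g = nx.Graph()
    for node in sorted(nodes):
        attrs = {"chromosome": network.annotation[node]}
        if node_attrs and node in node_attrs:
            attrs.update({k: str(v) for k, v in node_attrs[node].items()})
        g.add_node(node, **attrs)
    for i, (a, b) in enumerate(network.edges):
        g.add_edge(a, b, interaction=network.edge_flag(i), mi=float(network.mi[i]))
    nx.write_graphml(g, str(path))


def _is_number(cell: str) -> bool:
    try:
        float(cell)
        return True
    except ValueError:
        return False


def _fmt(v: float) -> str:
    f = float(v)
    if f.is_integer() and abs(f) < 1e15:
        return str(int(f))
    return repr(f)


def _dup(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for it in items:
        if it in seen:
            return it
        seen.add(it)
    return ""
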