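"""Readers and writers for the plain-text formats the pipeline touches.

Supported dialects:

* GCT 1.2 — expression matrix (``#1.2`` header, declared dimensions,
  NAME / Description columns);
* CLS (categorical) — phenotype labels, 3-line dialect;
* GMT — one gene set per line: name, description, member genes;
* SIF — interaction edges: ``nodeA  relation  nodeB [nodeC ...]``;
* TSV — per-sample covariate table (``sample_id``, ``value``) and the
  design table (``sample_id``, ``subject``, ``group``, ``timepoint``).

All functions operate on text streams so tests can run fully in memory.
Parsers reject structural errors (naming the offending line) rather than
silently repairing them; every writer emits files its own parser accepts.
"""

from __future__ import annotations

import logging
from typing import IO, Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .containers import (
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    ValidationError,
    META_COLUMNS,
)

log = logging.getLogger(__name__)


class ParseError(ValidationError):
    """Malformed input file; message carries the 1-based line number."""


# ---------------------------------------------------------------------------
# GCT 1.2


def parse_gct(stream: IO[str]) -> ExpressionMatrix:
    """Parse a GCT 1.2 expression file into a bare :class:`ExpressionMatrix`.

    Sample metadata is not part of GCT; attach a design table afterwards
    with :meth:`ExpressionMatrix.attach_design`.
    """
    version = stream.readline().strip()
    if version != "#1.2":
        raise ParseError(f"line 1: expected '#1.2', got {version!r}")
    dims = stream.readline().split("\t")
    try:
        n_genes, n_samples = int(dims[0]), int(dims[1])
    except (ValueError, IndexError):
        raise ParseError("line 2: expected '<n_genes>\\t<n_samples>'") from None
    header = stream.readline().rstrip("\n").split("\t")
    if len(header) < 2 or header[0].upper() != "NAME":
        raise ParseError("line 3: header must start with NAME\\tDescription")
    sample_ids = header[2:]
    if len(sample_ids) != n_samples:
        raise ParseError(
            f"line 3: declared {n_samples} samples, header has {len(sample_ids)}"
        )
    names: list[str] = []
    rows: list[list[float]] = []
    seen: set[str] = set()
    for lineno, line in enumerate(stream, start=4):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = line.split("\t")
        if len(parts) != 2 + n_samples:
            raise ParseError(
                f"line {lineno}: expected {2 + n_samples} fields, got {len(parts)}"
            )
        name = parts[0].strip()
        if name in seen:
            raise ParseError(f"line {lineno}: duplicate NAME {name!r}")
        seen.add(name)
        try:
            vals = [float(v) for v in parts[2:]]
        except ValueError as exc:
            raise ParseError(f"line {lineno}: non-numeric cell ({exc})") from None
        names.append(name)
        rows.append(vals)
    if len(names) != n_genes:
        raise ParseError(
            f"end of file: declared {n_genes} genes, found {len(names)}"
        )
    values = pd.DataFrame(rows, index=pd.Index(names, name="gene"),
                          columns=sample_ids, dtype=float)
    return ExpressionMatrix(values)


def write_gct(matrix: ExpressionMatrix, stream: IO[str],
              descriptions: Mapping[str, str] | None = None) -> None:
    values = matrix.values
    stream.write("#1.2\n")
    stream.write(f"{values.shape[0]}\t{values.shape[1]}\n")
    stream.write("NAME\tDescription\t" + "\t".join(map(str, values.columns)) + "\n")
    desc = descriptions or {}
    for gene, row in values.iterrows():
        cells = "\t".join(format(v, ".17g") for v in row.to_numpy())
        stream.write(f"{gene}\t{desc.get(gene, 'na')}\t{cells}\n")


# ---------------------------------------------------------------------------
# CLS (categorical)


def parse_cls(stream: IO[str]) -> list[str]:
    """Parse a categorical CLS file; returns one label per sample."""
    head = stream.readline().split()
    if len(head) != 3:
        raise ParseError("line 1: expected '<n_samples> <n_classes> 1'")
    try:
        n_samples, n_classes = int(head[0]), int(head[1])
    except ValueError:
        raise ParseError("line 1: counts must be integers") from None
    class_line = stream.readline().split()
    if not class_line or class_line[0] != "#":
        raise ParseError("line 2: expected '# <class names>'")
    class_names = class_line[1:]
    if len(class_names) != n_classes:
        raise ParseError(
            f"line 2: declared {n_classes} classes, listed {len(class_names)}"
        )
    labels = stream.readline().split()
    if len(labels) != n_samples:
        raise ParseError(
            f"line 3: declared {n_samples} samples, found {len(labels)} labels"
        )
    extra = set(labels) - set(class_names)
    if extra:
        raise ParseError(f"line 3: labels not in class list: {sorted(extra)}")
    return labels


def write_cls(labels: Iterable[str], stream: IO[str]) -> None:
    labels = list(labels)
    classes = list(dict.fromkeys(labels))  # first-appearance order
    stream.write(f"{len(labels)} {len(classes)} 1\n")
    stream.write("# " + " ".join(classes) + "\n")
    stream.write(" ".join(labels) + "\n")


# ---------------------------------------------------------------------------
# GMT


def parse_gmt(stream: IO[str]) -> GeneSetCollection:
    sets: list[GeneSet] = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        parts = [p.strip() for p in line.split("\t")]
        if len(parts) < 3:
            raise ParseError(
                f"line {lineno}: GMT line needs name, description, >=1 member"
            )
        name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
        if not members:
            raise ParseError(f"line {lineno}: gene set {name!r} is empty")
        uniq = frozenset(members)
        if len(uniq) != len(members):
            log.warning("gene set %s: duplicate members removed", name)
        sets.append(GeneSet(name, desc, uniq))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, stream: IO[str]) -> None:
    for s in collection:
        stream.write(s.name + "\t" + s.description + "\t"
                     + "\t".join(sorted(s.genes)) + "\n")


# ---------------------------------------------------------------------------
# SIF


def parse_sif(stream: IO[str]) -> nx.Graph:
    """Parse a SIF edge list into a simple undirected graph.

    Multi-target lines (``A rel B C``) expand to one edge per target;
    duplicate edges collapse; self-loops are rejected.
    """
    graph = nx.Graph()
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = [p.strip() for p in line.split("\t") if p.strip()]
        if len(parts) == 1:
            graph.add_node(parts[0])  # isolated node
            continue
        if len(parts) < 3:
            raise ParseError(
                f"line {lineno}: SIF line needs 'node relation target...'"
            )
        source, relation, targets = parts[0], parts[1], parts[2:]
        for target in targets:
            if target == source:
                raise ParseError(f"line {lineno}: self-loop on {source!r}")
            graph.add_edge(source, target, relation=relation)
    return graph


def write_sif(graph: nx.Graph, stream: IO[str],
              default_relation: str = "pp") -> None:
    for node in sorted(graph.nodes):
        if graph.degree(node) == 0:
            stream.write(f"{node}\n")
    for u, v, data in sorted(graph.edges(data=True)):
        rel = data.get("relation", default_relation)
        stream.write(f"{u}\t{rel}\t{v}\n")


# ---------------------------------------------------------------------------
# TSV tables


def parse_covariate_tsv(stream: IO[str]) -> pd.Series:
    """Covariate table: header ``sample_id<TAB>value``, one row per sample."""
    df = pd.read_csv(stream, sep="\t")
    if list(df.columns[:2]) != ["sample_id", "value"]:
        raise ParseError("covariate TSV must have header 'sample_id\\tvalue'")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ParseError(f"duplicate sample_id {dup!r} in covariate TSV")
    series = pd.Series(df["value"].to_numpy(float),
                       index=pd.Index(df["sample_id"].astype(str), name="sample_id"),
                       name="value")
    if not np.isfinite(series.to_numpy()).all():
        raise ParseError("covariate values must be finite")
    return series


def write_covariate_tsv(covariate: pd.Series, stream: IO[str]) -> None:
    stream.write("sample_id\tvalue\n")
    for sid, val in covariate.items():
        stream.write(f"{sid}\t{format(val, '.10g')}\n")


def parse_design_tsv(stream: IO[str]) -> pd.DataFrame:
    """Design table: sample_id, subject, group, timepoint (tab-separated)."""
    df = pd.read_csv(stream, sep="\t", dtype=str)
    required = ["sample_id", *META_COLUMNS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"design TSV missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        raise ParseError("duplicate sample_id in design TSV")
    return df.set_index("sample_id")[list(META_COLUMNS)]


def write_design_tsv(design: pd.DataFrame, stream: IO[str]) -> None:
    stream.write("sample_id\t" + "\t".join(META_COLUMNS) + "\n")
    for sid, row in design.iterrows():
        stream.write(sid + "\t" + "\t".join(row[c] for c in META_COLUMNS) + "\n")


# ---------------------------------------------------------------------------
# Identifier utilities


def uppercase_ids(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Normalize gene identifiers to uppercase (``--uppercase-ids``)."""
    values = matrix.values.copy()
    values.index = values.index.str.upper()
    return ExpressionMatrix(values, matrix.samples)


def collapse_duplicate_genes(values: pd.DataFrame) -> pd.DataFrame:
    """Collapse duplicate rows per gene, keeping the most variable probe.

    Of the rows sharing one identifier, the row with the largest maximum
    absolute deviation from its own grand mean is retained.
    """
    if not values.index.has_duplicates:
        return values
    arr = values.to_numpy(float)
    dev = np.abs(arr - arr.mean(axis=1, keepdims=True)).max(axis=1)
    order = pd.DataFrame({"dev": dev}, index=values.index)
    keep = (
        order.assign(pos=np.arange(len(order)))
        .sort_values(["dev", "pos"], ascending=[False, True])
        .groupby(level=0, sort=False)
        .head(1)["pos"]
        .sort_values()
    )
    return values.iloc[keep.to_numpy()]
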