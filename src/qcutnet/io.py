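"""Plain-text TSV readers and writers for every artifact in the pipeline.

All formats are tab-delimited UTF-8; lines starting with ``#`` are comments.
Paths ending in ``.gz`` are transparently (de)compressed. Validation is
strict: malformed input raises :class:`FormatError` naming the offending
row or cell.

In-memory containers are the field's standard ones:

* expression matrices and attribute matrices — :class:`pandas.DataFrame`
  (rows = entities, columns = conditions / attributes);
* networks — :class:`networkx.Graph` with string node ids and an optional
  ``weight`` edge attribute;
* partitions — ``dict`` mapping node id to a module label, labels contiguous
  integers starting at 1;
* term ontologies — :class:`networkx.DiGraph` with child → parent edges.
"""

from __future__ import annotations

import gzip
import io as _io
from typing import IO, Iterator

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "read_attribute_table",
    "read_edge_list",
    "read_expression_matrix",
    "read_partition",
    "read_term_parents",
    "write_edge_list",
    "write_expression_matrix",
    "write_partition",
]


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _open(path, mode: str = "rt") -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode, encoding="utf-8")


def _rows(handle: IO[str]) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, fields) for non-comment, non-blank lines."""
    for lineno, line in enumerate(handle, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        yield lineno, line.split("\t")


# ---------------------------------------------------------------------------
# expression matrices


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a genes-or-samples × conditions matrix of log-scale expression.

    The first non-comment row is a header: an id column name followed by
    condition ids. Every following row is an entity id and one numeric value
    per condition. Duplicate entity ids, missing values, and non-numeric
    cells are hard errors.
    """
    with _open(path) as fh:
        rows = _rows(fh)
        try:
            _, header = next(rows)
        except StopIteration:
            raise FormatError(f"{path}: empty expression file")
        condition_ids = header[1:]
        if len(condition_ids) < 2:
            raise FormatError(f"{path}: need at least 2 conditions, found {len(condition_ids)}")
        if len(set(condition_ids)) != len(condition_ids):
            raise FormatError(f"{path}: duplicate condition ids in header")
        ids: list[str] = []
        seen: set[str] = set()
        data: list[list[float]] = []
        for lineno, fields in rows:
            entity = fields[0]
            if entity in seen:
                raise FormatError(f"{path}:{lineno}: duplicate entity id {entity!r}")
            if len(fields) - 1 != len(condition_ids):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(condition_ids)} values, got {len(fields) - 1}"
                )
            values = []
            for cond, cell in zip(condition_ids, fields[1:]):
                try:
                    v = float(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric value {cell!r} "
                        f"for entity {entity!r}, condition {cond!r}"
                    ) from None
                if np.isnan(v):
                    raise FormatError(
                        f"{path}:{lineno}: missing value for entity {entity!r}, condition {cond!r}"
                    )
                values.append(v)
            seen.add(entity)
            ids.append(entity)
            data.append(values)
    if len(ids) < 2:
        raise FormatError(f"{path}: need at least 2 entities, found {len(ids)}")
    return pd.DataFrame(np.asarray(data, dtype=float), index=ids, columns=condition_ids)


def write_expression_matrix(expr: pd.DataFrame, path, header_comments: list[str] | None = None) -> None:
    with _open(path, "wt") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        fh.write("id\t" + "\t".join(map(str, expr.columns)) + "\n")
        for entity, row in zip(expr.index, expr.to_numpy()):
            fh.write(str(entity) + "\t" + "\t".join(format(v, ".10g") for v in row) + "\n")


# ---------------------------------------------------------------------------
# edge lists


def read_edge_list(path) -> nx.Graph:
    """Read an undirected simple graph from TSV rows ``node1 node2 [weight]``.

    Self-loops are rejected, as are duplicate edges whose weights conflict.
    Weights, when present, must be positive.
    """
    g = nx.Graph()
    with _open(path) as fh:
        for lineno, fields in _rows(fh):
            if len(fields) not in (2, 3):
                raise FormatError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(fields)}")
            u, v = fields[0], fields[1]
            if u == v:
                raise FormatError(f"{path}:{lineno}: self-loop on node {u!r}")
            w = None
            if len(fields) == 3:
                try:
                    w = float(fields[2])
                except ValueError:
                    raise FormatError(f"{path}:{lineno}: non-numeric weight {fields[2]!r}") from None
                if not w > 0:
                    raise FormatError(f"{path}:{lineno}: non-positive weight {w}")
            if g.has_edge(u, v):
                old = g.edges[u, v].get("weight")
                if old != w:
                    raise FormatError(
                        f"{path}:{lineno}: duplicate edge {u!r}-{v!r} with conflicting weight"
                    )
                continue
            if w is None:
                g.add_edge(u, v)
            else:
                g.add_edge(u, v, weight=w)
    return g


def write_edge_list(net: nx.Graph, path, header_comments: list[str] | None = None) -> None:
    with _open(path, "wt") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        for u, v, data in net.edges(data=True):
            if "weight" in data:
                fh.write(f"{u}\t{v}\t{format(data['weight'], '.10g')}\n")
            else:
                fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# partitions


def relabel_partition(part: dict[str, int]) -> dict[str, int]:
    """Renumber module labels to contiguous 1..k, ordered by original label."""
    labels = sorted(set(part.values()))
    remap = {old: new for new, old in enumerate(labels, start=1)}
    return {node: remap[lab] for node, lab in part.items()}


def read_partition(path) -> dict[str, int]:
    """Read TSV rows ``node_id module_label``; labels renumbered to 1..k."""
    part: dict[str, int] = {}
    with _open(path) as fh:
        for lineno, fields in _rows(fh):
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            node, label = fields
            if node in part:
                raise FormatError(f"{path}:{lineno}: node {node!r} listed twice")
            try:
                part[node] = int(label)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer module label {label!r}") from None
    if not part:
        raise FormatError(f"{path}: empty partition file")
    return relabel_partition(part)


def write_partition(part: dict[str, int], path, header_comments: list[str] | None = None) -> None:
    with _open(path, "wt") as fh:
        for line in header_comments or []:
            fh.write(f"# {line}\n")
        for node, label in part.items():
            fh.write(f"{node}\t{label}\n")


# ---------------------------------------------------------------------------
# annotations and ontologies


def read_attribute_table(path) -> pd.DataFrame:
    """Read (entity, attribute) pairs into a binary incidence DataFrame.

    Rows are entities in order of first appearance, columns attributes in
    order of first appearance; cell 1 where the pair was listed.
    """
    entities: dict[str, int] = {}
    attributes: dict[str, int] = {}
    pairs: list[tuple[int, int]] = []
    with _open(path) as fh:
        for lineno, fields in _rows(fh):
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            ent, attr = fields
            i = entities.setdefault(ent, len(entities))
            j = attributes.setdefault(attr, len(attributes))
            pairs.append((i, j))
    if not pairs:
        raise FormatError(f"{path}: empty annotation file")
    mat = np.zeros((len(entities), len(attributes)), dtype=int)
    for i, j in pairs:
        mat[i, j] = 1
    return pd.DataFrame(mat, index=list(entities), columns=list(attributes))


def read_term_parents(path) -> nx.DiGraph:
    """Read (child_term, parent_term) rows into a DAG with child → parent edges.

    A cyclic table is rejected with one cycle named in the error.
    """
    dag = nx.DiGraph()
    with _open(path) as fh:
        for lineno, fields in _rows(fh):
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            child, parent = fields
            dag.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(dag):
        cycle = nx.find_cycle(dag)
        pretty = " -> ".join([cycle[0][0]] + [v for _, v in cycle])
        raise FormatError(f"{path}: term-parent table contains a cycle: {pretty}")
    return dag
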