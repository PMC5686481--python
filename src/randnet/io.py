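"""File dialects: networks, attribute tables, value files, community files, reports.

Network files are plain text, whitespace-separated:

* **edge-list** — two tokens per row (``source target``); a single-token row
  declares an isolated node (same convention as SIF).
* **SIF** — three tokens per row (``source interaction target``); the
  interaction type is read and discarded; single-token rows declare isolated
  nodes.

Attribute tables are CSV with a header row; the first column holds node ids,
every other column a numeric attribute.  Attribute names are case-sensitive.

Comparison reports are text files made of fields: each field starts with a
``>``-prefixed explanation line followed by comma-separated-value rows.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd

from .graph import Graph

__all__ = [
    "AttributeTable",
    "ValueFile",
    "Community",
    "CommunitySpec",
    "ReportField",
    "ComparisonReport",
    "read_edge_list",
    "write_edge_list",
    "read_attribute_table",
    "write_attribute_table",
    "read_value_file",
    "read_community_file",
    "write_report",
    "read_report",
    "format_number",
]

PathLike = Union[str, Path]

#: node-id -> attribute-name -> numeric value
AttributeTable = Dict[str, Dict[str, float]]


@dataclass(frozen=True)
class ValueFile:
    """Ordered numeric values from a one-number-per-row file."""

    values: Tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("value file holds no values")
        if not all(math.isfinite(v) for v in self.values):
            raise ValueError("value file contains non-finite entries")

    @property
    def min(self) -> float:
        return min(self.values)

    @property
    def max(self) -> float:
        return max(self.values)


@dataclass(frozen=True)
class Community:
    """One community row: edge probability plus member names."""

    p: float
    members: Tuple[str, ...]

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError(f"community probability {self.p} outside [0, 1]")
        if len(self.members) < 2:
            raise ValueError("a community needs at least 2 members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"duplicate member in community {self.members!r}")


CommunitySpec = Tuple[Community, ...]


# ---------------------------------------------------------------------------
# networks


def read_edge_list(path: PathLike, dialect: str = "edge-list") -> Graph:
    """Read a network file in ``edge-list`` or ``sif`` dialect.

    Duplicate rows collapse to one edge; self-loop rows are dropped with a
    warning.  Malformed rows raise ``ValueError`` with their line number.
    """
    if dialect not in ("edge-list", "sif"):
        raise ValueError(f"unknown network dialect {dialect!r}")
    nodes: set = set()
    edges: set = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        if len(tokens) == 1:
            nodes.add(tokens[0])
            continue
        if dialect == "edge-list":
            if len(tokens) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(tokens)}"
                )
            u, v = tokens
        else:
            if len(tokens) != 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 columns "
                    f"(source interaction target), got {len(tokens)}"
                )
            u, _, v = tokens
        nodes.update((u, v))
        if u == v:
            warnings.warn(
                f"{path}: line {lineno}: dropped self-loop on {u!r}", stacklevel=2
            )
            continue
        edges.add((u, v) if u <= v else (v, u))
    return Graph(nodes, edges)


def write_edge_list(g: Graph, path: PathLike) -> None:
    """Write a Graph as an edge-list file (isolated nodes as single tokens)."""
    lines = [f"{u}\t{v}" for u, v in sorted(g.edges)]
    connected = {n for e in g.edges for n in e}
    lines.extend(sorted(g.nodes - connected))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# attribute tables


def read_attribute_table(path: PathLike) -> AttributeTable:
    """Read a CSV attribute table (first column: node id; rest: numeric).

    Attribute names are taken verbatim from the header (case preserved).
    Non-numeric cells and duplicate node ids raise ``ValueError``.
    """
    df = pd.read_csv(path, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: attribute table needs an id column plus >=1 attribute")
    id_col = df.columns[0]
    ids = df[id_col].astype(str)
    dup = ids[ids.duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate node id {dup.iloc[0]!r}")
    table: AttributeTable = {}
    numeric = {}
    for col in df.columns[1:]:
        try:
            numeric[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(bad[bad.isna() & df[col].notna()].index[0]) + 2  # header is row 1
            raise ValueError(
                f"{path}: non-numeric value in column {col!r}, row {row}"
            ) from None
    for i, node in enumerate(ids):
        table[node] = {col: float(numeric[col].iloc[i]) for col in df.columns[1:]}
    return table


def write_attribute_table(table: AttributeTable, path: PathLike, id_column: str = "id") -> None:
    """Write an attribute table as CSV (nodes sorted by id)."""
    nodes = sorted(table)
    attrs = sorted({a for row in table.values() for a in row})
    df = pd.DataFrame(
        {id_column: nodes, **{a: [table[n].get(a) for n in nodes] for a in attrs}}
    )
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# value files and community files


def read_value_file(path: PathLike, expected_count: Optional[int] = None) -> ValueFile:
    """Read a one-numeric-value-per-row file ('.' is the decimal separator).

    If ``expected_count`` is given and the row count differs, a warning is
    emitted and parsing proceeds (row count need not match the node count).
    """
    values: List[float] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        token = line.strip()
        if not token:
            continue
        try:
            values.append(float(token))
        except ValueError:
            raise ValueError(f"{path}: line {lineno}: not a number: {token!r}") from None
    if not values:
        raise ValueError(f"{path}: empty value file")
    if expected_count is not None and len(values) != expected_count:
        warnings.warn(
            f"{path}: {len(values)} values but {expected_count} expected "
            "(e.g. one per node); proceeding anyway",
            stacklevel=2,
        )
    return ValueFile(tuple(values))


def read_community_file(path: PathLike) -> CommunitySpec:
    """Read community rows: ``p member member [member ...]`` per line."""
    rows: List[Community] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        tokens = line.split()
        if not tokens:
            continue
        try:
            p = float(tokens[0])
        except ValueError:
            raise ValueError(
                f"{path}: line {lineno}: first token must be the edge "
                f"probability, got {tokens[0]!r}"
            ) from None
        try:
            rows.append(Community(p, tuple(tokens[1:])))
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from None
    if not rows:
        raise ValueError(f"{path}: empty community file")
    return tuple(rows)


# ---------------------------------------------------------------------------
# comparison reports


def format_number(x: float) -> str:
    """Report numeric format: 6 significant digits, '.' decimal separator."""
    return f"{x:.6g}"


@dataclass
class ReportField:
    """One report field: a ``>``-prefixed explanation plus CSV rows."""

    label: str
    rows: List[List[str]] = field(default_factory=list)


@dataclass
class ComparisonReport:
    """Ordered report fields; the first fields name the networks used."""

    mode: str  # "single_real" | "multi_real"
    fields: List[ReportField] = field(default_factory=list)

    def field_by_label(self, label: str) -> ReportField:
        for f in self.fields:
            if f.label == label:
                return f
        raise KeyError(label)


def write_report(report: ComparisonReport, path: PathLike) -> None:
    """Write the ``>``-annotated CSV report."""
    lines: List[str] = []
    for f in report.fields:
        lines.append(f"> {f.label}")
        for row in f.rows:
            lines.append(",".join(str(c) for c in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_report(path: PathLike) -> ComparisonReport:
    """Parse a report written by :func:`write_report` (round-trip support)."""
    fields: List[ReportField] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith(">"):
            fields.append(ReportField(line[1:].strip()))
        else:
            if not fields:
                raise ValueError(
                    f"{path}: line {lineno}: data row before any '>' field header"
                )
            fields[-1].rows.append(line.split(","))
    mode = "single_real"
    for f in fields:
        if f.label == "real networks" and len(f.rows) > 1:
            mode = "multi_real"
    return ComparisonReport(mode=mode, fields=fields)
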