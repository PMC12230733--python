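"""Build networks from delimited tabular files.

Mirrors the tabular loader workflow: preview the file, assign each column a
role (source id, target id, node attribute, edge attribute, or ignore) and a
datatype, then materialize an edge list as a directed multigraph.  Nodes are
deduplicated by their whitespace-trimmed key string (recorded as a ``name``
attribute); duplicate rows produce parallel edges; a row with an empty target
creates an isolated node.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .core import NetworkBundle, coerce_value
from .errors import CxParseError, TypeCoercionError

ROLES = ("source_id", "target_id", "source_attr", "target_attr", "edge_attr", "ignore")


@dataclass
class ColumnSpec:
    name: str
    role: str
    datatype: str = "string"
    attribute: Optional[str] = None  # attribute name; defaults to column name
    list_delimiter: Optional[str] = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown column role {self.role!r}")
        if self.attribute is None:
            self.attribute = self.name
        if self.datatype.startswith("list_of_") and self.list_delimiter is None:
            self.list_delimiter = "|"


@dataclass
class ImportPlan:
    columns: list[ColumnSpec]
    delimiter: str = ","
    header: bool = True

    def __post_init__(self) -> None:
        sources = [c for c in self.columns if c.role == "source_id"]
        targets = [c for c in self.columns if c.role == "target_id"]
        if len(sources) != 1:
            raise ValueError("exactly one source_id column is required")
        if len(targets) > 1:
            raise ValueError("at most one target_id column is allowed")


@dataclass
class ImportReport:
    skipped_rows: list[tuple[int, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def sniff_delimiter(text: str) -> str:
    """Tab wins when present in the first line; otherwise comma."""
    first_line = text.splitlines()[0] if text else ""
    return "\t" if "\t" in first_line else ","


def parse_rows(text: str, delimiter: Optional[str] = None) -> list[list[str]]:
    if delimiter is None:
        delimiter = sniff_delimiter(text)
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    return [row for row in reader]


def infer_datatype(values: Iterable[str]) -> str:
    """Infer a column datatype from text cells; empty cells are ignored."""
    non_empty = [v.strip() for v in values if v.strip() != ""]
    if not non_empty:
        return "string"
    if all(v.lower() in ("true", "false") for v in non_empty):
        return "boolean"
    def is_int(v: str) -> bool:
        try:
            int(v)
            return True
        except ValueError:
            return False
    def is_float(v: str) -> bool:
        try:
            float(v)
            return True
        except ValueError:
            return False
    if all(is_int(v) for v in non_empty):
        return "integer"
    if all(is_float(v) for v in non_empty):
        return "double"
    return "string"


@dataclass
class TablePreview:
    header: list[str]
    rows: list[list[str]]
    datatypes: list[str]
    delimiter: str


def preview_table(text: str, n: int = 10, delimiter: Optional[str] = None,
                  header: bool = True) -> TablePreview:
    """First ``n`` parsed rows with per-column inferred datatypes."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if delimiter is None:
        delimiter = sniff_delimiter(text)
    rows = parse_rows(text, delimiter)
    if not rows:
        return TablePreview([], [], [], delimiter)
    if header:
        head, body = rows[0], rows[1:]
    else:
        head = [f"column {i + 1}" for i in range(len(rows[0]))]
        body = rows
    width = len(head)
    datatypes = [
        infer_datatype(row[i] for row in body if i < len(row))
        for i in range(width)
    ]
    return TablePreview(head, body[:n], datatypes, delimiter)


def _cell_value(cell: str, spec: ColumnSpec):
    cell = cell.strip()
    if cell == "":
        return None
    if spec.datatype.startswith("list_of_"):
        inner = spec.datatype[len("list_of_"):]
        tokens = [t.strip() for t in cell.split(spec.list_delimiter or "|")]
        return coerce_value([t for t in tokens if t != ""], spec.datatype)
    return coerce_value(cell, spec.datatype)


def import_edge_list(
    rows: list[list[str]], plan: ImportPlan
) -> tuple[NetworkBundle, ImportReport]:
    """Materialize an edge list; returns the bundle plus a row-level report.

    Rows with an empty source key are skipped and reported; conflicting node
    attribute writes are last-row-wins with a warning.
    """
    report = ImportReport()
    bundle = NetworkBundle()
    node_by_key: dict[str, int] = {}

    col_index = {spec.name: i for i, spec in enumerate(plan.columns)}
    source_spec = next(c for c in plan.columns if c.role == "source_id")
    target_spec = next((c for c in plan.columns if c.role == "target_id"), None)

    def node_for(key: str) -> int:
        if key not in node_by_key:
            nid = bundle.add_node(attrs={"name": key})
            node_by_key[key] = nid
        return node_by_key[key]

    def write_node_attr(nid: int, spec: ColumnSpec, cell: str, row_no: int) -> None:
        value = _cell_value(cell, spec)
        if value is None:
            return
        existing = bundle.node_table.rows.get(nid, {}).get(spec.attribute)
        if existing is not None and existing != value:
            report.warnings.append(
                f"row {row_no}: attribute {spec.attribute!r} on node {nid} "
                f"overwritten ({existing!r} -> {value!r})"
            )
        bundle.node_table.set_value(nid, spec.attribute, value)

    for row_no, row in enumerate(rows, start=1):
        source_key = (row[col_index[source_spec.name]]
                      if col_index[source_spec.name] < len(row) else "").strip()
        if source_key == "":
            report.skipped_rows.append((row_no, "empty source key"))
            continue
        target_key = ""
        if target_spec is not None and col_index[target_spec.name] < len(row):
            target_key = row[col_index[target_spec.name]].strip()

        try:
            source_id = node_for(source_key)
            target_id = node_for(target_key) if target_key else None
            edge_id = (bundle.add_edge(source_id, target_id)
                       if target_id is not None else None)
            for i, spec in enumerate(plan.columns):
                if spec.role in ("source_id", "target_id", "ignore"):
                    continue
                cell = row[i] if i < len(row) else ""
                if spec.role == "source_attr":
                    write_node_attr(source_id, spec, cell, row_no)
                elif spec.role == "target_attr" and target_id is not None:
                    write_node_attr(target_id, spec, cell, row_no)
                elif spec.role == "edge_attr" and edge_id is not None:
                    value = _cell_value(cell, spec)
                    if value is not None:
                        bundle.edge_table.set_value(edge_id, spec.attribute, value)
        except TypeCoercionError as exc:
            report.skipped_rows.append((row_no, str(exc)))
            continue

    bundle.check_integrity()
    return bundle, report


def import_text(text: str, plan: ImportPlan) -> tuple[NetworkBundle, ImportReport]:
    """Convenience wrapper: parse text per the plan, then import."""
    rows = parse_rows(text, plan.delimiter)
    if not rows:
        raise CxParseError("empty tabular input", 0)
    body = rows[1:] if plan.header else rows
    if plan.header and len(rows[0]) != len(plan.columns):
        raise ValueError(
            f"plan covers {len(plan.columns)} columns but file has {len(rows[0])}"
        )
    return import_edge_list(body, plan)
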