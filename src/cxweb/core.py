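"""In-memory network, table, and workspace model.

The model mirrors the four client-side stores of the browser platform it is
compatible with: networks (a directed multigraph with integer element ids),
attribute tables for nodes / edges / the network itself, a visual style, and a
workspace that groups networks together with selection and panel state.

Attribute handling is strict: every stored value must conform to its declared
datatype, and coercion never performs a silent lossy cast.  Undeclared
attributes are auto-declared from the first value's inferred type, matching the
behaviour of a schemaless table editor.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Optional

import networkx as nx

from .errors import (
    ConflictError,
    CxParseError,
    ElementReferenceError,
    TypeCoercionError,
)

# ---------------------------------------------------------------------------
# Datatypes and coercion
# ---------------------------------------------------------------------------

SCALAR_DATATYPES = ("string", "integer", "long", "double", "boolean")
LIST_DATATYPES = tuple(f"list_of_{t}" for t in SCALAR_DATATYPES)
DATATYPES = SCALAR_DATATYPES + LIST_DATATYPES

#: integers beyond this cannot be represented exactly as a JSON double
MAX_SAFE_INTEGER = 2**53 - 1


def coerce_value(value: Any, datatype: str) -> Any:
    """Coerce ``value`` to ``datatype``, raising :class:`TypeCoercionError`.

    Strings are parsed for numeric types ("3" -> 3.0 for a double); booleans
    accept only ``True``/``False`` or the strings ``"true"``/``"false"``
    (case-insensitive) — tokens like ``"yes"`` are rejected.  Lossy casts
    (3.5 -> integer) are rejected.
    """
    if datatype not in DATATYPES:
        raise TypeCoercionError(f"unknown datatype {datatype!r}")
    if datatype.startswith("list_of_"):
        inner = datatype[len("list_of_"):]
        if not isinstance(value, (list, tuple)):
            raise TypeCoercionError(
                f"expected a list for {datatype}, got {type(value).__name__}"
            )
        return [coerce_value(v, inner) for v in value]
    if datatype == "string":
        if isinstance(value, str):
            return value
        raise TypeCoercionError(f"expected string, got {type(value).__name__}")
    if datatype == "boolean":
        if isinstance(value, bool):
            return value
        if isinstance(value, str) and value.lower() in ("true", "false"):
            return value.lower() == "true"
        raise TypeCoercionError(f"not a boolean: {value!r} (only true/false accepted)")
    if datatype in ("integer", "long"):
        if isinstance(value, bool):
            raise TypeCoercionError(f"boolean is not an {datatype}")
        if isinstance(value, int):
            return value
        if isinstance(value, float) and value.is_integer():
            return int(value)
        if isinstance(value, str):
            try:
                return int(value.strip())
            except ValueError:
                raise TypeCoercionError(f"not an {datatype}: {value!r}") from None
        raise TypeCoercionError(f"not an {datatype}: {value!r}")
    if datatype == "double":
        if isinstance(value, bool):
            raise TypeCoercionError("boolean is not a double")
        if isinstance(value, (int, float)):
            return float(value)
        if isinstance(value, str):
            try:
                return float(value.strip())
            except ValueError:
                raise TypeCoercionError(f"not a double: {value!r}") from None
        raise TypeCoercionError(f"not a double: {value!r}")
    raise TypeCoercionError(f"unknown datatype {datatype!r}")  # pragma: no cover


def infer_datatype_of_value(value: Any) -> str:
    """Infer a declaration datatype from a Python value."""
    if isinstance(value, bool):
        return "boolean"
    if isinstance(value, int):
        return "long" if abs(value) > 2**31 - 1 else "integer"
    if isinstance(value, float):
        return "double"
    if isinstance(value, (list, tuple)):
        if not value:
            return "list_of_string"
        return "list_of_" + infer_datatype_of_value(value[0]).replace("list_of_", "")
    return "string"


# ---------------------------------------------------------------------------
# Attribute tables
# ---------------------------------------------------------------------------


@dataclass
class AttributeDeclaration:
    """Schema entry for one attribute column.

    ``alias`` is the short key used in serialized element records; ``default``
    applies when an element carries no explicit value.
    """

    name: str
    datatype: str
    default: Any = None
    alias: Optional[str] = None

    def __post_init__(self) -> None:
        if self.datatype not in DATATYPES:
            raise TypeCoercionError(f"unknown datatype {self.datatype!r}")
        if self.default is not None:
            self.default = coerce_value(self.default, self.datatype)


class ElementTable:
    """Attribute storage for one scope (nodes, edges, or the network).

    Rows are keyed by element id; the network scope uses the single key 0.
    """

    def __init__(self, scope: str):
        if scope not in ("nodes", "edges", "network"):
            raise ValueError(f"bad table scope {scope!r}")
        self.scope = scope
        self.declarations: dict[str, AttributeDeclaration] = {}
        self.rows: dict[int, dict[str, Any]] = {}

    def declare(self, decl: AttributeDeclaration, *, replace: bool = False) -> None:
        if decl.name in self.declarations and not replace:
            existing = self.declarations[decl.name]
            if existing.datatype != decl.datatype:
                raise ConflictError(
                    f"attribute {decl.name!r} already declared as {existing.datatype}"
                )
            return
        self.declarations[decl.name] = decl

    def set_value(self, element: int, name: str, value: Any) -> None:
        """Set one attribute value, auto-declaring from the inferred type."""
        if name not in self.declarations:
            self.declare(AttributeDeclaration(name, infer_datatype_of_value(value)))
        decl = self.declarations[name]
        try:
            coerced = coerce_value(value, decl.datatype)
        except TypeCoercionError as exc:
            raise TypeCoercionError(
                f"attribute {name!r} on {self.scope} element {element}: {exc}"
            ) from None
        self.rows.setdefault(element, {})[name] = coerced

    def set_row(self, element: int, attrs: Mapping[str, Any]) -> None:
        for name, value in attrs.items():
            self.set_value(element, name, value)

    def get_value(self, element: int, name: str, default: Any = None) -> Any:
        row = self.rows.get(element)
        if row is not None and name in row:
            return row[name]
        decl = self.declarations.get(name)
        if decl is not None and decl.default is not None:
            return decl.default
        return default

    def drop_row(self, element: int) -> None:
        self.rows.pop(element, None)

    def copy(self) -> "ElementTable":
        out = ElementTable(self.scope)
        for d in self.declarations.values():
            out.declarations[d.name] = AttributeDeclaration(
                d.name, d.datatype, d.default, d.alias
            )
        out.rows = {k: dict(v) for k, v in self.rows.items()}
        return out


# ---------------------------------------------------------------------------
# Network bundle
# ---------------------------------------------------------------------------


class NetworkBundle:
    """A directed multigraph plus its tables, style, layout, and bypasses.

    The graph lives in a :class:`networkx.MultiDiGraph` whose edge keys are the
    integer edge ids; parallel edges and self-loops are permitted.  Unknown
    serialized aspects are preserved verbatim in ``opaque_aspects`` so that a
    document produced by a richer tool survives a round-trip untouched.
    """

    def __init__(self) -> None:
        from .style import VisualStyle  # local import: style has no core dep

        self.graph = nx.MultiDiGraph()
        self.node_table = ElementTable("nodes")
        self.edge_table = ElementTable("edges")
        self.network_table = ElementTable("network")
        self.style: "VisualStyle" = VisualStyle.default()
        self.node_bypasses: dict[int, dict[str, Any]] = {}
        self.edge_bypasses: dict[int, dict[str, Any]] = {}
        self.opaque_aspects: list[tuple[str, Any]] = []
        self._edge_endpoints: dict[int, tuple[int, int]] = {}

    # -- topology ----------------------------------------------------------

    @property
    def node_ids(self) -> list[int]:
        return sorted(self.graph.nodes)

    @property
    def edge_ids(self) -> list[int]:
        return sorted(self._edge_endpoints)

    def node_count(self) -> int:
        return self.graph.number_of_nodes()

    def edge_count(self) -> int:
        return len(self._edge_endpoints)

    def has_node(self, node_id: int) -> bool:
        return self.graph.has_node(node_id)

    def has_edge(self, edge_id: int) -> bool:
        return edge_id in self._edge_endpoints

    def edge_endpoints(self, edge_id: int) -> tuple[int, int]:
        try:
            return self._edge_endpoints[edge_id]
        except KeyError:
            raise ElementReferenceError(f"no edge with id {edge_id}") from None

    def _next_id(self, existing: Iterable[int]) -> int:
        ids = list(existing)
        return max(ids) + 1 if ids else 0

    def add_node(
        self,
        node_id: Optional[int] = None,
        attrs: Optional[Mapping[str, Any]] = None,
        *,
        x: Optional[float] = None,
        y: Optional[float] = None,
        z: Optional[float] = None,
    ) -> int:
        """Add a node, returning its id (next free integer when omitted)."""
        if node_id is None:
            node_id = self._next_id(self.graph.nodes)
        else:
            node_id = int(node_id)
            if node_id < 0:
                raise ValueError("node ids must be non-negative")
            if self.graph.has_node(node_id):
                raise ConflictError(f"node id {node_id} already exists")
        self.graph.add_node(node_id)
        if x is not None or y is not None:
            self.set_position(node_id, x or 0.0, y or 0.0, z)
        if attrs:
            self.node_table.set_row(node_id, attrs)
        return node_id

    def add_edge(
        self,
        source: int,
        target: int,
        attrs: Optional[Mapping[str, Any]] = None,
        edge_id: Optional[int] = None,
    ) -> int:
        """Add a directed edge; endpoints must already exist."""
        for endpoint in (source, target):
            if not self.graph.has_node(endpoint):
                raise ElementReferenceError(f"edge endpoint {endpoint} is not a node")
        if edge_id is None:
            edge_id = self._next_id(self._edge_endpoints)
        else:
            edge_id = int(edge_id)
            if edge_id < 0:
                raise ValueError("edge ids must be non-negative")
            if edge_id in self._edge_endpoints:
                raise ConflictError(f"edge id {edge_id} already exists")
        self.graph.add_edge(source, target, key=edge_id)
        self._edge_endpoints[edge_id] = (source, target)
        if attrs:
            self.edge_table.set_row(edge_id, attrs)
        return edge_id

    def remove_node(self, node_id: int) -> None:
        if not self.graph.has_node(node_id):
            raise ElementReferenceError(f"no node with id {node_id}")
        for eid in [e for e, (s, t) in self._edge_endpoints.items()
                    if s == node_id or t == node_id]:
            self.remove_edge(eid)
        self.graph.remove_node(node_id)
        self.node_table.drop_row(node_id)
        self.node_bypasses.pop(node_id, None)

    def remove_edge(self, edge_id: int) -> None:
        s, t = self.edge_endpoints(edge_id)
        self.graph.remove_edge(s, t, key=edge_id)
        del self._edge_endpoints[edge_id]
        self.edge_table.drop_row(edge_id)
        self.edge_bypasses.pop(edge_id, None)

    # -- layout ------------------------------------------------------------

    def set_position(
        self, node_id: int, x: float, y: float, z: Optional[float] = None
    ) -> None:
        if not self.graph.has_node(node_id):
            raise ElementReferenceError(f"no node with id {node_id}")
        data = self.graph.nodes[node_id]
        data["x"] = float(x)
        data["y"] = float(y)
        if z is not None:
            data["z"] = float(z)
        else:
            data.pop("z", None)

    def position(self, node_id: int) -> Optional[tuple[float, ...]]:
        data = self.graph.nodes[node_id]
        if "x" not in data:
            return None
        if "z" in data:
            return (data["x"], data["y"], data["z"])
        return (data["x"], data["y"])

    # -- integrity ---------------------------------------------------------

    def check_integrity(self) -> None:
        """Assert referential integrity; raises on violation."""
        for eid, (s, t) in self._edge_endpoints.items():
            if not self.graph.has_node(s) or not self.graph.has_node(t):
                raise ElementReferenceError(
                    f"edge {eid} references missing endpoint ({s}, {t})"
                )
        for table, ids in (
            (self.node_table, set(self.graph.nodes)),
            (self.edge_table, set(self._edge_endpoints)),
        ):
            for row_id in table.rows:
                if row_id not in ids:
                    raise ElementReferenceError(
                        f"{table.scope} table row {row_id} has no element"
                    )


# ---------------------------------------------------------------------------
# Size limits
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SizeLimitPolicy:
    """Import limits of the browser platform.

    Defaults mirror the deployed limits: at most 20 000 edges, at most 26 000
    nodes and edges combined, and a document strictly smaller than 500 MB.
    """

    max_edges: int = 20_000
    max_combined: int = 26_000
    max_bytes: int = 500 * 1000 * 1000

    def __post_init__(self) -> None:
        if self.max_edges <= 0 or self.max_combined <= 0 or self.max_bytes <= 0:
            raise ValueError("size limits must be strictly positive")


@dataclass(frozen=True)
class SizeDecision:
    accepted: bool
    reason: Optional[str] = None  # "edge limit" | "combined limit" | "file size"

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.accepted


def check_size_limits(
    node_count: int, edge_count: int, policy: SizeLimitPolicy = SizeLimitPolicy()
) -> SizeDecision:
    """Accept iff both element caps hold; the reason names the violated cap."""
    if node_count < 0 or edge_count < 0:
        raise ValueError("counts must be non-negative")
    if edge_count > policy.max_edges:
        return SizeDecision(False, "edge limit")
    if node_count + edge_count > policy.max_combined:
        return SizeDecision(False, "combined limit")
    return SizeDecision(True)


# ---------------------------------------------------------------------------
# Workspace
# ---------------------------------------------------------------------------

PANELS = ("left", "right", "bottom")


@dataclass
class ServiceRegistration:
    url: str
    enabled: bool = True


class Workspace:
    """Application state: named networks, selection, panels, services."""

    def __init__(self) -> None:
        self.networks: dict[str, NetworkBundle] = {}
        self.current_network: Optional[str] = None
        self.selections: dict[str, tuple[set[int], set[int]]] = {}
        self.panel_states: dict[str, str] = {p: "open" for p in PANELS}
        self.active_table_tab: int = 0
        self.installed_services: list[ServiceRegistration] = []

    def add_network(self, name: str, bundle: NetworkBundle, *, current: bool = True) -> None:
        if name in self.networks:
            raise ConflictError(f"network name {name!r} already in workspace")
        self.networks[name] = bundle
        self.selections[name] = (set(), set())
        if current or self.current_network is None:
            self.current_network = name

    def fresh_name(self, base: str) -> str:
        if base not in self.networks:
            return base
        i = 2
        while f"{base} ({i})" in self.networks:
            i += 1
        return f"{base} ({i})"

    def get_current(self) -> NetworkBundle:
        if self.current_network is None:
            raise ElementReferenceError("no current network")
        return self.networks[self.current_network]

    def set_selection(self, name: str, nodes: set[int], edges: set[int]) -> None:
        bundle = self.networks[name]
        for n in nodes:
            if not bundle.has_node(n):
                raise ElementReferenceError(f"selected node {n} not in network")
        for e in edges:
            if not bundle.has_edge(e):
                raise ElementReferenceError(f"selected edge {e} not in network")
        self.selections[name] = (set(nodes), set(edges))

    def set_panel(self, panel: str, state: str) -> None:
        if panel not in PANELS or state not in ("open", "closed"):
            raise ValueError(f"bad panel state {panel}={state}")
        self.panel_states[panel] = state


def save_workspace(ws: Workspace, destination) -> None:
    """Write a workspace snapshot (one JSON document) to a writable sink."""
    from .cx2 import serialize_cx2_obj

    doc = {
        "formatVersion": 1,
        "networks": [
            {
                "name": name,
                "cx2": serialize_cx2_obj(bundle),
                "selection": {
                    "nodes": sorted(ws.selections[name][0]),
                    "edges": sorted(ws.selections[name][1]),
                },
            }
            for name, bundle in ws.networks.items()
        ],
        "currentNetwork": ws.current_network,
        "panelStates": dict(ws.panel_states),
        "activeTableTab": ws.active_table_tab,
        "installedServices": [
            {"url": s.url, "enabled": s.enabled} for s in ws.installed_services
        ],
    }
    text = json.dumps(doc, separators=(",", ":"))
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        with open(destination, "w") as fh:
            fh.write(text)


def load_workspace(source) -> Workspace:
    """Read a snapshot back; inverse of :func:`save_workspace`."""
    from .cx2 import parse_cx2_obj

    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CxParseError(f"corrupt workspace snapshot: {exc.msg}", exc.pos) from None
    if not isinstance(doc, dict) or "networks" not in doc:
        raise CxParseError("corrupt workspace snapshot: missing networks", 0)
    ws = Workspace()
    for entry in doc["networks"]:
        bundle = parse_cx2_obj(entry["cx2"])
        ws.add_network(entry["name"], bundle, current=False)
        sel = entry.get("selection", {})
        ws.set_selection(
            entry["name"],
            set(sel.get("nodes", [])),
            set(sel.get("edges", [])),
        )
    ws.current_network = doc.get("currentNetwork")
    if ws.current_network is not None and ws.current_network not in ws.networks:
        raise CxParseError("currentNetwork names an absent network", 0)
    for panel, state in doc.get("panelStates", {}).items():
        ws.set_panel(panel, state)
    ws.active_table_tab = int(doc.get("activeTableTab", 0))
    ws.installed_services = [
        ServiceRegistration(s["url"], bool(s.get("enabled", True)))
        for s in doc.get("installedServices", [])
    ]
    return ws
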