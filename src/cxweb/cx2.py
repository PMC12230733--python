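"""CX2 document reader, writer, and validator.

CX2 is the JSON exchange format of the Cytoscape ecosystem: a document is a
JSON array whose first element is a version descriptor and whose remaining
elements are single-key "aspect" objects, each aspect an ordered list of
records sharing a schema.  Recognized aspects (attribute declarations,
network attributes, nodes, edges, visual properties, bypasses, metaData,
status) populate a :class:`~cxweb.core.NetworkBundle`; everything else is an
"opaque aspect" preserved verbatim and re-emitted on write, so documents
produced by richer tools survive a round-trip untouched.

Serialization is canonical and deterministic: aspects are written in a fixed
order (opaque aspects keep their original relative order) with compact JSON,
so serializing the same bundle twice yields byte-identical text.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Any, Optional

from .core import (
    MAX_SAFE_INTEGER,
    AttributeDeclaration,
    ElementTable,
    NetworkBundle,
    SizeDecision,
    SizeLimitPolicy,
    check_size_limits,
    coerce_value,
    infer_datatype_of_value,
)
from .errors import CxParseError, CxValidationError
from .style import (
    VISUAL_PROPERTIES,
    ContinuousControlPoint,
    MappingDefinition,
    VisualStyle,
    coerce_visual_value,
)

CX_VERSION = "2.0"

KNOWN_ASPECTS = (
    "attributeDeclarations",
    "networkAttributes",
    "nodes",
    "edges",
    "visualProperties",
    "nodeBypasses",
    "edgeBypasses",
    "metaData",
    "status",
)

# canonical write order for recognized aspects; opaque ones go before status
_WRITE_ORDER = (
    "metaData",
    "attributeDeclarations",
    "networkAttributes",
    "nodes",
    "edges",
    "visualProperties",
    "nodeBypasses",
    "edgeBypasses",
)


@dataclass
class Cx2Aspect:
    name: str
    elements: list[Any]


@dataclass
class Cx2Document:
    version: str
    has_fragments: bool
    aspects: list[Cx2Aspect]
    status_success: bool = True
    status_error: str = ""

    def aspect(self, name: str) -> Optional[Cx2Aspect]:
        for a in self.aspects:
            if a.name == name:
                return a
        return None


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # error | warning
    aspect: str
    index: Optional[int]
    message: str

    def __post_init__(self) -> None:
        if not self.message:
            raise ValueError("issue message must be non-empty")


# ---------------------------------------------------------------------------
# Document-level reading
# ---------------------------------------------------------------------------


def read_document(text: str) -> Cx2Document:
    """Parse raw text into an aspect-structured document (no semantics yet)."""
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CxParseError(f"not valid JSON: {exc.msg}", exc.pos) from None
    return _document_from_obj(raw)


def _document_from_obj(raw: Any) -> Cx2Document:
    if not isinstance(raw, list) or not raw:
        raise CxParseError("a CX2 document is a non-empty JSON array", 0)
    head = raw[0]
    if not isinstance(head, dict) or "CXVersion" not in head:
        raise CxParseError("first element must be the version descriptor", 0)
    version = str(head["CXVersion"])
    has_fragments = bool(head.get("hasFragments", False))
    aspects: list[Cx2Aspect] = []
    status_success, status_error = True, ""
    for i, entry in enumerate(raw[1:], start=1):
        if not isinstance(entry, dict) or len(entry) != 1:
            raise CxParseError(
                f"document element {i} is not a single-key aspect object", i
            )
        (name, elements), = entry.items()
        if not isinstance(elements, list):
            raise CxParseError(f"aspect {name!r} payload is not a list", i)
        if name == "status":
            if elements and isinstance(elements[0], dict):
                status_success = bool(elements[0].get("success", True))
                status_error = str(elements[0].get("error", ""))
            continue
        aspects.append(Cx2Aspect(name, elements))
    return Cx2Document(version, has_fragments, aspects, status_success, status_error)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

_DECL_SCOPES = ("nodes", "edges", "networkAttributes")


def _iter_declarations(doc: Cx2Document):
    aspect = doc.aspect("attributeDeclarations")
    if aspect is None:
        return
    for element in aspect.elements:
        if not isinstance(element, dict):
            continue
        for scope in _DECL_SCOPES:
            for name, spec in (element.get(scope) or {}).items():
                yield scope, name, spec if isinstance(spec, dict) else {}


def validate_cx2(doc: Cx2Document) -> list[ValidationIssue]:
    """Check structural rules; returns issues ordered by aspect then index."""
    issues: list[ValidationIssue] = []

    def err(aspect: str, index: Optional[int], message: str) -> None:
        issues.append(ValidationIssue("error", aspect, index, message))

    def warn(aspect: str, index: Optional[int], message: str) -> None:
        issues.append(ValidationIssue("warning", aspect, index, message))

    if doc.has_fragments:
        err("", None, "fragmented CX2 (hasFragments=true) is not supported")

    seen_names: set[str] = set()
    for a in doc.aspects:
        if a.name in seen_names:
            err(a.name, None, f"duplicate aspect {a.name!r}")
        seen_names.add(a.name)

    from .core import DATATYPES

    declared: dict[str, set[str]] = {s: set() for s in _DECL_SCOPES}
    for scope, name, spec in _iter_declarations(doc):
        if name in declared[scope]:
            err("attributeDeclarations", None,
                f"duplicate declaration {name!r} in scope {scope}")
        declared[scope].add(name)
        dtype = spec.get("d", "string")
        if dtype not in DATATYPES:
            err("attributeDeclarations", None,
                f"unknown datatype {dtype!r} for attribute {name!r}")

    node_ids: set[int] = set()
    nodes_aspect = doc.aspect("nodes")
    if nodes_aspect is not None:
        for i, record in enumerate(nodes_aspect.elements):
            nid = record.get("id") if isinstance(record, dict) else None
            if not isinstance(nid, int) or isinstance(nid, bool) or nid < 0:
                err("nodes", i, "node record lacks a non-negative integer id")
                continue
            if nid in node_ids:
                err("nodes", i, f"duplicate node id {nid}")
            node_ids.add(nid)

    edge_ids: set[int] = set()
    edges_aspect = doc.aspect("edges")
    if edges_aspect is not None:
        for i, record in enumerate(edges_aspect.elements):
            if not isinstance(record, dict):
                err("edges", i, "edge record is not an object")
                continue
            eid = record.get("id")
            if not isinstance(eid, int) or isinstance(eid, bool) or eid < 0:
                err("edges", i, "edge record lacks a non-negative integer id")
            elif eid in edge_ids:
                err("edges", i, f"duplicate edge id {eid}")
            else:
                edge_ids.add(eid)
            for end in ("s", "t"):
                ref = record.get(end)
                if ref not in node_ids:
                    err("edges", i, f"edge references absent node {ref!r} ({end})")

    # oversized longs lose precision in JSON doubles
    for scope, name, spec in _iter_declarations(doc):
        if spec.get("d") in ("long", "list_of_long"):
            default = spec.get("v")
            if isinstance(default, int) and abs(default) > MAX_SAFE_INTEGER:
                warn("attributeDeclarations", None,
                     f"long default of {name!r} exceeds 2^53-1")

    vp_aspect = doc.aspect("visualProperties")
    if vp_aspect is not None:
        for i, element in enumerate(vp_aspect.elements):
            if not isinstance(element, dict):
                err("visualProperties", i, "visual properties element is not an object")
                continue
            for side, scope in (("nodeMapping", "nodes"), ("edgeMapping", "edges")):
                for prop, mapping in (element.get(side) or {}).items():
                    attr = (mapping.get("definition") or {}).get("attribute")
                    if attr and attr not in declared[scope]:
                        warn("visualProperties", i,
                             f"mapping on {prop} references undeclared "
                             f"attribute {attr!r} (resolution falls back to default)")

    order = {name: i for i, name in enumerate(
        [a.name for a in doc.aspects] + [""]
    )}
    issues.sort(key=lambda iss: (order.get(iss.aspect, len(order)),
                                 -1 if iss.index is None else iss.index))
    return issues


# ---------------------------------------------------------------------------
# Parsing into a bundle
# ---------------------------------------------------------------------------


def _apply_declarations(doc: Cx2Document, bundle: NetworkBundle) -> dict[str, dict[str, str]]:
    """Install declarations; returns alias->name maps per scope."""
    alias_maps: dict[str, dict[str, str]] = {s: {} for s in _DECL_SCOPES}
    table_for = {
        "nodes": bundle.node_table,
        "edges": bundle.edge_table,
        "networkAttributes": bundle.network_table,
    }
    for scope, name, spec in _iter_declarations(doc):
        decl = AttributeDeclaration(
            name,
            spec.get("d", "string"),
            spec.get("v"),
            spec.get("a"),
        )
        table_for[scope].declare(decl, replace=True)
        if decl.alias:
            alias_maps[scope][decl.alias] = name
    return alias_maps


def _expand_record(values: dict[str, Any], aliases: dict[str, str]) -> dict[str, Any]:
    return {aliases.get(k, k): v for k, v in values.items()}


def _mapping_from_json(obj: dict[str, Any]) -> MappingDefinition:
    kind = {"DISCRETE": "discrete", "CONTINUOUS": "continuous",
            "PASSTHROUGH": "passthrough"}.get(obj.get("type", ""))
    if kind is None:
        raise CxValidationError(f"unknown mapping type {obj.get('type')!r}")
    definition = obj.get("definition") or {}
    attribute = definition.get("attribute", "")
    if kind == "discrete":
        pairs = [(e.get("v"), e.get("vp")) for e in definition.get("map", [])]
        return MappingDefinition("discrete", attribute, discrete_map=pairs)
    if kind == "continuous":
        points = [
            ContinuousControlPoint(float(e["v"]), e["vp"])
            for e in definition.get("map", [])
        ]
        return MappingDefinition("continuous", attribute, continuous_points=points)
    return MappingDefinition("passthrough", attribute)


def _mapping_to_json(definition: MappingDefinition) -> dict[str, Any]:
    if definition.kind == "discrete":
        return {
            "type": "DISCRETE",
            "definition": {
                "attribute": definition.attribute,
                "map": [{"v": k, "vp": v} for k, v in definition.discrete_map],
            },
        }
    if definition.kind == "continuous":
        return {
            "type": "CONTINUOUS",
            "definition": {
                "attribute": definition.attribute,
                "map": [
                    {"v": p.threshold, "vp": p.value}
                    for p in definition.continuous_points
                ],
            },
        }
    return {"type": "PASSTHROUGH", "definition": {"attribute": definition.attribute}}


def _style_from_aspect(elements: list[Any]) -> VisualStyle:
    style = VisualStyle.default()
    for element in elements:
        if not isinstance(element, dict):
            continue
        defaults = element.get("default") or {}
        for side in ("network", "node", "edge"):
            for prop, value in (defaults.get(side) or {}).items():
                if prop in VISUAL_PROPERTIES:
                    style.set_default(prop, value)
        for side in ("nodeMapping", "edgeMapping"):
            for prop, mapping_obj in (element.get(side) or {}).items():
                if prop in VISUAL_PROPERTIES:
                    style.set_mapping(prop, _mapping_from_json(mapping_obj))
    return style


def _style_to_aspect(style: VisualStyle) -> list[Any]:
    defaults: dict[str, dict[str, Any]] = {"network": {}, "node": {}, "edge": {}}
    for prop, value in style.defaults.items():
        defaults[VISUAL_PROPERTIES[prop].applies_to][prop] = value
    node_maps = {
        p: _mapping_to_json(d) for p, d in style.mappings.items()
        if VISUAL_PROPERTIES[p].applies_to == "node"
    }
    edge_maps = {
        p: _mapping_to_json(d) for p, d in style.mappings.items()
        if VISUAL_PROPERTIES[p].applies_to == "edge"
    }
    element: dict[str, Any] = {"default": defaults}
    if node_maps:
        element["nodeMapping"] = dict(sorted(node_maps.items()))
    if edge_maps:
        element["edgeMapping"] = dict(sorted(edge_maps.items()))
    return [element]


def parse_cx2_obj(raw: Any) -> NetworkBundle:
    """Build a bundle from an already-decoded CX2 array."""
    doc = _document_from_obj(raw)
    issues = validate_cx2(doc)
    errors = [i for i in issues if i.severity == "error"]
    if errors:
        first = errors[0]
        where = f" (aspect {first.aspect!r}"
        where += f", element {first.index})" if first.index is not None else ")"
        raise CxValidationError(first.message + where)

    bundle = NetworkBundle()
    alias_maps = _apply_declarations(doc, bundle)

    aspect = doc.aspect("networkAttributes")
    if aspect is not None:
        for element in aspect.elements:
            if isinstance(element, dict):
                bundle.network_table.set_row(
                    0, _expand_record(element, alias_maps["networkAttributes"])
                )

    aspect = doc.aspect("nodes")
    if aspect is not None:
        for record in aspect.elements:
            nid = bundle.add_node(record["id"])
            if "x" in record and "y" in record:
                bundle.set_position(nid, record["x"], record["y"], record.get("z"))
            values = _expand_record(record.get("v") or {}, alias_maps["nodes"])
            bundle.node_table.set_row(nid, values)

    aspect = doc.aspect("edges")
    if aspect is not None:
        for record in aspect.elements:
            eid = bundle.add_edge(record["s"], record["t"], edge_id=record["id"])
            values = _expand_record(record.get("v") or {}, alias_maps["edges"])
            bundle.edge_table.set_row(eid, values)

    aspect = doc.aspect("visualProperties")
    if aspect is not None:
        bundle.style = _style_from_aspect(aspect.elements)

    for name, bypasses in (("nodeBypasses", bundle.node_bypasses),
                           ("edgeBypasses", bundle.edge_bypasses)):
        aspect = doc.aspect(name)
        if aspect is None:
            continue
        for record in aspect.elements:
            element_id = record["id"]
            coerced = {}
            for prop, value in (record.get("v") or {}).items():
                if prop in VISUAL_PROPERTIES:
                    coerced[prop] = coerce_visual_value(value, VISUAL_PROPERTIES[prop])
            bypasses[element_id] = coerced

    for a in doc.aspects:
        if a.name not in KNOWN_ASPECTS:
            bundle.opaque_aspects.append((a.name, a.elements))

    bundle.check_integrity()
    return bundle


def parse_cx2(text: str) -> NetworkBundle:
    """Parse CX2 text into a network bundle (see module docstring)."""
    try:
        raw = json.loads(text)
    except json.JSONDecodeError as exc:
        raise CxParseError(f"not valid JSON: {exc.msg}", exc.pos) from None
    return parse_cx2_obj(raw)


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _declarations_to_json(table: ElementTable) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for name in sorted(table.declarations):
        decl = table.declarations[name]
        spec: dict[str, Any] = {"d": decl.datatype}
        if decl.default is not None:
            spec["v"] = decl.default
        if decl.alias:
            spec["a"] = decl.alias
        out[name] = spec
    return out


def _contract_record(values: dict[str, Any], table: ElementTable) -> dict[str, Any]:
    out = {}
    for name in sorted(values):
        decl = table.declarations.get(name)
        key = decl.alias if decl is not None and decl.alias else name
        out[key] = values[name]
    return out


def serialize_cx2_obj(bundle: NetworkBundle) -> list[Any]:
    """Serialize a bundle to a CX2 array (decoded JSON form)."""
    nodes = []
    for nid in bundle.node_ids:
        record: dict[str, Any] = {"id": nid}
        pos = bundle.position(nid)
        if pos is not None:
            record["x"], record["y"] = pos[0], pos[1]
            if len(pos) == 3:
                record["z"] = pos[2]
        values = bundle.node_table.rows.get(nid) or {}
        if values:
            record["v"] = _contract_record(values, bundle.node_table)
        nodes.append(record)

    edges = []
    for eid in bundle.edge_ids:
        s, t = bundle.edge_endpoints(eid)
        record = {"id": eid, "s": s, "t": t}
        values = bundle.edge_table.rows.get(eid) or {}
        if values:
            record["v"] = _contract_record(values, bundle.edge_table)
        edges.append(record)

    aspects: dict[str, list[Any]] = {}
    declarations = {
        "nodes": _declarations_to_json(bundle.node_table),
        "edges": _declarations_to_json(bundle.edge_table),
        "networkAttributes": _declarations_to_json(bundle.network_table),
    }
    declarations = {k: v for k, v in declarations.items() if v}
    aspects["attributeDeclarations"] = [declarations] if declarations else []
    net_row = bundle.network_table.rows.get(0) or {}
    aspects["networkAttributes"] = (
        [_contract_record(net_row, bundle.network_table)] if net_row else []
    )
    aspects["nodes"] = nodes
    aspects["edges"] = edges
    aspects["visualProperties"] = _style_to_aspect(bundle.style)
    aspects["nodeBypasses"] = [
        {"id": nid, "v": dict(sorted(props.items()))}
        for nid, props in sorted(bundle.node_bypasses.items())
        if props
    ]
    aspects["edgeBypasses"] = [
        {"id": eid, "v": dict(sorted(props.items()))}
        for eid, props in sorted(bundle.edge_bypasses.items())
        if props
    ]

    ordered: list[tuple[str, list[Any]]] = []
    for name in _WRITE_ORDER:
        if name == "metaData":
            continue
        payload = aspects[name]
        if payload or name in ("nodes", "edges"):
            ordered.append((name, payload))
    for name, payload in bundle.opaque_aspects:
        ordered.append((name, payload))

    meta = [{"name": name, "elementCount": len(payload)} for name, payload in ordered]
    doc: list[Any] = [{"CXVersion": CX_VERSION, "hasFragments": False}]
    doc.append({"metaData": meta})
    for name, payload in ordered:
        doc.append({name: payload})
    doc.append({"status": [{"success": True}]})
    return doc


def serialize_cx2(bundle: NetworkBundle) -> str:
    """Serialize to canonical compact JSON text (deterministic)."""
    return json.dumps(serialize_cx2_obj(bundle), separators=(",", ":"))


# ---------------------------------------------------------------------------
# Import limits
# ---------------------------------------------------------------------------


def enforce_import_limits(
    byte_length: int,
    node_count: int,
    edge_count: int,
    policy: SizeLimitPolicy = SizeLimitPolicy(),
) -> SizeDecision:
    """Reject documents at or beyond the byte cap, then apply element caps."""
    if byte_length < 0:
        raise ValueError("byte_length must be non-negative")
    if byte_length >= policy.max_bytes:
        return SizeDecision(False, "file size")
    return check_size_limits(node_count, edge_count, policy)
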