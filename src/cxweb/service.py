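"""Service App protocol: descriptors, task lifecycle, and result actions.

A Service App is an external analysis service described entirely by data: its
metadata endpoint returns a descriptor (menu placement, input dialog
parameters, result action kinds), the client submits a task payload carrying
the current (sub)network as CX2 plus parameter values, polls the task until
terminal, and applies the typed result actions to the workspace.  The closed
action vocabulary is updateTables, addNetworks, updateSelection,
updateLayouts, updateNetwork, and openURL.

Transports are injectable: any callable ``(method, url, body) -> (status,
json_body)`` works, so the in-process :class:`ReferenceService` drives the
full protocol without sockets; a stdlib HTTP wrapper is provided for running
it as a real server.
"""

from __future__ import annotations

import json
import threading
import time
from dataclasses import dataclass, field
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Any, Callable, Optional

from .core import ServiceRegistration, Workspace
from .cx2 import parse_cx2_obj, serialize_cx2_obj
from .errors import (
    ConflictError,
    CxParseError,
    CxValidationError,
    TaskFailedError,
    TaskTimeoutError,
    TransportError,
)

ACTION_KINDS = (
    "updateTables",
    "addNetworks",
    "updateSelection",
    "updateLayouts",
    "updateNetwork",
    "openURL",
)

PARAMETER_KINDS = ("text", "number", "choice", "flag", "nodeColumn", "edgeColumn")

INPUT_SCOPES = ("all", "selected")


def split_gene_set(text: str) -> list[str]:
    """Split a comma- or space-delimited gene symbol set into clean tokens."""
    tokens: list[str] = []
    for part in text.split(","):
        tokens.extend(part.split())
    return [t.strip() for t in tokens if t.strip()]


# ---------------------------------------------------------------------------
# Descriptor
# ---------------------------------------------------------------------------


@dataclass
class ParameterSpec:
    key: str
    display_name: str
    kind: str
    required: bool = False
    default: Any = None
    choices: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in PARAMETER_KINDS:
            raise CxValidationError(f"unknown parameter kind {self.kind!r}")
        if self.kind == "choice" and not self.choices:
            raise CxValidationError(f"choice parameter {self.key!r} has no choices")


@dataclass
class ServiceDescriptor:
    name: str
    description: str = ""
    version: str = ""
    menu_path: list[str] = field(default_factory=list)
    input_scope: str = "all"
    parameters: list[ParameterSpec] = field(default_factory=list)
    actions: list[str] = field(default_factory=list)
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name:
            raise CxValidationError("service descriptor requires a name")
        if self.input_scope not in INPUT_SCOPES:
            raise CxValidationError(f"unknown input scope {self.input_scope!r}")
        bad = [a for a in self.actions if a not in ACTION_KINDS]
        if bad:
            raise CxValidationError(f"unknown result action kinds: {bad}")
        if not self.menu_path:
            self.menu_path = [self.name]

    def to_json(self) -> dict[str, Any]:
        doc = {
            "name": self.name,
            "description": self.description,
            "version": self.version,
            "menu": list(self.menu_path),
            "scope": self.input_scope,
            "parameters": [
                {
                    "key": p.key,
                    "displayName": p.display_name,
                    "kind": p.kind,
                    "required": p.required,
                    **({"default": p.default} if p.default is not None else {}),
                    **({"choices": p.choices} if p.choices else {}),
                }
                for p in self.parameters
            ],
            "actions": list(self.actions),
        }
        doc.update(self.extra)
        return doc


_DESCRIPTOR_FIELDS = {
    "name", "description", "version", "menu", "scope", "parameters", "actions"
}


def parse_descriptor(obj: dict[str, Any]) -> ServiceDescriptor:
    """Build a descriptor from metadata JSON; unknown fields pass through."""
    if not isinstance(obj, dict):
        raise CxParseError("service metadata must be a JSON object", 0)
    if not obj.get("name"):
        raise CxValidationError("service metadata lacks a name")
    parameters = [
        ParameterSpec(
            key=p["key"],
            display_name=p.get("displayName", p["key"]),
            kind=p.get("kind", "text"),
            required=bool(p.get("required", False)),
            default=p.get("default"),
            choices=list(p.get("choices", [])),
        )
        for p in obj.get("parameters", [])
    ]
    return ServiceDescriptor(
        name=obj["name"],
        description=obj.get("description", ""),
        version=obj.get("version", ""),
        menu_path=list(obj.get("menu", [])),
        input_scope=obj.get("scope", "all"),
        parameters=parameters,
        actions=list(obj.get("actions", [])),
        extra={k: v for k, v in obj.items() if k not in _DESCRIPTOR_FIELDS},
    )


# ---------------------------------------------------------------------------
# Task request
# ---------------------------------------------------------------------------


def _check_parameter(spec: ParameterSpec, value: Any, bundle) -> Any:
    if spec.kind == "number":
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise CxValidationError(f"parameter {spec.key!r} must be a number")
        return value
    if spec.kind == "flag":
        if not isinstance(value, bool):
            raise CxValidationError(f"parameter {spec.key!r} must be a flag")
        return value
    if spec.kind == "choice":
        if value not in spec.choices:
            raise CxValidationError(
                f"parameter {spec.key!r}: {value!r} not among {spec.choices}"
            )
        return value
    if spec.kind in ("nodeColumn", "edgeColumn"):
        table = bundle.node_table if spec.kind == "nodeColumn" else bundle.edge_table
        if value not in table.declarations:
            raise CxValidationError(
                f"parameter {spec.key!r}: column {value!r} not in "
                f"{table.scope} table"
            )
        return value
    if not isinstance(value, str):
        raise CxValidationError(f"parameter {spec.key!r} must be text")
    return value


def build_task_request(
    desc: ServiceDescriptor, ws: Workspace, inputs: dict[str, Any]
) -> dict[str, Any]:
    """Assemble the task payload: validated parameters plus the CX2 network.

    When the descriptor's scope is "selected", only selected nodes (and the
    edges among them) are exported; an empty selection is an error.
    """
    bundle = ws.get_current()
    values: dict[str, Any] = {}
    for spec in desc.parameters:
        if spec.key in inputs:
            values[spec.key] = _check_parameter(spec, inputs[spec.key], bundle)
        elif spec.default is not None:
            values[spec.key] = spec.default
        elif spec.required:
            raise CxValidationError(f"required parameter {spec.key!r} is missing")
    unknown = set(inputs) - {p.key for p in desc.parameters}
    if unknown:
        raise CxValidationError(f"unknown parameters: {sorted(unknown)}")

    export = bundle
    if desc.input_scope == "selected":
        selected_nodes, _ = ws.selections[ws.current_network]
        if not selected_nodes:
            raise CxValidationError(
                "service scope is 'selected' but the selection is empty"
            )
        from .core import NetworkBundle

        export = NetworkBundle()
        export.node_table = bundle.node_table.copy()
        export.node_table.rows = {
            k: v for k, v in export.node_table.rows.items() if k in selected_nodes
        }
        for nid in sorted(selected_nodes):
            export.add_node(nid)
            pos = bundle.position(nid)
            if pos is not None:
                export.set_position(nid, *pos)
        export.edge_table = bundle.edge_table.copy()
        kept = set()
        for eid in bundle.edge_ids:
            s, t = bundle.edge_endpoints(eid)
            if s in selected_nodes and t in selected_nodes:
                export.add_edge(s, t, edge_id=eid)
                kept.add(eid)
        export.edge_table.rows = {
            k: v for k, v in export.edge_table.rows.items() if k in kept
        }
        export.style = bundle.style.copy()

    return {
        "service": desc.name,
        "scope": desc.input_scope,
        "parameters": values,
        "network": serialize_cx2_obj(export),
    }


# ---------------------------------------------------------------------------
# Result actions
# ---------------------------------------------------------------------------


@dataclass
class ResultAction:
    kind: str
    payload: dict[str, Any]

    def __post_init__(self) -> None:
        if self.kind not in ACTION_KINDS:
            raise CxValidationError(f"unknown result action kind {self.kind!r}")

    def to_json(self) -> dict[str, Any]:
        return {"action": self.kind, "payload": self.payload}


def parse_result_actions(obj: Any) -> list[ResultAction]:
    if not isinstance(obj, list):
        raise CxParseError("service result must be a JSON array of actions", 0)
    actions = []
    for i, entry in enumerate(obj):
        if not isinstance(entry, dict) or "action" not in entry:
            raise CxParseError(f"result entry {i} is not an action object", i)
        actions.append(ResultAction(entry["action"], entry.get("payload", {})))
    return actions


@dataclass
class ApplyReport:
    effects: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


def apply_actions(ws: Workspace, actions: list[ResultAction]) -> tuple[Workspace, ApplyReport]:
    """Apply result actions to the workspace; openURL becomes an effect record.

    Ids in a payload that the network lacks produce warnings and are skipped;
    a malformed payload raises after prior actions have been applied.
    """
    report = ApplyReport()
    for action in actions:
        payload = action.payload
        try:
            if action.kind == "updateTables":
                bundle = ws.get_current()
                scope = payload.get("scope", "nodes")
                table = bundle.node_table if scope == "nodes" else bundle.edge_table
                has = bundle.has_node if scope == "nodes" else bundle.has_edge
                from .core import AttributeDeclaration

                for column in payload.get("columns", []):
                    table.declare(
                        AttributeDeclaration(
                            column["name"], column.get("datatype", "string")
                        )
                    )
                for raw_id, row in payload["rows"].items():
                    element = int(raw_id)
                    if not has(element):
                        report.warnings.append(
                            f"updateTables: no {scope[:-1]} with id {element}"
                        )
                        continue
                    table.set_row(element, row)
            elif action.kind == "addNetworks":
                for entry in payload["networks"]:
                    bundle = parse_cx2_obj(entry["cx2"])
                    name = ws.fresh_name(entry.get("name", "Service result"))
                    ws.add_network(name, bundle, current=False)
            elif action.kind == "updateSelection":
                bundle = ws.get_current()
                nodes, edges = set(), set()
                for nid in payload.get("nodes", []):
                    if bundle.has_node(int(nid)):
                        nodes.add(int(nid))
                    else:
                        report.warnings.append(f"updateSelection: no node {nid}")
                for eid in payload.get("edges", []):
                    if bundle.has_edge(int(eid)):
                        edges.add(int(eid))
                    else:
                        report.warnings.append(f"updateSelection: no edge {eid}")
                ws.set_selection(ws.current_network, nodes, edges)
            elif action.kind == "updateLayouts":
                bundle = ws.get_current()
                for raw_id, coords in payload["positions"].items():
                    element = int(raw_id)
                    if not bundle.has_node(element):
                        report.warnings.append(f"updateLayouts: no node {element}")
                        continue
                    bundle.set_position(element, coords[0], coords[1],
                                        coords[2] if len(coords) > 2 else None)
            elif action.kind == "updateNetwork":
                bundle = parse_cx2_obj(payload["cx2"])
                name = ws.current_network
                if name is None:
                    raise CxValidationError("updateNetwork with no current network")
                ws.networks[name] = bundle
                ws.selections[name] = (set(), set())
            elif action.kind == "openURL":
                report.effects.append(("openURL", payload["url"]))
        except (KeyError, TypeError, ValueError) as exc:
            raise CxValidationError(
                f"malformed payload for action {action.kind!r}: {exc}"
            ) from None
    return ws, report


# ---------------------------------------------------------------------------
# Registry
# ---------------------------------------------------------------------------


def register_service(ws: Workspace, url: str) -> None:
    if any(s.url == url for s in ws.installed_services):
        raise ConflictError(f"service {url!r} already registered")
    ws.installed_services.append(ServiceRegistration(url))


def list_services(ws: Workspace) -> list[ServiceRegistration]:
    return list(ws.installed_services)


# ---------------------------------------------------------------------------
# Client: submit / poll / retrieve
# ---------------------------------------------------------------------------

Transport = Callable[[str, str, Optional[dict]], tuple[int, Any]]


def fetch_descriptor(transport: Transport, base_url: str) -> ServiceDescriptor:
    status, body = transport("GET", base_url, None)
    if status != 200:
        raise TransportError(f"metadata endpoint returned {status}", status)
    return parse_descriptor(body)


def run_task(
    transport: Transport,
    base_url: str,
    payload: dict[str, Any],
    *,
    poll_interval: float = 0.5,
    max_polls: int = 240,
    sleep: Callable[[float], None] = time.sleep,
) -> list[ResultAction]:
    """Drive the full task lifecycle and return the parsed result actions."""
    base = base_url.rstrip("/")
    status, body = transport("POST", base, payload)
    if status // 100 != 2:
        raise TransportError(f"task submission returned {status}", status)
    if not isinstance(body, dict) or "id" not in body:
        raise CxParseError("submission response lacks a task id", 0)
    task_id = body["id"]

    state = None
    for attempt in range(max_polls):
        status, body = transport("GET", f"{base}/{task_id}/status", None)
        if status != 200:
            raise TransportError(f"status endpoint returned {status}", status)
        state = body.get("state")
        if state in ("complete", "failed"):
            break
        sleep(poll_interval)
    else:
        raise TaskTimeoutError(
            f"task {task_id} not terminal after {max_polls} polls"
        )
    if state == "failed":
        raise TaskFailedError(body.get("message", "task failed"))

    status, body = transport("GET", f"{base}/{task_id}/result", None)
    if status != 200:
        raise TransportError(f"result endpoint returned {status}", status)
    return parse_result_actions(body)


# ---------------------------------------------------------------------------
# Reference service
# ---------------------------------------------------------------------------


@dataclass
class _Task:
    state: str
    progress: int
    message: str
    actions: list[ResultAction] = field(default_factory=list)


class ReferenceService:
    """In-process service conforming to the protocol.

    The handler maps a task payload to result actions; it runs synchronously
    at submission, and an exception puts the task in the failed state with
    the exception message.  ``transport`` plugs straight into
    :func:`run_task`, so the whole protocol can be exercised without sockets.
    """

    def __init__(
        self,
        descriptor: ServiceDescriptor,
        handler: Callable[[dict[str, Any]], list[ResultAction]],
        base_url: str = "http://service.local/v1/service",
    ):
        self.descriptor = descriptor
        self.handler = handler
        self.base_url = base_url.rstrip("/")
        self.tasks: dict[str, _Task] = {}
        self._counter = 0

    def _submit(self, payload: dict[str, Any]) -> str:
        self._counter += 1
        task_id = f"task-{self._counter}"
        try:
            actions = self.handler(payload)
            self.tasks[task_id] = _Task("complete", 100, "", actions)
        except Exception as exc:  # handler failure becomes task state
            self.tasks[task_id] = _Task("failed", 100, str(exc))
        return task_id

    def transport(self, method: str, url: str, body: Optional[dict]) -> tuple[int, Any]:
        url = url.rstrip("/")
        if url == self.base_url:
            if method == "GET":
                return 200, self.descriptor.to_json()
            if method == "POST":
                return 200, {"id": self._submit(body or {})}
            return 405, {"error": "method not allowed"}
        if url.startswith(self.base_url + "/"):
            rest = url[len(self.base_url) + 1:].split("/")
            if len(rest) == 2:
                task_id, leaf = rest
                task = self.tasks.get(task_id)
                if task is None:
                    return 404, {"error": f"unknown task {task_id}"}
                if leaf == "status" and method == "GET":
                    return 200, {
                        "state": task.state,
                        "progress": task.progress,
                        "message": task.message,
                    }
                if leaf == "result" and method == "GET":
                    if task.state != "complete":
                        return 409, {"error": f"task is {task.state}"}
                    return 200, [a.to_json() for a in task.actions]
        return 404, {"error": "not found"}


def serve_reference_service(
    service: ReferenceService, host: str = "127.0.0.1", port: int = 0
) -> ThreadingHTTPServer:
    """Expose a reference service over real HTTP (stdlib server).

    Returns the started server; ``server.server_address`` carries the bound
    port.  Intended for the demo CLI and manual testing.
    """

    class Handler(BaseHTTPRequestHandler):
        def _dispatch(self, method: str) -> None:
            body = None
            if method == "POST":
                length = int(self.headers.get("Content-Length", 0))
                raw = self.rfile.read(length) if length else b"{}"
                try:
                    body = json.loads(raw)
                except json.JSONDecodeError:
                    self._reply(400, {"error": "invalid JSON"})
                    return
            status, payload = service.transport(
                method, service.base_url.rstrip("/") + self.path.rstrip("/"), body
            )
            self._reply(status, payload)

        def _reply(self, status: int, payload: Any) -> None:
            data = json.dumps(payload).encode()
            self.send_response(status)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(data)))
            self.end_headers()
            self.wfile.write(data)

        def do_GET(self) -> None:  # noqa: N802 - stdlib naming
            self._dispatch("GET")

        def do_POST(self) -> None:  # noqa: N802 - stdlib naming
            self._dispatch("POST")

        def log_message(self, *args: Any) -> None:
            pass

    server = ThreadingHTTPServer((host, port), Handler)
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    return server
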