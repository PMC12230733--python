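"""Shareable view-state URLs.

A share URL carries the network reference in its final path segment and the
view state in its query string: ``selectednodes`` is a ``+``-joined list of
node ids, ``selectededges`` a ``+``-joined list of ``e``-prefixed edge ids,
``left``/``right``/``bottom`` are panel flags (open/closed), and
``activeTableBrowserTab`` the active table tab index.  Absent parameters
default to empty selections, all panels open, tab 0.

Because ``+`` is the id separator, query values are split on ``+`` *before*
percent-decoding; unrecognized parameters are preserved for round-trips but
never interpreted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from urllib.parse import quote, unquote, urlsplit

from .errors import CxParseError

PANEL_PARAMS = ("left", "right", "bottom")
TAB_PARAM = "activeTableBrowserTab"
_CANONICAL = ("selectednodes", "selectededges") + PANEL_PARAMS + (TAB_PARAM,)


@dataclass
class SharedViewState:
    network_ref: str = ""
    selected_nodes: list[int] = field(default_factory=list)
    selected_edges: list[int] = field(default_factory=list)
    panel_states: dict[str, str] = field(
        default_factory=lambda: {p: "open" for p in PANEL_PARAMS}
    )
    active_table_tab: int = 0
    extra_params: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for panel, state in self.panel_states.items():
            if panel not in PANEL_PARAMS or state not in ("open", "closed"):
                raise ValueError(f"bad panel state {panel}={state}")
        if self.active_table_tab < 0:
            raise ValueError("tab index must be non-negative")
        if any(i < 0 for i in self.selected_nodes + self.selected_edges):
            raise ValueError("element ids must be non-negative")


def _split_query(query: str) -> list[tuple[str, str]]:
    if not query:
        return []
    pairs = []
    for token in query.split("&"):
        if not token:
            continue
        key, _, value = token.partition("=")
        pairs.append((key, value))
    return pairs


def _parse_id(token: str, *, edge: bool) -> int:
    raw = token
    if edge:
        if not token.startswith("e"):
            raise CxParseError(f"edge id token {raw!r} lacks the 'e' prefix")
        token = token[1:]
    if not token.isdigit():
        kind = "edge" if edge else "node"
        raise CxParseError(f"malformed {kind} id token {raw!r}")
    return int(token)


def parse_share_url(url: str) -> SharedViewState:
    """Decode a share URL into its view state."""
    parts = urlsplit(url)
    segments = [s for s in parts.path.split("/") if s]
    network_ref = segments[-1] if segments else ""
    state = SharedViewState(network_ref=network_ref)
    for key, value in _split_query(parts.query):
        if key == "selectednodes":
            state.selected_nodes = [
                _parse_id(t, edge=False) for t in value.split("+") if t
            ]
        elif key == "selectededges":
            state.selected_edges = [
                _parse_id(t, edge=True) for t in value.split("+") if t
            ]
        elif key in PANEL_PARAMS:
            if value not in ("open", "closed"):
                raise CxParseError(f"unknown panel token {value!r} for {key}")
            state.panel_states[key] = value
        elif key == TAB_PARAM:
            if not value.isdigit():
                raise CxParseError(f"malformed tab index {value!r}")
            state.active_table_tab = int(value)
        else:
            state.extra_params.append((unquote(key), unquote(value)))
    return state


def build_share_url(state: SharedViewState, base: str) -> str:
    """Encode a view state as a share URL under ``base``.

    Parameters are emitted in canonical order; selection parameters are
    omitted when empty; output is deterministic, so equal states build
    byte-identical URLs.
    """
    params: list[tuple[str, str]] = []
    if state.selected_nodes:
        params.append(
            ("selectednodes", "+".join(str(i) for i in state.selected_nodes))
        )
    if state.selected_edges:
        params.append(
            ("selectededges", "+".join(f"e{i}" for i in state.selected_edges))
        )
    for panel in PANEL_PARAMS:
        params.append((panel, state.panel_states.get(panel, "open")))
    params.append((TAB_PARAM, str(state.active_table_tab)))
    for key, value in state.extra_params:
        params.append((quote(key, safe=""), quote(value, safe="")))
    query = "&".join(f"{k}={v}" for k, v in params)
    prefix = base.rstrip("/")
    path = f"{prefix}/{state.network_ref}" if state.network_ref else prefix
    return f"{path}?{query}" if query else path


@dataclass(frozen=True)
class ImportDirective:
    source_url: str


def parse_import_directive(url: str) -> ImportDirective | None:
    """Extract the ``?import=`` source URL, decoded exactly once."""
    parts = urlsplit(url)
    for key, value in _split_query(parts.query):
        if key == "import":
            return ImportDirective(unquote(value))
    return None
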