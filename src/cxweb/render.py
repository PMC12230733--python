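"""Deterministic vector export of a styled, laid-out network.

A :class:`Scene` is an ordered list of drawables — edges first, then nodes,
then labels — derived from a bundle, its resolved style sheet, and node
coordinates.  Elements whose visibility resolves to false are excluded, and
hiding a node also hides its incident edges.  :func:`write_svg` emits SVG 1.1
with one graphical element per drawable and byte-identical output across
runs, so exported figures diff cleanly under version control.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional
from xml.sax.saxutils import escape, quoteattr

from .core import NetworkBundle
from .errors import ContractError

MARGIN = 10.0


@dataclass
class NodeDrawable:
    element_id: int
    x: float
    y: float
    size: float
    shape: str
    fill: str
    opacity: float


@dataclass
class EdgeDrawable:
    element_id: int
    x1: float
    y1: float
    x2: float
    y2: float
    width: float
    color: str
    line_style: str
    arrow: str
    opacity: float


@dataclass
class LabelDrawable:
    element_id: int
    x: float
    y: float
    text: str
    font_size: float


@dataclass
class Scene:
    edges: list[EdgeDrawable] = field(default_factory=list)
    nodes: list[NodeDrawable] = field(default_factory=list)
    labels: list[LabelDrawable] = field(default_factory=list)
    bounds: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    background: str = "#FFFFFF"

    def drawable_count(self) -> int:
        return len(self.edges) + len(self.nodes) + len(self.labels)


def build_scene(
    bundle: NetworkBundle,
    sheet: Optional[dict[str, Any]] = None,
    layout: Optional[dict[int, tuple[float, float]]] = None,
) -> Scene:
    """Assemble drawables from resolved visual values and coordinates.

    ``sheet`` defaults to resolving the bundle's own style; ``layout``
    defaults to the bundle's stored node positions.  Every visible node must
    have coordinates.
    """
    from .style import resolve_sheet

    if sheet is None:
        sheet = resolve_sheet(bundle)
    if layout is None:
        layout = {}
        for nid in bundle.node_ids:
            pos = bundle.position(nid)
            if pos is not None:
                layout[nid] = (pos[0], pos[1])

    nodes_sheet, edges_sheet = sheet["nodes"], sheet["edges"]

    visible_nodes = [
        nid for nid in bundle.node_ids if bool(nodes_sheet.loc[nid, "NODE_VISIBILITY"])
    ]
    missing = [nid for nid in visible_nodes if nid not in layout]
    if missing:
        raise ContractError(f"nodes without coordinates: {missing}")
    visible_set = set(visible_nodes)

    scene = Scene()
    scene.background = bundle.style.defaults.get(
        "NETWORK_BACKGROUND_COLOR", "#FFFFFF"
    )

    for eid in bundle.edge_ids:
        s, t = bundle.edge_endpoints(eid)
        if s not in visible_set or t not in visible_set:
            continue
        if not bool(edges_sheet.loc[eid, "EDGE_VISIBILITY"]):
            continue
        scene.edges.append(
            EdgeDrawable(
                eid,
                layout[s][0], layout[s][1], layout[t][0], layout[t][1],
                float(edges_sheet.loc[eid, "EDGE_WIDTH"]),
                str(edges_sheet.loc[eid, "EDGE_LINE_COLOR"]),
                str(edges_sheet.loc[eid, "EDGE_LINE_STYLE"]),
                str(edges_sheet.loc[eid, "EDGE_TARGET_ARROW"]),
                float(edges_sheet.loc[eid, "EDGE_OPACITY"]),
            )
        )

    for nid in visible_nodes:  # ascending id fixes z-order among overlaps
        x, y = layout[nid]
        scene.nodes.append(
            NodeDrawable(
                nid, x, y,
                float(nodes_sheet.loc[nid, "NODE_SIZE"]),
                str(nodes_sheet.loc[nid, "NODE_SHAPE"]),
                str(nodes_sheet.loc[nid, "NODE_BACKGROUND_COLOR"]),
                float(nodes_sheet.loc[nid, "NODE_OPACITY"]),
            )
        )
        scene.labels.append(
            LabelDrawable(
                nid, x, y,
                str(nodes_sheet.loc[nid, "NODE_LABEL"]),
                float(nodes_sheet.loc[nid, "NODE_LABEL_FONT_SIZE"]),
            )
        )

    if scene.nodes:
        min_x = min(n.x - n.size / 2 for n in scene.nodes) - MARGIN
        max_x = max(n.x + n.size / 2 for n in scene.nodes) + MARGIN
        min_y = min(n.y - n.size / 2 for n in scene.nodes) - MARGIN
        max_y = max(n.y + n.size / 2 for n in scene.nodes) + MARGIN
        scene.bounds = (min_x, min_y, max_x - min_x, max_y - min_y)
    else:
        scene.bounds = (0.0, 0.0, 0.0, 0.0)
    return scene


# ---------------------------------------------------------------------------
# SVG emission
# ---------------------------------------------------------------------------

_DASH = {"solid": None, "dashed": "8,4", "dotted": "2,3"}


def _fmt(x: float) -> str:
    return f"{x:.3f}".rstrip("0").rstrip(".")


def _shape_element(node: NodeDrawable) -> str:
    half = node.size / 2
    common = f' fill={quoteattr(node.fill)} fill-opacity="{_fmt(node.opacity)}"'
    if node.shape == "ellipse":
        return (f'<ellipse cx="{_fmt(node.x)}" cy="{_fmt(node.y)}" '
                f'rx="{_fmt(half)}" ry="{_fmt(half)}"{common}/>')
    if node.shape in ("rectangle", "round-rectangle"):
        rx = ' rx="4"' if node.shape == "round-rectangle" else ""
        return (f'<rect x="{_fmt(node.x - half)}" y="{_fmt(node.y - half)}" '
                f'width="{_fmt(node.size)}" height="{_fmt(node.size)}"{rx}{common}/>')
    if node.shape == "triangle":
        points = [(node.x, node.y - half), (node.x + half, node.y + half),
                  (node.x - half, node.y + half)]
    elif node.shape == "diamond":
        points = [(node.x, node.y - half), (node.x + half, node.y),
                  (node.x, node.y + half), (node.x - half, node.y)]
    else:  # hexagon
        points = [
            (node.x + half * math.cos(math.radians(a)),
             node.y + half * math.sin(math.radians(a)))
            for a in (0, 60, 120, 180, 240, 300)
        ]
    point_text = " ".join(f"{_fmt(px)},{_fmt(py)}" for px, py in points)
    return f'<polygon points="{point_text}"{common}/>'


def _edge_element(edge: EdgeDrawable) -> str:
    dash = _DASH.get(edge.line_style)
    dash_attr = f' stroke-dasharray="{dash}"' if dash else ""
    marker = ' marker-end="url(#arrow)"' if edge.arrow != "none" else ""
    return (f'<line x1="{_fmt(edge.x1)}" y1="{_fmt(edge.y1)}" '
            f'x2="{_fmt(edge.x2)}" y2="{_fmt(edge.y2)}" '
            f'stroke={quoteattr(edge.color)} stroke-width="{_fmt(edge.width)}" '
            f'stroke-opacity="{_fmt(edge.opacity)}"{dash_attr}{marker}/>')


def write_svg(scene: Scene) -> str:
    """Emit SVG 1.1 text: one graphical element per drawable, deterministic."""
    x, y, width, height = scene.bounds
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        (f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
         f'viewBox="{_fmt(x)} {_fmt(y)} {_fmt(width)} {_fmt(height)}" '
         f'width="{_fmt(width)}" height="{_fmt(height)}">'),
    ]
    if any(e.arrow != "none" for e in scene.edges):
        lines.append(
            '<defs><marker id="arrow" viewBox="0 0 10 10" refX="10" refY="5" '
            'markerWidth="6" markerHeight="6" orient="auto-start-reverse">'
            '<path d="M 0 0 L 10 5 L 0 10 z"/></marker></defs>'
        )
    for edge in scene.edges:
        lines.append(_edge_element(edge))
    for node in scene.nodes:
        lines.append(_shape_element(node))
    for label in scene.labels:
        lines.append(
            f'<text x="{_fmt(label.x)}" y="{_fmt(label.y)}" '
            f'text-anchor="middle" dominant-baseline="middle" '
            f'font-size="{_fmt(label.font_size)}">{escape(label.text)}</text>'
        )
    lines.append("</svg>")
    return "\n".join(lines)


def render_bundle_svg(bundle: NetworkBundle) -> str:
    """Convenience: resolve, build the scene, and emit SVG in one call."""
    return write_svg(build_scene(bundle))
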