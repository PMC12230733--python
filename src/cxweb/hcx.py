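"""Hierarchical (HCX) networks: validation, subnetwork extraction, layouts.

An HCX model pairs two networks: a *hierarchy* whose edges point parent to
child and whose nodes ("assemblies" — protein complexes, pathways,
organelles) each carry a member list, and a flat *interaction* network those
members reference.  The member list lives in the ``HCX::members`` node
attribute and the root carries ``HCX::isRoot``; a network-level
``ndexSchema`` attribute beginning with "hierarchy" marks a document as HCX.

Two layouts are provided: a nested circle-packing "cell view" (each assembly
drawn as a circle containing its children, leaf area proportional to member
count) and a layered "tree view" (depth on y, subtrees side by side).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import networkx as nx

from .core import NetworkBundle
from .cx2 import ValidationIssue
from .errors import ContractError, ElementReferenceError

MEMBERS_ATTRIBUTE = "HCX::members"
ROOT_ATTRIBUTE = "HCX::isRoot"
SCHEMA_ATTRIBUTE = "ndexSchema"


def is_hcx(bundle: NetworkBundle) -> bool:
    """True when the network-level schema marker declares a hierarchy."""
    marker = bundle.network_table.get_value(0, SCHEMA_ATTRIBUTE)
    return isinstance(marker, str) and marker.startswith("hierarchy")


@dataclass
class HcxBundle:
    hierarchy: NetworkBundle
    interaction: NetworkBundle

    def members(self, assembly: int) -> list[int]:
        raw = self.hierarchy.node_table.get_value(assembly, MEMBERS_ATTRIBUTE) or []
        return [int(m) for m in raw]

    def is_root(self, assembly: int) -> bool:
        return bool(self.hierarchy.node_table.get_value(assembly, ROOT_ATTRIBUTE))

    def roots(self) -> list[int]:
        return [n for n in self.hierarchy.node_ids if self.is_root(n)]

    def children(self, assembly: int) -> list[int]:
        return sorted(self.hierarchy.graph.successors(assembly))

    def parent(self, assembly: int) -> Optional[int]:
        preds = list(self.hierarchy.graph.predecessors(assembly))
        return preds[0] if preds else None


@dataclass(frozen=True)
class Circle:
    x: float
    y: float
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("circle radius must be positive")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def validate_hcx(h: HcxBundle) -> list[ValidationIssue]:
    """Structural checks; errors block layout, warnings do not."""
    issues: list[ValidationIssue] = []
    roots = h.roots()
    if len(roots) != 1:
        issues.append(ValidationIssue(
            "error", "nodes", None,
            f"hierarchy must have exactly one root, found {len(roots)}"))
    if not nx.is_directed_acyclic_graph(h.hierarchy.graph):
        issues.append(ValidationIssue(
            "error", "edges", None, "hierarchy contains a cycle"))
    interaction_ids = set(h.interaction.node_ids)
    for assembly in h.hierarchy.node_ids:
        missing = [m for m in h.members(assembly) if m not in interaction_ids]
        if missing:
            issues.append(ValidationIssue(
                "error", "nodes", assembly,
                f"assembly {assembly} references absent interaction "
                f"nodes {sorted(missing)}"))
    for assembly in h.hierarchy.node_ids:
        parent_members = set(h.members(assembly))
        for child in h.children(assembly):
            extra = set(h.members(child)) - parent_members
            if extra:
                issues.append(ValidationIssue(
                    "warning", "nodes", child,
                    f"assembly {child} has members {sorted(extra)} missing "
                    f"from its parent {assembly}"))
    return issues


# ---------------------------------------------------------------------------
# Subnetwork extraction
# ---------------------------------------------------------------------------


def extract_assembly_subnetwork(h: HcxBundle, assembly: int) -> NetworkBundle:
    """Induced interaction subgraph on the assembly's members.

    Attribute tables are restricted to the surviving elements; the
    interaction network's style is carried over, so the extracted view is
    rendered like its parent.
    """
    if not h.hierarchy.has_node(assembly):
        raise ElementReferenceError(f"no hierarchy node with id {assembly}")
    members = set(h.members(assembly))
    src = h.interaction
    out = NetworkBundle()
    out.node_table = src.node_table.copy()
    out.node_table.rows = {
        k: v for k, v in out.node_table.rows.items() if k in members
    }
    for nid in sorted(members):
        pos = src.position(nid)
        out.add_node(nid)
        if pos is not None:
            out.set_position(nid, *pos)
    out.edge_table = src.edge_table.copy()
    kept_edges = set()
    for eid in src.edge_ids:
        s, t = src.edge_endpoints(eid)
        if s in members and t in members:
            out.add_edge(s, t, edge_id=eid)
            kept_edges.add(eid)
    out.edge_table.rows = {
        k: v for k, v in out.edge_table.rows.items() if k in kept_edges
    }
    out.style = src.style.copy()
    out.node_bypasses = {k: dict(v) for k, v in src.node_bypasses.items()
                         if k in members}
    out.edge_bypasses = {k: dict(v) for k, v in src.edge_bypasses.items()
                         if k in kept_edges}
    out.check_integrity()
    return out


# ---------------------------------------------------------------------------
# Circle packing ("Cell View")
# ---------------------------------------------------------------------------


def _tangent_candidates(c1: Circle, c2: Circle, r: float) -> list[tuple[float, float]]:
    """Centers of a radius-``r`` circle externally tangent to ``c1`` and ``c2``."""
    d1, d2 = c1.radius + r, c2.radius + r
    dx, dy = c2.x - c1.x, c2.y - c1.y
    d = math.hypot(dx, dy)
    if d == 0 or d > d1 + d2 or d < abs(d1 - d2):
        return []
    a = (d1 * d1 - d2 * d2 + d * d) / (2 * d)
    h_sq = d1 * d1 - a * a
    h = math.sqrt(max(0.0, h_sq))
    mx, my = c1.x + a * dx / d, c1.y + a * dy / d
    return [
        (mx + h * -dy / d, my + h * dx / d),
        (mx - h * -dy / d, my - h * dx / d),
    ]


def _pack_siblings(radii: list[float]) -> list[tuple[float, float]]:
    """Greedy tangent-pair packing: deterministic, pairwise non-overlapping.

    Circles are placed in the given order; each new circle takes the valid
    tangent position closest to the origin of the growing cluster.
    """
    eps = 1e-9
    placed: list[Circle] = []
    for r in radii:
        if not placed:
            placed.append(Circle(0.0, 0.0, r))
            continue
        if len(placed) == 1:
            c = placed[0]
            placed.append(Circle(c.x + c.radius + r, c.y, r))
            continue
        best: Optional[tuple[float, float, float]] = None
        for i in range(len(placed)):
            for j in range(i + 1, len(placed)):
                for (x, y) in _tangent_candidates(placed[i], placed[j], r):
                    if any(
                        math.hypot(x - c.x, y - c.y) < c.radius + r - eps
                        for c in placed
                    ):
                        continue
                    dist = math.hypot(x, y)
                    key = (dist, round(x, 9), round(y, 9))
                    if best is None or key < best:
                        best = key
        if best is None:  # degenerate fallback: extend to the right
            edge = max(c.x + c.radius for c in placed)
            placed.append(Circle(edge + r, 0.0, r))
        else:
            placed.append(Circle(best[1], best[2], r))
    return [(c.x, c.y) for c in placed]


def _enclose(circles: list[Circle]) -> tuple[float, float, float]:
    """Center and radius of a circle containing all given circles.

    Uses the area-weighted centroid as center; not minimal, but
    deterministic and tight enough for nesting.
    """
    if not circles:
        return 0.0, 0.0, 1.0
    total = sum(c.radius**2 for c in circles)
    cx = sum(c.x * c.radius**2 for c in circles) / total
    cy = sum(c.y * c.radius**2 for c in circles) / total
    radius = max(math.hypot(c.x - cx, c.y - cy) + c.radius for c in circles)
    return cx, cy, radius


def circle_pack_layout(
    h: HcxBundle, root_radius: float = 500.0, padding: float = 0.05
) -> dict[int, Circle]:
    """Nested circle packing of the hierarchy.

    Leaf radius scales with sqrt(member count), so leaf *area* tracks
    assembly size; an internal assembly's radius is the enclosing radius of
    its packed children grown by ``padding``.  The root circle is scaled to
    ``root_radius`` and centered at the origin.  Deterministic: children are
    packed in order of decreasing radius (ties by id).
    """
    issues = validate_hcx(h)
    if any(i.severity == "error" for i in issues):
        raise ContractError(
            "hierarchy fails validation: " + issues[0].message
        )
    if root_radius <= 0 or padding < 0:
        raise ValueError("root_radius must be positive and padding >= 0")

    root = h.roots()[0]
    radius: dict[int, float] = {}
    offsets: dict[int, tuple[float, float]] = {}  # child center in parent frame

    def measure(assembly: int) -> float:
        children = h.children(assembly)
        if not children:
            r = math.sqrt(max(1, len(h.members(assembly))))
            radius[assembly] = r
            return r
        child_radii = [(measure(c), c) for c in children]
        order = sorted(child_radii, key=lambda t: (-t[0], t[1]))
        positions = _pack_siblings([r for r, _ in order])
        circles = [Circle(x, y, r) for (x, y), (r, _) in zip(positions, order)]
        cx, cy, enclose_r = _enclose(circles)
        for circle, (_, child) in zip(circles, order):
            offsets[child] = (circle.x - cx, circle.y - cy)
        r = enclose_r * (1.0 + padding)
        radius[assembly] = r
        return r

    measure(root)
    scale = root_radius / radius[root]

    out: dict[int, Circle] = {}

    def place(assembly: int, x: float, y: float) -> None:
        out[assembly] = Circle(x, y, radius[assembly] * scale)
        for child in h.children(assembly):
            ox, oy = offsets[child]
            place(child, x + ox * scale, y + oy * scale)

    place(root, 0.0, 0.0)
    return out


# ---------------------------------------------------------------------------
# Layered tree layout ("Tree View")
# ---------------------------------------------------------------------------


def tree_layout(
    h: HcxBundle, level_gap: float = 80.0, sibling_gap: float = 60.0
) -> dict[int, tuple[float, float]]:
    """Layered layout: y = depth * level_gap, parents centered over children.

    Leaves are placed left-to-right in depth-first order (siblings by id),
    ``sibling_gap`` apart, which keeps subtrees horizontally disjoint.
    """
    issues = validate_hcx(h)
    if any(i.severity == "error" for i in issues):
        raise ContractError("hierarchy fails validation: " + issues[0].message)
    root = h.roots()[0]
    positions: dict[int, tuple[float, float]] = {}
    next_leaf_x = 0.0

    def assign(assembly: int, depth: int) -> float:
        nonlocal next_leaf_x
        y = depth * level_gap
        children = h.children(assembly)
        if not children:
            x = next_leaf_x
            next_leaf_x += sibling_gap
        else:
            xs = [assign(c, depth + 1) for c in children]
            x = sum(xs) / len(xs)
        positions[assembly] = (x, y)
        return x

    assign(root, 0)
    return positions


def apply_cell_view(h: HcxBundle, root_radius: float = 500.0,
                    padding: float = 0.05) -> None:
    """Write packed circles onto the hierarchy bundle's layout.

    Centers go to node x/y; radii to a ``cellview::radius`` node attribute.
    """
    circles = circle_pack_layout(h, root_radius, padding)
    for assembly, circle in circles.items():
        h.hierarchy.set_position(assembly, circle.x, circle.y)
        h.hierarchy.node_table.set_value(
            assembly, "cellview::radius", float(circle.radius)
        )
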