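"""Data-driven visual style resolution.

A style holds a default value per visual property plus optional mapping
functions — discrete (lookup), continuous (piecewise-linear over a numeric
attribute), or passthrough (attribute used directly).  Per-element bypasses
override everything.  Resolution precedence is therefore

    bypass  >  mapping (when the element carries a non-null mapped attribute)
            >  default

and is total: every (element, applicable property) pair resolves to a value.

Continuous mappings clamp outside the terminal control points and interpolate
linearly between adjacent ones; colors are interpolated per 8-bit sRGB channel
with half-up rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any, Optional

import pandas as pd

from .core import ElementTable, NetworkBundle
from .errors import ContractError

# ---------------------------------------------------------------------------
# Visual property vocabulary
# ---------------------------------------------------------------------------

NODE_SHAPES = ("ellipse", "rectangle", "round-rectangle", "triangle", "diamond", "hexagon")
LINE_STYLES = ("solid", "dashed", "dotted")
ARROW_SHAPES = ("none", "triangle", "circle", "square", "tee")


@dataclass(frozen=True)
class VisualPropertyKey:
    name: str
    value_kind: str  # color | number | text | enum | boolean
    applies_to: str  # node | edge | network
    enum_tokens: tuple[str, ...] = ()


_PROPS = [
    VisualPropertyKey("NODE_BACKGROUND_COLOR", "color", "node"),
    VisualPropertyKey("NODE_SIZE", "number", "node"),
    VisualPropertyKey("NODE_SHAPE", "enum", "node", NODE_SHAPES),
    VisualPropertyKey("NODE_LABEL", "text", "node"),
    VisualPropertyKey("NODE_LABEL_FONT_SIZE", "number", "node"),
    VisualPropertyKey("NODE_VISIBILITY", "boolean", "node"),
    VisualPropertyKey("NODE_OPACITY", "number", "node"),
    VisualPropertyKey("EDGE_LINE_COLOR", "color", "edge"),
    VisualPropertyKey("EDGE_WIDTH", "number", "edge"),
    VisualPropertyKey("EDGE_LINE_STYLE", "enum", "edge", LINE_STYLES),
    VisualPropertyKey("EDGE_TARGET_ARROW", "enum", "edge", ARROW_SHAPES),
    VisualPropertyKey("EDGE_VISIBILITY", "boolean", "edge"),
    VisualPropertyKey("EDGE_OPACITY", "number", "edge"),
    VisualPropertyKey("NETWORK_BACKGROUND_COLOR", "color", "network"),
]

VISUAL_PROPERTIES: dict[str, VisualPropertyKey] = {p.name: p for p in _PROPS}

DEFAULTS = {
    "NODE_BACKGROUND_COLOR": "#CCCCCC",
    "NODE_SIZE": 40.0,
    "NODE_SHAPE": "ellipse",
    "NODE_LABEL": "",
    "NODE_LABEL_FONT_SIZE": 12.0,
    "NODE_VISIBILITY": True,
    "NODE_OPACITY": 1.0,
    "EDGE_LINE_COLOR": "#999999",
    "EDGE_WIDTH": 2.0,
    "EDGE_LINE_STYLE": "solid",
    "EDGE_TARGET_ARROW": "none",
    "EDGE_VISIBILITY": True,
    "EDGE_OPACITY": 1.0,
    "NETWORK_BACKGROUND_COLOR": "#FFFFFF",
}


class NoMatch:
    """Sentinel: a mapping did not apply; the caller falls back to defaults."""

    _instance: Optional["NoMatch"] = None

    def __new__(cls) -> "NoMatch":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "NO_MATCH"


NO_MATCH = NoMatch()


# -- color helpers ----------------------------------------------------------


def parse_color(text: str) -> tuple[int, int, int]:
    if (
        not isinstance(text, str)
        or len(text) != 7
        or text[0] != "#"
        or any(c not in "0123456789abcdefABCDEF" for c in text[1:])
    ):
        raise ValueError(f"not a #RRGGBB color: {text!r}")
    return tuple(int(text[i : i + 2], 16) for i in (1, 3, 5))  # type: ignore[return-value]


def format_color(rgb: tuple[int, int, int]) -> str:
    return "#{:02X}{:02X}{:02X}".format(*rgb)


def normalize_color(text: str) -> str:
    return format_color(parse_color(text))


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def coerce_visual_value(value: Any, key: VisualPropertyKey) -> Any:
    """Cast ``value`` to the property's kind; raises ValueError on failure."""
    if key.value_kind == "color":
        return normalize_color(value)
    if key.value_kind == "number":
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ValueError(f"not a number: {value!r}")
        return float(value)
    if key.value_kind == "text":
        if isinstance(value, str):
            return value
        if isinstance(value, bool):
            return "true" if value else "false"
        if isinstance(value, (int, float)):
            return repr(value) if isinstance(value, float) else str(value)
        raise ValueError(f"not renderable as text: {value!r}")
    if key.value_kind == "enum":
        if value in key.enum_tokens:
            return value
        raise ValueError(f"{value!r} not in {key.enum_tokens}")
    if key.value_kind == "boolean":
        if isinstance(value, bool):
            return value
        raise ValueError(f"not a boolean: {value!r}")
    raise ValueError(f"unknown value kind {key.value_kind}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Mapping definitions
# ---------------------------------------------------------------------------


@dataclass
class ContinuousControlPoint:
    threshold: float
    value: Any


@dataclass
class MappingDefinition:
    """One mapping function attached to a visual property."""

    kind: str  # discrete | continuous | passthrough
    attribute: str
    discrete_map: list[tuple[Any, Any]] = field(default_factory=list)
    continuous_points: list[ContinuousControlPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in ("discrete", "continuous", "passthrough"):
            raise ValueError(f"unknown mapping kind {self.kind!r}")
        if self.kind == "continuous":
            pts = self.continuous_points
            if len(pts) < 2:
                raise ValueError("continuous mapping needs >= 2 control points")
            thresholds = [p.threshold for p in pts]
            if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
                raise ValueError("control point thresholds must strictly increase")
        if self.kind == "discrete":
            keys = [k for k, _ in self.discrete_map]
            if len(set(map(repr, keys))) != len(keys):
                raise ValueError("discrete mapping has duplicate attribute values")


def evaluate_continuous(definition: MappingDefinition, value: Any, key: VisualPropertyKey):
    """Piecewise-linear evaluation with terminal clamping.

    Returns :data:`NO_MATCH` for non-numeric input so the caller can fall back
    to the default.
    """
    if definition.kind != "continuous":
        raise ContractError("not a continuous mapping")
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        return NO_MATCH
    x = float(value)
    pts = definition.continuous_points
    if x <= pts[0].threshold:
        return coerce_visual_value(pts[0].value, key)
    if x >= pts[-1].threshold:
        return coerce_visual_value(pts[-1].value, key)
    for lo, hi in zip(pts, pts[1:]):
        if x == lo.threshold:
            return coerce_visual_value(lo.value, key)
        if lo.threshold < x < hi.threshold:
            frac = (x - lo.threshold) / (hi.threshold - lo.threshold)
            if key.value_kind == "number":
                a, b = float(lo.value), float(hi.value)
                return a + frac * (b - a)
            if key.value_kind == "color":
                rgb_lo = parse_color(lo.value)
                rgb_hi = parse_color(hi.value)
                rgb = tuple(
                    _round_half_up(a + frac * (b - a))
                    for a, b in zip(rgb_lo, rgb_hi)
                )
                return format_color(rgb)  # type: ignore[arg-type]
            # non-interpolable kinds step at the upper control point
            return coerce_visual_value(lo.value, key)
    return coerce_visual_value(pts[-1].value, key)  # pragma: no cover


def evaluate_discrete(definition: MappingDefinition, value: Any):
    """Exact-equality lookup; NO_MATCH when the value has no entry."""
    if definition.kind != "discrete":
        raise ContractError("not a discrete mapping")
    for attr_value, visual in definition.discrete_map:
        if type(attr_value) is type(value) and attr_value == value:
            return visual
        # numeric equality across int/float, excluding bools
        if (
            isinstance(attr_value, (int, float))
            and isinstance(value, (int, float))
            and not isinstance(attr_value, bool)
            and not isinstance(value, bool)
            and attr_value == value
        ):
            return visual
    return NO_MATCH


def evaluate_passthrough(definition: MappingDefinition, value: Any, key: VisualPropertyKey):
    """Use the attribute value directly, cast to the property's kind."""
    if definition.kind != "passthrough":
        raise ContractError("not a passthrough mapping")
    try:
        return coerce_visual_value(value, key)
    except (ValueError, TypeError):
        return NO_MATCH


# ---------------------------------------------------------------------------
# Style container and resolution
# ---------------------------------------------------------------------------


class VisualStyle:
    """Defaults plus mappings for the full visual-property vocabulary.

    Every property always has a default, so resolution can never fail.
    """

    def __init__(self) -> None:
        self.defaults: dict[str, Any] = {}
        self.mappings: dict[str, MappingDefinition] = {}

    @classmethod
    def default(cls) -> "VisualStyle":
        style = cls()
        style.defaults = dict(DEFAULTS)
        return style

    def set_default(self, prop: str, value: Any) -> None:
        key = VISUAL_PROPERTIES[prop]
        self.defaults[prop] = coerce_visual_value(value, key)

    def set_mapping(self, prop: str, definition: MappingDefinition) -> None:
        if prop not in VISUAL_PROPERTIES:
            raise ContractError(f"unknown visual property {prop!r}")
        if prop not in self.defaults:
            raise ContractError(f"mapped property {prop!r} has no default")
        self.mappings[prop] = definition

    def copy(self) -> "VisualStyle":
        out = VisualStyle()
        out.defaults = dict(self.defaults)
        out.mappings = dict(self.mappings)
        return out


def resolve_element_property(
    prop: str,
    element: int,
    style: VisualStyle,
    bypasses: dict[int, dict[str, Any]],
    table: ElementTable,
) -> Any:
    """Resolve one property for one element: bypass > mapping > default."""
    key = VISUAL_PROPERTIES.get(prop)
    if key is None:
        raise ContractError(f"unknown visual property {prop!r}")
    bypass = bypasses.get(element, {})
    if prop in bypass:
        return coerce_visual_value(bypass[prop], key)
    definition = style.mappings.get(prop)
    if definition is not None:
        value = table.get_value(element, definition.attribute)
        if value is not None:
            if definition.kind == "continuous":
                result = evaluate_continuous(definition, value, key)
            elif definition.kind == "discrete":
                result = evaluate_discrete(definition, value)
            else:
                result = evaluate_passthrough(definition, value, key)
            if result is not NO_MATCH:
                return coerce_visual_value(result, key)
    return coerce_visual_value(style.defaults[prop], key)


def resolve_sheet(bundle: NetworkBundle) -> dict[str, pd.DataFrame]:
    """Resolve every applicable property for every element.

    Returns ``{"nodes": frame, "edges": frame}`` indexed by element id, one
    column per visual property of that class.
    """
    node_props = [p for p in VISUAL_PROPERTIES.values() if p.applies_to == "node"]
    edge_props = [p for p in VISUAL_PROPERTIES.values() if p.applies_to == "edge"]
    node_rows = {
        nid: {
            p.name: resolve_element_property(
                p.name, nid, bundle.style, bundle.node_bypasses, bundle.node_table
            )
            for p in node_props
        }
        for nid in bundle.node_ids
    }
    edge_rows = {
        eid: {
            p.name: resolve_element_property(
                p.name, eid, bundle.style, bundle.edge_bypasses, bundle.edge_table
            )
            for p in edge_props
        }
        for eid in bundle.edge_ids
    }
    nodes = pd.DataFrame.from_dict(node_rows, orient="index")
    edges = pd.DataFrame.from_dict(edge_rows, orient="index")
    if nodes.empty:
        nodes = pd.DataFrame(columns=[p.name for p in node_props])
    if edges.empty:
        edges = pd.DataFrame(columns=[p.name for p in edge_props])
    return {"nodes": nodes, "edges": edges}
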