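"""Seeded generators for networks, styles, hierarchies, and service results.

Everything here is a pure function of its spec (seed included): the same
seed always yields byte-identical artifacts, and every generated artifact
passes the validators of its consuming module.  The generators emulate the
*shape* of real inputs — random-graph topology, mixed-datatype attribute
tables, nested assembly hierarchies, enrichment-style result tables — not
their biology.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional

from .core import AttributeDeclaration, NetworkBundle
from .errors import ContractError
from .hcx import (
    MEMBERS_ATTRIBUTE,
    ROOT_ATTRIBUTE,
    SCHEMA_ATTRIBUTE,
    HcxBundle,
)
from .service import ResultAction
from .style import (
    ContinuousControlPoint,
    MappingDefinition,
    VisualStyle,
)

#: scenario name -> seed, the single seed table used throughout the tests
SCENARIO_SEEDS = {
    "small-network": 1,
    "styled-network": 2,
    "hierarchy-shallow": 3,
    "hierarchy-deep": 4,
    "enrichment": 5,
}

_NODE_TYPES = ("kinase", "phosphatase", "receptor", "ligand", "scaffold")
_INTERACTIONS = ("binds", "activates", "inhibits")


@dataclass
class FixtureSpec:
    seed: int = 1
    node_count: int = 10
    edge_count: int = 15
    hierarchy_depth: int = 3
    max_branching: int = 3
    style_complexity: int = 1  # 0: defaults only, 1: mappings + a bypass


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------


def random_bundle(spec: FixtureSpec) -> NetworkBundle:
    """Random directed multigraph with mixed-datatype attributes.

    Edge endpoints are sampled uniformly with replacement (self-loops and
    parallel edges possible), emulating an unfiltered interaction download.
    """
    if spec.node_count == 0 and spec.edge_count > 0:
        raise ContractError("cannot place edges in an empty network")
    rng = random.Random(spec.seed)
    bundle = NetworkBundle()
    bundle.network_table.set_value(0, "name", f"fixture network (seed {spec.seed})")
    for i in range(spec.node_count):
        bundle.add_node(
            i,
            {
                "name": f"N{i}",
                "score": round(rng.uniform(0, 100), 3),
                "type": rng.choice(_NODE_TYPES),
                "active": rng.random() < 0.5,
                "tags": [f"t{rng.randrange(5)}" for _ in range(rng.randrange(3))],
            },
            x=round(rng.uniform(-300, 300), 2),
            y=round(rng.uniform(-300, 300), 2),
        )
    for _ in range(spec.edge_count):
        source = rng.randrange(spec.node_count)
        target = rng.randrange(spec.node_count)
        bundle.add_edge(
            source,
            target,
            {
                "weight": round(rng.uniform(0, 1), 4),
                "interaction": rng.choice(_INTERACTIONS),
            },
        )
    if spec.style_complexity >= 1:
        bundle.style = style_fixture(spec.seed)
        if spec.node_count:
            bypassed = rng.randrange(spec.node_count)
            bundle.node_bypasses[bypassed] = {"NODE_BACKGROUND_COLOR": "#123456"}
    bundle.check_integrity()
    return bundle


def opaque_aspect_fixture(seed: int) -> tuple[str, list]:
    """A plausible third-party aspect to exercise opaque round-trips."""
    rng = random.Random(seed)
    return (
        f"customAnnotations_{seed}",
        [
            {"id": i, "note": f"annotation {rng.randrange(1000)}",
             "weight": round(rng.random(), 6)}
            for i in range(rng.randrange(1, 4))
        ],
    )


# ---------------------------------------------------------------------------
# Styles
# ---------------------------------------------------------------------------


def style_fixture(seed: int) -> VisualStyle:
    """A style exercising all three mapping kinds over the fixture schema."""
    rng = random.Random(seed)
    style = VisualStyle.default()
    style.set_mapping(
        "NODE_SIZE",
        MappingDefinition(
            "continuous",
            "score",
            continuous_points=[
                ContinuousControlPoint(0.0, 10.0 + rng.randrange(10)),
                ContinuousControlPoint(50.0, 40.0 + rng.randrange(10)),
                ContinuousControlPoint(100.0, 80.0 + rng.randrange(10)),
            ],
        ),
    )
    style.set_mapping(
        "NODE_BACKGROUND_COLOR",
        MappingDefinition(
            "continuous",
            "score",
            continuous_points=[
                ContinuousControlPoint(0.0, "#0000FF"),
                ContinuousControlPoint(100.0, "#FF0000"),
            ],
        ),
    )
    shapes = ("triangle", "diamond", "hexagon", "rectangle")
    style.set_mapping(
        "NODE_SHAPE",
        MappingDefinition(
            "discrete",
            "type",
            discrete_map=[
                (t, shapes[i % len(shapes)]) for i, t in enumerate(_NODE_TYPES)
            ],
        ),
    )
    style.set_mapping("NODE_LABEL", MappingDefinition("passthrough", "name"))
    style.set_mapping(
        "EDGE_LINE_STYLE",
        MappingDefinition(
            "discrete",
            "interaction",
            discrete_map=[("binds", "solid"), ("activates", "dashed"),
                          ("inhibits", "dotted")],
        ),
    )
    return style


# ---------------------------------------------------------------------------
# Hierarchies
# ---------------------------------------------------------------------------


def random_hierarchy(spec: FixtureSpec) -> HcxBundle:
    """Nested assembly hierarchy over a flat interaction network.

    A single root owns every interaction node; member sets strictly shrink
    from root to leaves along every path (children partition, or drop a
    member when an assembly has a single child).
    """
    if spec.hierarchy_depth < 1:
        raise ContractError("hierarchy depth must be >= 1")
    rng = random.Random(spec.seed)

    interaction = random_bundle(
        FixtureSpec(
            seed=spec.seed + 1,
            node_count=max(spec.node_count, 4),
            edge_count=spec.edge_count,
            style_complexity=0,
        )
    )
    all_members = interaction.node_ids

    hierarchy = NetworkBundle()
    hierarchy.network_table.set_value(0, SCHEMA_ATTRIBUTE, "hierarchy_v0.1")
    hierarchy.network_table.set_value(0, "name", f"fixture hierarchy (seed {spec.seed})")
    hierarchy.node_table.declare(
        AttributeDeclaration(MEMBERS_ATTRIBUTE, "list_of_long")
    )
    hierarchy.node_table.declare(AttributeDeclaration(ROOT_ATTRIBUTE, "boolean"))

    def new_assembly(members: list[int], *, root: bool = False) -> int:
        assembly = hierarchy.add_node(
            attrs={
                MEMBERS_ATTRIBUTE: sorted(members),
                "name": f"assembly {hierarchy.node_count()}",
            }
        )
        if root:
            hierarchy.node_table.set_value(assembly, ROOT_ATTRIBUTE, True)
        return assembly

    def grow(assembly: int, members: list[int], depth: int) -> None:
        if depth >= spec.hierarchy_depth or len(members) < 2:
            return
        k = min(len(members), rng.randint(2, max(2, spec.max_branching)))
        shuffled = members[:]
        rng.shuffle(shuffled)
        parts: list[list[int]] = [[] for _ in range(k)]
        for i, member in enumerate(shuffled):
            parts[i % k].append(member)
        parts = [sorted(p) for p in parts if p]
        if len(parts) == 1:  # single child must still shrink
            parts[0] = parts[0][:-1]
            if not parts[0]:
                return
        for part in parts:
            child = new_assembly(part)
            hierarchy.add_edge(assembly, child)
            grow(child, part, depth + 1)

    root = new_assembly(all_members, root=True)
    grow(root, all_members, 1)
    h = HcxBundle(hierarchy=hierarchy, interaction=interaction)
    return h


# ---------------------------------------------------------------------------
# Enrichment-style service results
# ---------------------------------------------------------------------------

#: the 10 result columns a functional-enrichment Service App adds to the
#: node table: pathway identity, overlap proportions, significance, and
#: run metadata (algorithm, source database, run descriptor)
ENRICHMENT_COLUMNS = (
    ("enrichment::pathwayName", "string"),
    ("enrichment::pathwayId", "string"),
    ("enrichment::description", "string"),
    ("enrichment::pValue", "double"),
    ("enrichment::overlapGeneCount", "integer"),
    ("enrichment::querySize", "integer"),
    ("enrichment::pathwaySize", "integer"),
    ("enrichment::overlapFraction", "double"),
    ("enrichment::algorithm", "string"),
    ("enrichment::sourceDatabase", "string"),
)

_PATHWAYS = (
    ("GO:0006281", "DNA repair"),
    ("GO:0007049", "cell cycle"),
    ("GO:0016192", "vesicle-mediated transport"),
    ("REAC:R-HSA-109582", "hemostasis"),
    ("KEGG:04010", "MAPK signaling pathway"),
)
_SOURCES = ("GO:BP", "Reactome", "KEGG")


def enrichment_result_fixture(bundle: NetworkBundle, seed: int) -> ResultAction:
    """An updateTables action mirroring a functional-enrichment result.

    Every node receives one row over the 10 documented columns; values are
    synthesized deterministically from the seed.
    """
    if bundle.node_count() < 1:
        raise ContractError("enrichment fixture needs at least one node")
    rng = random.Random(seed)
    rows = {}
    for nid in bundle.node_ids:
        pathway_id, pathway_name = rng.choice(_PATHWAYS)
        pathway_size = rng.randint(20, 400)
        query_size = rng.randint(3, 50)
        overlap = rng.randint(1, min(query_size, pathway_size))
        rows[str(nid)] = {
            "enrichment::pathwayName": pathway_name,
            "enrichment::pathwayId": pathway_id,
            "enrichment::description": f"{pathway_name} ({pathway_id})",
            "enrichment::pValue": round(10 ** -rng.uniform(1, 12), 14),
            "enrichment::overlapGeneCount": overlap,
            "enrichment::querySize": query_size,
            "enrichment::pathwaySize": pathway_size,
            "enrichment::overlapFraction": round(overlap / query_size, 6),
            "enrichment::algorithm": rng.choice(("g:SCS", "fdr", "bonferroni")),
            "enrichment::sourceDatabase": rng.choice(_SOURCES),
        }
    payload = {
        "scope": "nodes",
        "columns": [{"name": n, "datatype": d} for n, d in ENRICHMENT_COLUMNS],
        "rows": rows,
    }
    return ResultAction("updateTables", payload)
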