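"""Lay out an assembly hierarchy as nested circles and extract a subnetwork.

The "cell view" packs each assembly's children inside its circle, with leaf
area proportional to member count; the subnetwork viewer pulls the induced
interaction subgraph for any assembly.
"""

from cxweb import circle_pack_layout, extract_assembly_subnetwork, tree_layout
from cxweb.fixtures import FixtureSpec, random_hierarchy

h = random_hierarchy(FixtureSpec(seed=3, node_count=16, edge_count=24,
                                 hierarchy_depth=3))
root = h.roots()[0]
print(f"hierarchy: {h.hierarchy.node_count()} assemblies over "
      f"{h.interaction.node_count()} interaction nodes")

circles = circle_pack_layout(h, root_radius=500.0, padding=0.05)
for assembly in h.hierarchy.node_ids[:5]:
    c = circles[assembly]
    print(f"  assembly {assembly}: {len(h.members(assembly))} members, "
          f"circle r={c.radius:.1f} at ({c.x:.1f}, {c.y:.1f})")
# every child circle lies inside its parent; sibling circles never overlap

first_leaf = next(a for a in h.hierarchy.node_ids if not h.children(a))
sub = extract_assembly_subnetwork(h, first_leaf)
print(f"subnetwork of assembly {first_leaf}: {sub.node_count()} nodes, "
      f"{sub.edge_count()} edges (induced on its members)")

positions = tree_layout(h)
print(f"tree view places the root at x={positions[root][0]:.1f}, "
      "centered over its children")
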