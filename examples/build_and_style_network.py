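"""Build a small network, attach data-driven style mappings, and resolve them.

Shows the resolution precedence: bypass > mapping > default.
"""

from cxweb import NetworkBundle, MappingDefinition, resolve_sheet
from cxweb.style import ContinuousControlPoint

bundle = NetworkBundle()
for i, (name, score) in enumerate([("TP53", 90.0), ("MDM2", 45.0), ("CDK2", 5.0)]):
    bundle.add_node(i, {"name": name, "score": score}, x=i * 80.0, y=0.0)
bundle.add_edge(0, 1, {"interaction": "inhibits"})
bundle.add_edge(1, 2, {"interaction": "binds"})

# node size tracks the score linearly between 10 (score 0) and 50 (score 100)
bundle.style.set_mapping("NODE_SIZE", MappingDefinition(
    "continuous", "score",
    continuous_points=[ContinuousControlPoint(0, 10.0),
                       ContinuousControlPoint(100, 50.0)],
))
bundle.style.set_mapping("NODE_LABEL", MappingDefinition("passthrough", "name"))
# one bypass: MDM2 forced red regardless of any mapping
bundle.node_bypasses[1] = {"NODE_BACKGROUND_COLOR": "#FF0000"}

sheet = resolve_sheet(bundle)["nodes"]
print(sheet[["NODE_LABEL", "NODE_SIZE", "NODE_BACKGROUND_COLOR"]])
# NODE_SIZE is 10 + 0.4 * score; MDM2's color is the bypass, the others the
# default — every (element, property) pair always resolves to a concrete value.
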