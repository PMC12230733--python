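# cxweb

A headless Python toolkit for the computational core of browser-based network
biology platforms in the Cytoscape ecosystem: the CX2/HCX exchange formats,
data-driven visual styles, hierarchical cell-map layouts, the Service App
task protocol, shareable view-state URLs, import size limits, and
deterministic SVG export.

It is written for bioinformaticians and tool developers who need to produce,
validate, transform, or render CX2 networks from scripts and pipelines —
without a browser — while staying byte-compatible with the web platform's
conventions.

## What it implements

- **Network model** (`cxweb.core`): directed multigraphs with integer element
  ids, typed attribute tables (strict datatype coercion, auto-declaration),
  a workspace (networks, selections, panel state, installed services) with
  JSON snapshots, and the documented import limits — at most 20 000 edges,
  at most 26 000 nodes + edges combined, and documents strictly under 500 MB.
- **CX2 I/O** (`cxweb.cx2`): parse / validate / serialize the aspect-oriented
  JSON format. Unknown ("opaque") aspects are preserved verbatim;
  serialization is canonical, so output is byte-stable across runs.
- **Style engine** (`cxweb.style`): resolve defaults, discrete / continuous /
  passthrough mappings, and per-element bypasses into concrete visual values.
  Precedence is `bypass > mapping > default`; continuous mappings are
  piecewise-linear with terminal clamping, colors interpolated per sRGB
  channel with half-up rounding.
- **Tabular import** (`cxweb.tabular`): build networks from CSV/TSV edge
  lists with per-column roles and datatypes, previews, and type inference.
- **HCX hierarchies** (`cxweb.hcx`): validation (single root, acyclicity,
  membership integrity), induced assembly-subnetwork extraction, nested
  circle-packing "cell view" (leaf area ∝ member count), and a layered tree
  layout.
- **Service Apps** (`cxweb.service`): data-described external analysis
  services — metadata descriptors, task submit/poll/result, and the typed
  result actions `updateTables`, `addNetworks`, `updateSelection`,
  `updateLayouts`, `updateNetwork`, `openURL` — plus an in-process reference
  service for loopback testing and a stdlib HTTP wrapper.
- **Share URLs** (`cxweb.share`): encode/decode network reference, node/edge
  selection, panel flags, and the active table tab; `?import=` directives.
- **SVG export** (`cxweb.render`): scene building (edges, nodes, labels;
  visibility cascades) and deterministic SVG 1.1 emission.
- **Synthetic fixtures** (`cxweb.fixtures`): seeded generators for networks,
  styles, hierarchies, and enrichment-style service results.

## Worked example

```python
from cxweb import NetworkBundle, MappingDefinition, resolve_sheet
from cxweb.style import ContinuousControlPoint

bundle = NetworkBundle()
for i, (name, score) in enumerate([("TP53", 90.0), ("MDM2", 45.0), ("CDK2", 5.0)]):
    bundle.add_node(i, {"name": name, "score": score}, x=i * 80.0, y=0.0)
bundle.add_edge(0, 1); bundle.add_edge(1, 2)

bundle.style.set_mapping("NODE_SIZE", MappingDefinition(
    "continuous", "score",
    continuous_points=[ContinuousControlPoint(0, 10.0),
                       ContinuousControlPoint(100, 50.0)]))
bundle.node_bypasses[1] = {"NODE_BACKGROUND_COLOR": "#FF0000"}

print(resolve_sheet(bundle)["nodes"][["NODE_SIZE", "NODE_BACKGROUND_COLOR"]])
```

prints

```
   NODE_SIZE NODE_BACKGROUND_COLOR
0       46.0               #CCCCCC
1       28.0               #FF0000
2       12.0               #CCCCCC
```

Node sizes follow the continuous mapping (`10 + 0.4 · score`: 46, 28, 12);
node 1's color is its bypass, which wins over mappings and defaults; the
others fall back to the default fill. The `examples/` directory has one
short script per capability (CX2 round-trips, cell-view packing, the Service
App loopback, share URLs and SVG export), each printing the numbers it
computes.

There is also a thin CLI:

```sh
cxweb fixtures network --seed 1 --out net.cx2
cxweb validate --limits net.cx2
cxweb render net.cx2 --out net.svg
cxweb url parse "https://web.cytoscape.org/0/networks/abc?selectednodes=1+2"
```

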