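# Methods

This note documents the models, conventions, and numerical choices behind
`cxweb`, and what the synthetic generators do and do not emulate.

## Data model

Networks are directed multigraphs (self-loops and parallel edges allowed)
with non-negative integer element ids, unique within nodes and within edges.
The graph is held in a `networkx.MultiDiGraph` with edge ids as keys.
Attribute tables are scoped (nodes / edges / network; the network scope has
a single row) and schema'd by declarations with the ten CX2 datatypes
(`string`, `integer`, `long`, `double`, `boolean` and their list forms).

Coercion is strict: numeric strings parse to numbers, `"true"/"false"` to
booleans, but lossy casts (3.5 → integer), loose boolean tokens (`"yes"`),
implicit stringification, and implicit list splitting are all rejected.
`long` and `integer` are one Python `int` in memory and are distinguished
only in declarations; longs beyond 2^53−1 draw a validation warning because
JSON doubles cannot hold them exactly. Setting an undeclared attribute
auto-declares it from the value's inferred type (ints within 32 bits become
`integer`, beyond become `long`).

The workspace mirrors a client session — named networks, per-network
selections, left/right/bottom panel flags, the active table tab, and the
registry of installed service URLs — and snapshots to a single JSON document
whose round-trip is the identity under structural comparison. This replaces
a browser's local cache with an explicit on-disk artifact.

### Import limits

The platform-compatible limits are two conjunctive element caps plus a byte
cap: at most 20 000 edges, at most 26 000 nodes + edges combined, and a
document byte length strictly below 500 MB (500 × 10^6 bytes; the byte
check uses `>=` rejection so the bound itself is rejected). Reading the two
element clauses as a conjunction is deliberate: under a disjunction a
26 000-edge network would be admissible, contradicting the edge cap. Both
counts are taken on the fully parsed network, after any nodes implied by
import. Acceptance is monotone: adding elements can only move a network
from accepted to rejected.

## CX2 dialect

A document is a JSON array; element 0 is the version descriptor
(`{"CXVersion": "2.0", "hasFragments": false}`); each following element is a
single-key aspect object. Recognized aspects: `attributeDeclarations`
(per-scope name → `{d, v, a}` for datatype / default / alias),
`networkAttributes` (one record), `nodes` (`id`, optional `x, y, z`, values
under `v`), `edges` (`id`, `s`, `t`, `v`), `visualProperties`,
`nodeBypasses` / `edgeBypasses` (`id`, `v`), `metaData`, `status`. Aliases
are expanded on parse and re-applied on write. Fragmented documents
(`hasFragments: true`) are rejected. `z` coordinates are preserved but
unused by the layouts here.

Everything else is an opaque aspect: its decoded payload is carried in
order and re-emitted verbatim. Canonical write order is version, metaData,
attributeDeclarations, networkAttributes, nodes, edges, visualProperties,
nodeBypasses, edgeBypasses, opaque aspects (original order), status; JSON is
compact with keys in construction order, so serialization is deterministic
and parse∘serialize is the identity on canonical text.

Validation returns issues (severity, aspect, element index, message)
ordered by aspect then index rather than raising; parsing rejects documents
with error-severity issues, naming the first offending aspect and element.
A mapping that references an undeclared attribute is only a warning, since
resolution degrades gracefully to the default.

## Style resolution

The visual-property vocabulary covers the properties a figure needs: node
fill color, size, shape (ellipse, rectangle, round-rectangle, triangle,
diamond, hexagon), label, label size, visibility, opacity; edge color,
width, line style (solid, dashed, dotted), target arrow, visibility,
opacity; network background. Every property always has a default, so
resolution is total.

Precedence is bypass ≻ mapping ≻ default; a mapping is consulted only when
the element carries a non-null value of the mapped attribute (null/missing
means "unmapped", never zero). Continuous mappings require ≥ 2 control
points with strictly increasing thresholds; inputs at a threshold take that
point's value exactly, inputs between points interpolate linearly, and
out-of-range inputs clamp to the terminal values — clamping keeps the map
total and monotone where the underlying convention is unstated. Colors are
`#RRGGBB` (normalized uppercase), interpolated per 8-bit sRGB channel with
half-up rounding; opacity is a separate numeric property rather than an
alpha channel. Discrete mappings are exact-equality lookups after datatype
normalization (booleans never equal ints). Passthrough casts the attribute
to the property's kind (strict `#RRGGBB` parse for colors) and signals
no-match on failure.

## Tabular import

Delimiter sniffing is minimal and predictable: a tab in the first line means
TSV, otherwise comma (RFC 4180 quoting either way). Type inference per
column: all integers → `integer`; any decimal/exponent but all numeric →
`double`; all `true`/`false` case-insensitive → `boolean`; otherwise
`string`; empty cells are ignored and an all-empty column is `string`.

Node keys are whitespace-trimmed, case-sensitive strings; each distinct key
becomes one node carrying the key as its `name`. Every row with non-empty
source and target adds one edge (duplicates give parallel edges); an empty
target yields an isolated node; an empty source skips the row with a
reported row number. Conflicting node-attribute writes are last-row-wins
with a warning — deterministic under streaming. List cells split on the
declared delimiter (default `|`).

## HCX hierarchies and layouts

An HCX model is a hierarchy network (edges parent → child) over a flat
interaction network; membership lives in the `HCX::members` node attribute,
the root carries `HCX::isRoot`, and a network-level `ndexSchema` attribute
beginning with `hierarchy` marks the document. Validation errors: not
exactly one root, cycles, membership ids absent from the interaction
network. A child whose members are not a subset of its parent's is only a
warning — real maps contain such annotations and they do not break layout.
Fields beyond these pass through as ordinary (or opaque) attributes.

**Circle packing.** Leaf radius is `sqrt(max(1, member_count))`, so leaf
area tracks assembly size and radius is monotone in member count at equal
depth. Siblings are packed greedily in order of decreasing radius (ties by
id): the first at the origin, the second tangent to it, and each subsequent
circle at the valid position tangent to some pair of placed circles that is
closest to the origin — a deterministic front-free variant of tangent-pair
packing, O(n³) in the sibling count, which is ample at hierarchy fan-outs.
The sibling set is enclosed by a circle centered at the area-weighted
centroid with radius `max(dist + r)` (not the minimal enclosing circle, but
deterministic and tight enough), and the parent radius is that enclosure
grown by the `padding` fraction (default 0.05). Applied bottom-up, then
scaled so the root has `root_radius` (default 500 layout units) and placed
top-down. Guarantees, verified as properties with tolerance 10⁻⁶ ×
root_radius: every child circle lies inside its parent, and siblings never
overlap; two equal siblings end up congruent and tangent.

**Tree layout.** Depth sets `y = depth · level_gap`; leaves are placed
left-to-right in depth-first order (siblings by id) at `sibling_gap`
spacing; internal nodes center over their children. Subtrees occupy
disjoint leaf intervals, so no two nodes collide.

Subnetwork extraction returns the induced interaction subgraph on an
assembly's members with tables, bypasses, and style restricted/copied, so
the extracted view renders like its parent network.

## Service App protocol

Endpoint shapes: `GET {base}` returns the metadata descriptor, `POST {base}`
submits a task and returns `{"id": ...}`, `GET {base}/{id}/status` returns
`{state, progress, message}` with `complete`/`failed` terminal, and
`GET {base}/{id}/result` returns the action list. Polling defaults to 0.5 s
intervals with a budget of 240 polls, both configurable; the sleep function
is injectable so tests run instantly. Parameter kinds are text, number,
choice, flag, and node/edge column selectors (validated against the exported
network's table); scope `selected` exports the selected nodes and the edges
among them, and an empty selection is an error.

Result payload schemas are package-defined (the deployed services' schemas
are not published): `updateTables` carries scope, column declarations, and
per-element rows; `addNetworks` a list of named CX2 payloads; fresh names
are generated on collision. Unknown descriptor fields are preserved
opaquely. Applying `updateTables` twice with identical values is a no-op;
rows naming absent elements warn and continue, while a structurally
malformed payload raises after prior actions have been applied. Gene-set
strings split on commas first, then whitespace, dropping empties.

The reference service runs the handler synchronously at submission; a
handler exception becomes a `failed` task whose message is surfaced to the
client. The same object backs an optional stdlib HTTP server, so the
loopback tests exercise the identical code path that serves real requests.

## Share URLs

The network reference is the final path segment; `selectednodes` is a
`+`-joined id list, `selectededges` likewise with an `e` prefix per id,
panels are `left`/`right`/`bottom` ∈ {open, closed}, and
`activeTableBrowserTab` is carried verbatim (its origin is not specified as
0- or 1-based). Absent parameters default to empty selections, open panels,
tab 0. Because `+` is the separator, values are split before
percent-decoding; unknown parameters round-trip unharmed but are never
interpreted. Building emits parameters in canonical order and omits empty
selections, so parse∘build is the identity and build∘parse canonicalizes.
The `?import=` directive value is decoded exactly once.

## SVG export

A scene lists drawables in paint order — edges, then nodes (ascending id,
which fixes z-order among overlaps), then labels centered on node centers —
with hidden elements excluded and node visibility cascading to incident
edges. Bounds are the node-circle bounding box plus a 10-unit margin. The
writer emits exactly one SVG 1.1 graphical element per drawable (`line`,
`ellipse`/`rect`/`polygon`, `text`), formats numbers to three decimals, and
is byte-deterministic. Edges are straight segments; arrowheads appear only
when the arrow property is not `none`. Raster formats are out of scope: SVG
is the normative, diff-able surface.

## Synthetic generators

All generators are pure functions of their spec, seed included. They
emulate the *shape* of inputs, not biology: `random_bundle` samples edge
endpoints uniformly with replacement (so degree structure is Poisson-like,
with none of the modularity or hubs of real interactomes) and populates
numeric/string/boolean/list attributes; `random_hierarchy` partitions
members top-down so member sets strictly shrink along every path;
`style_fixture` always exercises all three mapping kinds;
`enrichment_result_fixture` emits one `updateTables` action over 10 columns
covering the documented result classes — pathway name and id, description,
P-value, overlap gene count, query size, pathway size, overlap fraction,
algorithm, source database — with deterministic synthetic values. The
concrete column names are package-chosen; only their number and content
classes follow the documented result schema. Passing tests on these
fixtures demonstrates the contracts (round-trips, precedence, geometry,
protocol identity), not performance or biological plausibility on real
maps.

## Problem sizes and tolerances

The default suites use networks of ≲ 20 nodes, hierarchies of depth ≤ 4
with branching ≤ 4 over ≤ 30 interaction nodes, 50 seeds for round-trip
checks and 20 for geometry — sizes at which every property is checked
exhaustively and the full suite runs in seconds. Geometric assertions use
an absolute tolerance of 10⁻⁶ × root_radius; interpolation oracles use
10⁻⁹ absolute. The size-limit boundaries in `scripts/acceptance.py` are
found by bisection over the validator itself rather than read from the
policy object, so the reported numbers are measured behavior.

## Known limitations

CX (version 1), `.cys` session files, fragmented CX2, `.sif`/`.xlsx`
import, undo history, authentication, curved edges, and raster export are
out of scope. The visual-property vocabulary is the minimal documented set,
not the full deployed palette. The enclosing circle used in packing is not
minimal, so packings are slightly looser than an optimal packer would
produce; determinism was preferred over density.
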