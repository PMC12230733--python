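"""Serialize a network to CX2 and read it back, preserving an opaque aspect.

Unknown aspects ride along verbatim, so annotations written by another tool
survive the round-trip untouched.
"""

from cxweb import parse_cx2, serialize_cx2
from cxweb.fixtures import FixtureSpec, random_bundle

bundle = random_bundle(FixtureSpec(seed=1, node_count=6, edge_count=8))
bundle.opaque_aspects.append(
    ("myAnnotations", [{"id": 0, "note": "written by another tool"}])
)

text = serialize_cx2(bundle)
restored = parse_cx2(text)

print(f"document size: {len(text)} bytes")
print(f"nodes: {restored.node_count()}, edges: {restored.edge_count()}")
print(f"opaque aspects preserved: {[name for name, _ in restored.opaque_aspects]}")
print(f"round-trip canonical: {serialize_cx2(restored) == text}")
# True: serialization is canonical, so parse -> serialize is the identity.
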