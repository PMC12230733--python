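"""Drive the full Service App protocol against an in-process service.

A service is described by data (menu, dialog parameters, result actions);
the client submits the network as CX2, polls the task, and applies the
returned actions.  Here the service mimics a functional-enrichment run.
"""

from cxweb import Workspace, apply_actions, build_task_request, run_task
from cxweb.fixtures import FixtureSpec, enrichment_result_fixture, random_bundle
from cxweb.service import ParameterSpec, ReferenceService, ServiceDescriptor

descriptor = ServiceDescriptor(
    name="Enrichment (demo)",
    description="adds enrichment-style result columns to the node table",
    version="1.0",
    menu_path=["Apps", "Enrichment demo"],
    parameters=[ParameterSpec("geneColumn", "Gene column", "nodeColumn",
                              required=True)],
    actions=["updateTables"],
)


def handler(payload):
    from cxweb.cx2 import parse_cx2_obj

    network = parse_cx2_obj(payload["network"])
    return [enrichment_result_fixture(network, seed=5)]


service = ReferenceService(descriptor, handler)

bundle = random_bundle(FixtureSpec(seed=5, node_count=5, edge_count=4,
                                   style_complexity=0))
ws = Workspace()
ws.add_network("net", bundle)

payload = build_task_request(descriptor, ws, {"geneColumn": "name"})
actions = run_task(service.transport, service.base_url, payload,
                   sleep=lambda _: None)
before = set(bundle.node_table.declarations)
apply_actions(ws, actions)
added = sorted(set(bundle.node_table.declarations) - before)

print(f"received {len(actions)} action(s); "
      f"{len(added)} new node-table columns:")
for name in added:
    print(f"  {name} = {bundle.node_table.get_value(0, name)!r}  (node 0)")
# 10 columns: pathway identity, overlap proportions, P-value, and run metadata
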