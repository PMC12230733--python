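"""Service App protocol: descriptors, task lifecycle, result actions."""

import pytest

from cxweb.core import Workspace
from cxweb.cx2 import parse_cx2_obj, serialize_cx2_obj
from cxweb.errors import (
    ConflictError,
    CxValidationError,
    TaskFailedError,
    TaskTimeoutError,
)
from cxweb.fixtures import (
    ENRICHMENT_COLUMNS,
    FixtureSpec,
    enrichment_result_fixture,
    random_bundle,
)
from cxweb.service import (
    ReferenceService,
    ResultAction,
    ServiceDescriptor,
    ParameterSpec,
    apply_actions,
    build_task_request,
    fetch_descriptor,
    list_services,
    parse_descriptor,
    register_service,
    run_task,
    split_gene_set,
)

NO_SLEEP = dict(sleep=lambda _: None)


def enrichment_descriptor():
    return ServiceDescriptor(
        name="Enrichment",
        description="functional enrichment over a gene-set column",
        version="1.0",
        menu_path=["Apps", "Enrichment"],
        parameters=[
            ParameterSpec("geneColumn", "Gene column", "nodeColumn",
                          required=True),
        ],
        actions=["updateTables"],
    )


def workspace_with(bundle) -> Workspace:
    ws = Workspace()
    ws.add_network("net", bundle)
    return ws


class TestDescriptor:
    def test_parse_fixture_descriptor(self):
        desc = parse_descriptor(enrichment_descriptor().to_json())
        assert desc.name == "Enrichment"
        assert len(desc.menu_path) >= 1
        assert desc.parameters[0].kind == "nodeColumn"

    def test_unknown_action_kind_names_the_token(self):
        doc = enrichment_descriptor().to_json()
        doc["actions"] = ["reformatDisk"]
        with pytest.raises(CxValidationError, match="reformatDisk"):
            parse_descriptor(doc)

    def test_missing_name_is_an_error(self):
        with pytest.raises(CxValidationError):
            parse_descriptor({"actions": []})

    def test_unknown_parameter_kind_is_an_error(self):
        doc = enrichment_descriptor().to_json()
        doc["parameters"][0]["kind"] = "telepathy"
        with pytest.raises(CxValidationError, match="telepathy"):
            parse_descriptor(doc)

    def test_unknown_fields_round_trip(self):
        doc = enrichment_descriptor().to_json()
        doc["citation"] = "doi:10/x"
        desc = parse_descriptor(doc)
        assert desc.extra["citation"] == "doi:10/x"
        assert parse_descriptor(desc.to_json()) == desc


class TestTaskRequest:
    def test_payload_carries_column_and_network(self, small_bundle):
        ws = workspace_with(small_bundle)
        small_bundle.node_table.set_value(0, "CD_MemberList", "TP53 BRCA1")
        payload = build_task_request(
            enrichment_descriptor(), ws, {"geneColumn": "CD_MemberList"}
        )
        assert payload["parameters"]["geneColumn"] == "CD_MemberList"
        network = parse_cx2_obj(payload["network"])
        assert network.node_count() == small_bundle.node_count()

    def test_missing_required_parameter_names_it(self, small_bundle):
        ws = workspace_with(small_bundle)
        with pytest.raises(CxValidationError, match="geneColumn"):
            build_task_request(enrichment_descriptor(), ws, {})

    def test_column_selector_must_name_an_existing_column(self, small_bundle):
        ws = workspace_with(small_bundle)
        with pytest.raises(CxValidationError, match="ghostColumn"):
            build_task_request(
                enrichment_descriptor(), ws, {"geneColumn": "ghostColumn"}
            )

    def test_selected_scope_exports_only_the_selection(self, small_bundle):
        desc = enrichment_descriptor()
        desc.input_scope = "selected"
        ws = workspace_with(small_bundle)
        ws.set_selection("net", {0, 1}, set())
        payload = build_task_request(desc, ws, {"geneColumn": "name"})
        network = parse_cx2_obj(payload["network"])
        assert network.node_count() == 2

    def test_selected_scope_with_empty_selection_is_an_error(self, small_bundle):
        desc = enrichment_descriptor()
        desc.input_scope = "selected"
        ws = workspace_with(small_bundle)
        with pytest.raises(CxValidationError, match="selection is empty"):
            build_task_request(desc, ws, {"geneColumn": "name"})

    def test_gene_set_splitting_commas_then_whitespace(self):
        assert split_gene_set("TP53, BRCA1  EGFR ,,MYC") == [
            "TP53", "BRCA1", "EGFR", "MYC"
        ]


class TestProtocolLoopback:
    def _echo_service(self):
        desc = enrichment_descriptor()

        def handler(payload):
            network = parse_cx2_obj(payload["network"])
            column = payload["parameters"]["geneColumn"]
            rows = {
                str(n): {"echo::column": column} for n in network.node_ids
            }
            return [ResultAction("updateTables", {
                "scope": "nodes",
                "columns": [{"name": "echo::column", "datatype": "string"}],
                "rows": rows,
            })]

        return ReferenceService(desc, handler), handler

    def test_loopback_actions_equal_handler_output(self, small_bundle):
        service, handler = self._echo_service()
        ws = workspace_with(small_bundle)
        payload = build_task_request(
            service.descriptor, ws, {"geneColumn": "name"}
        )
        received = run_task(service.transport, service.base_url, payload,
                            **NO_SLEEP)
        assert [a.to_json() for a in received] == [
            a.to_json() for a in handler(payload)
        ]

    def test_metadata_endpoint_is_self_consistent(self):
        service, _ = self._echo_service()
        desc = fetch_descriptor(service.transport, service.base_url)
        assert desc == service.descriptor

    def test_handler_failure_surfaces_the_message(self, small_bundle):
        desc = enrichment_descriptor()

        def bad_handler(payload):
            raise RuntimeError("column not found: xyz")

        service = ReferenceService(desc, bad_handler)
        with pytest.raises(TaskFailedError, match="column not found: xyz"):
            run_task(service.transport, service.base_url, {}, **NO_SLEEP)

    def test_unknown_task_id_is_not_found(self):
        service, _ = self._echo_service()
        status, _ = service.transport(
            "GET", f"{service.base_url}/task-999/status", None
        )
        assert status == 404

    def test_poll_timeout(self):
        def never_done(method, url, body):
            if method == "POST":
                return 200, {"id": "t"}
            return 200, {"state": "processing", "progress": 10, "message": ""}

        with pytest.raises(TaskTimeoutError):
            run_task(never_done, "http://x/svc", {}, max_polls=3, **NO_SLEEP)

    def test_loopback_over_real_http(self, small_bundle):
        import json
        import urllib.request

        from cxweb.service import serve_reference_service

        service, _ = self._echo_service()
        server = serve_reference_service(service)
        port = server.server_address[1]
        try:
            def transport(method, url, body):
                data = json.dumps(body).encode() if body is not None else None
                request = urllib.request.Request(url, data=data, method=method)
                with urllib.request.urlopen(request, timeout=10) as response:
                    return response.status, json.loads(response.read())

            base = f"http://127.0.0.1:{port}"
            ws = workspace_with(small_bundle)
            payload = build_task_request(
                service.descriptor, ws, {"geneColumn": "name"}
            )
            actions = run_task(transport, base, payload, **NO_SLEEP)
            assert actions[0].kind == "updateTables"
        finally:
            server.shutdown()


class TestApplyActions:
    def test_enrichment_fixture_adds_exactly_its_columns(self, plain_bundle):
        ws = workspace_with(plain_bundle)
        before = set(plain_bundle.node_table.declarations)
        action = enrichment_result_fixture(plain_bundle, seed=5)
        apply_actions(ws, [action])
        after = set(plain_bundle.node_table.declarations)
        assert after - before == {name for name, _ in ENRICHMENT_COLUMNS}
        assert before <= after  # pre-existing columns untouched
        for nid in plain_bundle.node_ids:
            for name, _ in ENRICHMENT_COLUMNS:
                assert plain_bundle.node_table.get_value(nid, name) is not None

    def test_update_tables_is_idempotent(self, plain_bundle):
        ws = workspace_with(plain_bundle)
        action = enrichment_result_fixture(plain_bundle, seed=5)
        apply_actions(ws, [action])
        snapshot = {k: dict(v) for k, v in plain_bundle.node_table.rows.items()}
        apply_actions(ws, [action])
        assert plain_bundle.node_table.rows == snapshot

    def test_update_tables_unknown_id_warns_and_continues(self, plain_bundle):
        ws = workspace_with(plain_bundle)
        action = ResultAction("updateTables", {
            "scope": "nodes",
            "columns": [{"name": "c", "datatype": "string"}],
            "rows": {"0": {"c": "ok"}, "999": {"c": "ghost"}},
        })
        _, report = apply_actions(ws, [action])
        assert len(report.warnings) == 1
        assert plain_bundle.node_table.get_value(0, "c") == "ok"

    def test_update_selection_replaces_exactly(self, plain_bundle):
        ws = workspace_with(plain_bundle)
        ws.set_selection("net", {0}, set())
        apply_actions(ws, [ResultAction("updateSelection",
                                        {"nodes": [1, 2], "edges": []})])
        assert ws.selections["net"] == ({1, 2}, set())

    def test_open_url_is_an_external_effect_only(self, plain_bundle):
        ws = workspace_with(plain_bundle)
        before = serialize_cx2_obj(plain_bundle)
        _, report = apply_actions(
            ws, [ResultAction("openURL", {"url": "https://example.org"})]
        )
        assert report.effects == [("openURL", "https://example.org")]
        assert serialize_cx2_obj(plain_bundle) == before

    def test_add_networks_uses_a_fresh_name(self, plain_bundle, small_bundle):
        ws = workspace_with(plain_bundle)
        payload = {"networks": [{"name": "net",
                                 "cx2": serialize_cx2_obj(small_bundle)}]}
        apply_actions(ws, [ResultAction("addNetworks", payload)])
        assert set(ws.networks) == {"net", "net (2)"}
        assert ws.current_network == "net"

    def test_update_layouts_moves_listed_nodes(self, plain_bundle):
        ws = workspace_with(plain_bundle)
        apply_actions(ws, [ResultAction("updateLayouts",
                                        {"positions": {"0": [5.0, 6.0]}})])
        assert plain_bundle.position(0) == (5.0, 6.0)

    def test_malformed_payload_raises_but_keeps_prior_actions(self, plain_bundle):
        ws = workspace_with(plain_bundle)
        good = ResultAction("updateLayouts", {"positions": {"0": [1.0, 2.0]}})
        bad = ResultAction("updateLayouts", {"wrong": True})
        with pytest.raises(CxValidationError):
            apply_actions(ws, [good, bad])
        assert plain_bundle.position(0) == (1.0, 2.0)

    def test_unknown_action_kind_rejected_at_construction(self):
        with pytest.raises(CxValidationError):
            ResultAction("reformatDisk", {})


class TestRegistry:
    def test_register_list_and_duplicate(self):
        ws = Workspace()
        assert list_services(ws) == []
        register_service(ws, "https://svc.example/one")
        assert [s.url for s in list_services(ws)] == ["https://svc.example/one"]
        with pytest.raises(ConflictError):
            register_service(ws, "https://svc.example/one")
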