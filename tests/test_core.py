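"""Network model, attribute coercion, size limits, workspace snapshots."""

import io

import pytest

from cxweb.core import (
    AttributeDeclaration,
    ElementTable,
    NetworkBundle,
    SizeLimitPolicy,
    Workspace,
    check_size_limits,
    coerce_value,
    load_workspace,
    save_workspace,
)
from cxweb.errors import (
    ConflictError,
    CxParseError,
    ElementReferenceError,
    TypeCoercionError,
)
from cxweb.service import register_service
from tests.conftest import bundles_equal


class TestGraphMutations:
    def test_first_node_gets_id_zero(self):
        bundle = NetworkBundle()
        assert bundle.add_node() == 0
        assert bundle.node_count() == 1

    def test_duplicate_node_id_conflicts(self):
        bundle = NetworkBundle()
        bundle.add_node(5)
        with pytest.raises(ConflictError):
            bundle.add_node(5)

    def test_ids_resume_after_explicit_assignment(self):
        bundle = NetworkBundle()
        bundle.add_node(7)
        assert bundle.add_node() == 8

    def test_edge_requires_existing_endpoints(self):
        bundle = NetworkBundle()
        bundle.add_node(0)
        bundle.add_node(1)
        assert bundle.add_edge(0, 1) == 0
        assert bundle.edge_count() == 1
        with pytest.raises(ElementReferenceError):
            bundle.add_edge(0, 9)

    def test_self_loops_and_parallel_edges_allowed(self):
        bundle = NetworkBundle()
        bundle.add_node(0)
        bundle.add_node(1)
        bundle.add_edge(0, 0)
        bundle.add_edge(0, 1)
        bundle.add_edge(0, 1)
        assert bundle.edge_count() == 3

    def test_removing_node_cascades_to_edges_and_tables(self):
        bundle = NetworkBundle()
        bundle.add_node(0, {"name": "a"})
        bundle.add_node(1)
        bundle.add_edge(0, 1, {"weight": 1.0})
        bundle.remove_node(0)
        assert bundle.edge_count() == 0
        assert 0 not in bundle.node_table.rows
        bundle.check_integrity()


class TestCoercion:
    @pytest.mark.parametrize(
        "value,datatype,expected",
        [
            ("3", "double", 3.0),
            ("42", "integer", 42),
            (7, "double", 7.0),
            ("true", "boolean", True),
            (["a", "b"], "list_of_string", ["a", "b"]),
            (["1", "2"], "list_of_integer", [1, 2]),
        ],
    )
    def test_accepted_coercions(self, value, datatype, expected):
        assert coerce_value(value, datatype) == expected

    @pytest.mark.parametrize(
        "value,datatype",
        [
            ("yes", "boolean"),       # only true/false accepted
            (3.5, "integer"),         # lossy cast
            ("x", "double"),
            (1, "string"),            # no silent stringification
            ("a b c", "list_of_string"),  # no implicit splitting
        ],
    )
    def test_rejected_coercions(self, value, datatype):
        with pytest.raises(TypeCoercionError):
            coerce_value(value, datatype)

    def test_string_attribute_reads_back_verbatim(self):
        table = ElementTable("nodes")
        table.set_value(0, "name", "TP53")
        assert table.get_value(0, "name") == "TP53"

    def test_declared_double_coerces_string_value(self):
        bundle = NetworkBundle()
        bundle.node_table.declare(AttributeDeclaration("score", "double"))
        bundle.add_node(0, {"score": "3"})
        assert bundle.node_table.get_value(0, "score") == 3.0

    def test_auto_declaration_infers_type(self):
        table = ElementTable("nodes")
        table.set_value(0, "hits", 3)
        assert table.declarations["hits"].datatype == "integer"
        with pytest.raises(TypeCoercionError):
            table.set_value(1, "hits", "many")

    def test_error_names_attribute_and_element(self):
        table = ElementTable("nodes")
        table.declare(AttributeDeclaration("flag", "boolean"))
        with pytest.raises(TypeCoercionError, match=r"'flag' on nodes element 4"):
            table.set_value(4, "flag", "yes")

    def test_declaration_default_applies_when_value_absent(self):
        table = ElementTable("nodes")
        table.declare(AttributeDeclaration("kind", "string", default="unknown"))
        assert table.get_value(0, "kind") == "unknown"


class TestSizeLimits:
    def test_boundary_accepts_printed_limits(self):
        assert check_size_limits(6_000, 20_000).accepted

    def test_empty_network_accepted(self):
        assert check_size_limits(0, 0).accepted

    def test_one_edge_past_edge_cap_rejected(self):
        decision = check_size_limits(100, 20_001)
        assert not decision.accepted
        assert decision.reason == "edge limit"

    def test_one_element_past_combined_cap_rejected(self):
        assert check_size_limits(10_000, 16_000).accepted
        decision = check_size_limits(10_000, 16_001)
        assert not decision.accepted
        assert decision.reason == "combined limit"

    def test_monotone_in_edge_count(self):
        # adding an edge never flips rejected back to accepted
        previous = True
        for edges in range(19_990, 20_010):
            accepted = check_size_limits(5_000, edges).accepted
            assert previous or not accepted
            previous = accepted

    def test_policy_rejects_nonpositive_limits(self):
        with pytest.raises(ValueError):
            SizeLimitPolicy(max_edges=0)


class TestWorkspaceSnapshots:
    def _workspace(self, small_bundle, plain_bundle) -> Workspace:
        ws = Workspace()
        ws.add_network("alpha", small_bundle)
        ws.add_network("beta", plain_bundle, current=False)
        ws.set_selection("alpha", {0, 1}, {2})
        ws.set_panel("right", "closed")
        ws.active_table_tab = 2
        register_service(ws, "https://example.org/v1/service")
        return ws

    def test_round_trip_preserves_everything(self, small_bundle, plain_bundle):
        ws = self._workspace(small_bundle, plain_bundle)
        sink = io.StringIO()
        save_workspace(ws, sink)
        restored = load_workspace(io.StringIO(sink.getvalue()))
        assert set(restored.networks) == {"alpha", "beta"}
        assert restored.current_network == "alpha"
        assert restored.selections["alpha"] == ({0, 1}, {2})
        assert restored.panel_states == {"left": "open", "right": "closed",
                                         "bottom": "open"}
        assert restored.active_table_tab == 2
        assert [s.url for s in restored.installed_services] == [
            "https://example.org/v1/service"
        ]
        for name in ws.networks:
            assert bundles_equal(ws.networks[name], restored.networks[name])

    def test_truncated_snapshot_is_a_parse_error(self, small_bundle, plain_bundle):
        ws = self._workspace(small_bundle, plain_bundle)
        sink = io.StringIO()
        save_workspace(ws, sink)
        truncated = sink.getvalue()[: len(sink.getvalue()) // 2]
        with pytest.raises(CxParseError):
            load_workspace(io.StringIO(truncated))

    def test_selection_must_reference_existing_elements(self, plain_bundle):
        ws = Workspace()
        ws.add_network("net", plain_bundle)
        with pytest.raises(ElementReferenceError):
            ws.set_selection("net", {999}, set())
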