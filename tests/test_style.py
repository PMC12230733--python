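"""Visual-style mapping evaluation and resolution precedence."""

import pytest
from hypothesis import given, settings, strategies as st

from cxweb.core import ElementTable, NetworkBundle
from cxweb.errors import ContractError
from cxweb.fixtures import FixtureSpec, random_bundle, style_fixture
from cxweb.style import (
    NO_MATCH,
    VISUAL_PROPERTIES,
    ContinuousControlPoint,
    MappingDefinition,
    VisualStyle,
    evaluate_continuous,
    evaluate_discrete,
    evaluate_passthrough,
    resolve_element_property,
    resolve_sheet,
)

SIZE = VISUAL_PROPERTIES["NODE_SIZE"]
COLOR = VISUAL_PROPERTIES["NODE_BACKGROUND_COLOR"]
LABEL = VISUAL_PROPERTIES["NODE_LABEL"]


def size_ramp(points):
    return MappingDefinition(
        "continuous", "score",
        continuous_points=[ContinuousControlPoint(t, v) for t, v in points],
    )


class TestContinuous:
    RAMP = size_ramp([(0, 10.0), (100, 50.0)])

    def test_linear_interpolation(self):
        # straight-line oracle: 10 + 0.25 * 40
        assert evaluate_continuous(self.RAMP, 25, SIZE) == 20.0

    def test_control_points_are_exact(self):
        assert evaluate_continuous(self.RAMP, 100, SIZE) == 50.0
        assert evaluate_continuous(self.RAMP, 0, SIZE) == 10.0

    def test_out_of_range_clamps_to_terminal_points(self):
        assert evaluate_continuous(self.RAMP, -5, SIZE) == 10.0
        assert evaluate_continuous(self.RAMP, 1e9, SIZE) == 50.0

    def test_color_interpolates_per_channel_with_half_up_rounding(self):
        ramp = size_ramp([(0, "#000000"), (100, "#FFFFFF")])
        # per-channel oracle: round_half_up(127.5) = 128 = 0x80
        assert evaluate_continuous(ramp, 50, COLOR) == "#808080"

    def test_non_numeric_input_signals_no_match(self):
        assert evaluate_continuous(self.RAMP, "high", SIZE) is NO_MATCH
        assert evaluate_continuous(self.RAMP, True, SIZE) is NO_MATCH

    def test_thresholds_must_strictly_increase(self):
        with pytest.raises(ValueError):
            size_ramp([(0, 1.0), (0, 2.0)])
        with pytest.raises(ValueError):
            size_ramp([(5, 1.0)])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        a=st.floats(-100, 100), span=st.floats(1, 100),
        lo=st.floats(0, 50), hi=st.floats(51, 200),
    )
    def test_midpoint_equals_mean_of_endpoints(self, a, span, lo, hi):
        ramp = size_ramp([(a, lo), (a + span, hi)])
        mid = evaluate_continuous(ramp, a + span / 2, SIZE)
        assert mid == pytest.approx((lo + hi) / 2, abs=1e-9)


class TestDiscreteAndPassthrough:
    def test_discrete_lookup_and_fallback(self):
        mapping = MappingDefinition(
            "discrete", "type", discrete_map=[("kinase", "triangle")]
        )
        assert evaluate_discrete(mapping, "kinase") == "triangle"
        assert evaluate_discrete(mapping, "phosphatase") is NO_MATCH

    def test_discrete_on_boolean_attribute(self):
        mapping = MappingDefinition(
            "discrete", "active", discrete_map=[(True, "#FF0000")]
        )
        assert evaluate_discrete(mapping, True) == "#FF0000"
        assert evaluate_discrete(mapping, 1) is NO_MATCH  # bools are not ints

    def test_passthrough_label(self):
        mapping = MappingDefinition("passthrough", "name")
        assert evaluate_passthrough(mapping, "TP53", LABEL) == "TP53"

    def test_passthrough_color_strict_parse(self):
        mapping = MappingDefinition("passthrough", "col")
        assert evaluate_passthrough(mapping, "#00FF00", COLOR) == "#00FF00"
        assert evaluate_passthrough(mapping, "green-ish", COLOR) is NO_MATCH


class TestResolution:
    def _bundle_with_mapping(self):
        bundle = NetworkBundle()
        bundle.add_node(7, {"score": 50.0})
        bundle.style.set_mapping(
            "NODE_BACKGROUND_COLOR",
            size_ramp([(0, "#000000"), (100, "#FFFFFF")]),
        )
        return bundle

    def test_bypass_beats_mapping(self):
        bundle = self._bundle_with_mapping()
        bundle.node_bypasses[7] = {"NODE_BACKGROUND_COLOR": "#123456"}
        value = resolve_element_property(
            "NODE_BACKGROUND_COLOR", 7, bundle.style, bundle.node_bypasses,
            bundle.node_table,
        )
        assert value == "#123456"

    def test_mapping_beats_default(self):
        bundle = self._bundle_with_mapping()
        value = resolve_element_property(
            "NODE_BACKGROUND_COLOR", 7, bundle.style, bundle.node_bypasses,
            bundle.node_table,
        )
        assert value == "#808080"

    def test_missing_attribute_falls_back_to_default(self):
        bundle = self._bundle_with_mapping()
        bundle.node_table.rows[7].pop("score")
        value = resolve_element_property(
            "NODE_BACKGROUND_COLOR", 7, bundle.style, bundle.node_bypasses,
            bundle.node_table,
        )
        assert value == bundle.style.defaults["NODE_BACKGROUND_COLOR"]

    def test_unknown_property_is_a_contract_error(self):
        with pytest.raises(ContractError):
            resolve_element_property(
                "NODE_AURA", 0, VisualStyle.default(), {}, ElementTable("nodes")
            )

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_sheet_equals_elementwise_resolution(self, seed):
        bundle = random_bundle(FixtureSpec(seed=seed, node_count=6, edge_count=8))
        sheet = resolve_sheet(bundle)
        for nid in bundle.node_ids:
            for prop in sheet["nodes"].columns:
                expected = resolve_element_property(
                    prop, nid, bundle.style, bundle.node_bypasses,
                    bundle.node_table,
                )
                assert sheet["nodes"].loc[nid, prop] == expected
        for eid in bundle.edge_ids:
            for prop in sheet["edges"].columns:
                expected = resolve_element_property(
                    prop, eid, bundle.style, bundle.edge_bypasses,
                    bundle.edge_table,
                )
                assert sheet["edges"].loc[eid, prop] == expected

    def test_defaults_only_style_gives_identical_rows(self):
        bundle = NetworkBundle()
        for i in range(3):
            bundle.add_node(i)
        sheet = resolve_sheet(bundle)["nodes"]
        assert (sheet.nunique() == 1).all()

    def test_empty_network_gives_empty_sheet(self):
        sheet = resolve_sheet(NetworkBundle())
        assert sheet["nodes"].empty and sheet["edges"].empty

    def test_removing_attributes_only_moves_results_toward_defaults(self):
        bundle = random_bundle(FixtureSpec(seed=4, node_count=5, edge_count=5))
        before = resolve_sheet(bundle)["nodes"]
        bundle.node_table.rows = {}
        after = resolve_sheet(bundle)["nodes"]
        defaults = bundle.style.defaults
        for nid in bundle.node_ids:
            for prop in after.columns:
                if after.loc[nid, prop] != before.loc[nid, prop]:
                    assert after.loc[nid, prop] == defaults[prop]

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(1, 1000), value=st.text(min_size=1, max_size=8))
    def test_precedence_law_bypass_always_wins(self, seed, value):
        style = style_fixture(seed)
        table = ElementTable("nodes")
        table.set_value(0, "name", value)
        bypasses = {0: {"NODE_LABEL": "BYPASSED"}}
        resolved = resolve_element_property(
            "NODE_LABEL", 0, style, bypasses, table
        )
        assert resolved == "BYPASSED"
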