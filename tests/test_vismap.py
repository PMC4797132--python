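import numpy as np
import pandas as pd
import pytest

from modnet import (ConditionSeries, Network, VisualMapping, apply_mapping,
                    condition_matrix, overlay_series)


@pytest.fixture
def valued_net():
    net = Network()
    net.add_node("a", freq=1.0)
    net.add_node("b", freq=2.0)
    net.add_node("c", freq=3.0)
    net.add_edge("a", "b", weight=0.5)
    net.add_edge("b", "c", weight=-0.5)
    return net


class TestApplyMapping:
    def test_linear_endpoints_and_midpoint(self, valued_net):
        m = VisualMapping("freq", "node_size", domain=(1, 3), range=(10, 30))
        out = apply_mapping(valued_net, m)
        assert list(out["style"]) == [10.0, 20.0, 30.0]

    def test_clamp_out_of_domain(self, valued_net):
        valued_net.add_node("d", freq=5.0)
        m = VisualMapping("freq", "node_size", domain=(1, 3), range=(10, 30))
        out = apply_mapping(valued_net, m)
        assert out.loc["d", "style"] == 30.0
        assert out.loc["d", "flag"] == "clamped"

    def test_hide_out_of_domain(self, valued_net):
        valued_net.add_node("d", freq=5.0)
        m = VisualMapping("freq", "node_size", domain=(1, 3), range=(10, 30),
                         out_of_domain="hide")
        out = apply_mapping(valued_net, m)
        assert out.loc["d", "flag"] == "hidden"

    def test_diverging_midpoint_is_white(self):
        net = Network()
        net.add_node("x", v=0.0)
        m = VisualMapping("v", "node_color", domain=(-2, 2),
                          range=("#0000ff", "#ffffff", "#ff0000"))
        out = apply_mapping(net, m)
        assert out.loc["x", "style"] == "#ffffff"

    def test_missing_value_neutral(self, valued_net):
        valued_net.add_node("naked")
        m = VisualMapping("freq", "node_color", domain=(1, 3),
                          range=("#000000", "#ffffff"))
        out = apply_mapping(valued_net, m)
        assert out.loc["naked", "flag"] == "absent"

    def test_constant_attribute_maps_to_midpoint(self):
        net = Network()
        net.add_node("a", v=2.0)
        net.add_node("b", v=2.0)
        m = VisualMapping("v", "node_size", domain="auto", range=(10, 30))
        with pytest.warns(UserWarning):
            out = apply_mapping(net, m)
        assert list(out["style"]) == [20.0, 20.0]

    def test_monotone_in_value(self):
        rng = np.random.default_rng(4)
        net = Network()
        vals = rng.uniform(-5, 5, 25)
        for i, v in enumerate(vals):
            net.add_node(f"n{i:02d}", v=float(v))
        m = VisualMapping("v", "node_size", domain="auto", range=(5, 50))
        out = apply_mapping(net, m)
        df = out.sort_values("value")
        assert df["style"].is_monotonic_increasing

    def test_idempotent(self, valued_net):
        m = VisualMapping("freq", "node_size", domain=(1, 3), range=(10, 30))
        a = apply_mapping(valued_net, m)
        b = apply_mapping(valued_net, m)
        pd.testing.assert_frame_equal(a, b)

    def test_edge_width_mapping(self, valued_net):
        m = VisualMapping("weight", "edge_width", domain=(-1, 1), range=(0, 8))
        out = apply_mapping(valued_net, m)
        assert out.loc["a|b", "style"] == pytest.approx(6.0)
        assert out.loc["b|c", "style"] == pytest.approx(2.0)


class TestOverlaySeries:
    @pytest.fixture
    def series(self):
        vals = pd.DataFrame({"cond1": [0.0, 1.0, 2.0], "cond2": [4.0, 1.0, 0.0]},
                            index=["a", "b", "c"])
        return ConditionSeries(conditions=["cond1", "cond2"], values=vals)

    @pytest.fixture
    def coords(self):
        return {"a": (0.0, 0.0), "b": (1.0, 1.0), "c": (2.0, 0.0)}

    def test_one_frame_per_condition_identical_coords(self, valued_net, series,
                                                      coords):
        m = VisualMapping("expr", "node_color", range=("#000000", "#ffffff"))
        frames = overlay_series(valued_net, series, m, coords)
        assert list(frames) == ["cond1", "cond2"]
        xy1 = frames["cond1"][["x", "y"]]
        xy2 = frames["cond2"][["x", "y"]]
        pd.testing.assert_frame_equal(xy1, xy2)

    def test_shared_domain_across_conditions(self, valued_net, series, coords):
        """The series-global max gets the range-max style in its own frame."""
        m = VisualMapping("expr", "node_color", range=("#000000", "#ffffff"))
        frames = overlay_series(valued_net, series, m, coords)
        # global max 4.0 sits in cond2 at node a
        assert frames["cond2"].loc["a", "style"] == "#ffffff"
        # cond1's local max (2.0) must NOT reach the range max
        assert frames["cond1"].loc["c", "style"] != "#ffffff"

    def test_all_missing_condition_neutral_frame(self, valued_net, coords):
        vals = pd.DataFrame({"ok": [1.0, 2.0, 3.0],
                             "gone": [np.nan] * 3}, index=["a", "b", "c"])
        series = ConditionSeries(conditions=["ok", "gone"], values=vals)
        m = VisualMapping("expr", "node_color", range=("#000000", "#ffffff"))
        with pytest.warns(UserWarning):
            frames = overlay_series(valued_net, series, m, coords)
        assert (frames["gone"]["flag"] == "absent").all()

    def test_edge_target_rejected(self, valued_net, series, coords):
        m = VisualMapping("w", "edge_width")
        with pytest.raises(ValueError):
            overlay_series(valued_net, series, m, coords)


class TestConditionMatrix:
    def test_shape_and_header(self):
        vals = pd.DataFrame({"c1": [1, 2, 3], "c2": [4, 5, 6]},
                            index=["a", "b", "c"])
        series = ConditionSeries(conditions=["c1", "c2"], values=vals)
        out = condition_matrix(series)
        assert out.shape == (3, 2) and list(out.columns) == ["c1", "c2"]

    def test_cluster_order_groups_rows(self):
        vals = pd.DataFrame({"c1": [1, 2, 3, 4]}, index=list("abcd"))
        series = ConditionSeries(conditions=["c1"], values=vals)
        out = condition_matrix(series, node_order=["c", "a", "d", "b"])
        assert list(out.index) == ["c", "a", "d", "b"]
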