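"""Feed-forward diffusion model: activation ramp analytics, layering rules,
propagation arithmetic, monotonicity and superposition properties."""

import dataclasses

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ringconn import (
    FFNParams,
    Neuron,
    SynapseEdge,
    ValidationError,
    activation,
    aggregate,
    build_ffn,
    input_fractions,
    mean_group_activity,
    propagate,
    sweep,
)
from conftest import cluster_groups, random_connectome

P = FFNParams()


def chain(w1_count, w1_total, w2_count, w2_total):
    """s -> i -> r with controllable input fractions via filler neurons."""
    neurons = [
        Neuron("s", cell_class="sensory", sensory_origin="CO2"),
        Neuron("i", cell_class="interneuron"),
        Neuron("r", cell_class="rpn", cluster="CRZ"),
        Neuron("f1", cell_class="other"),
        Neuron("f2", cell_class="other"),
    ]
    edges = [SynapseEdge("s", "i", w1_count), SynapseEdge("i", "r", w2_count)]
    if w1_total > w1_count:
        edges.append(SynapseEdge("f1", "i", w1_total - w1_count))
    if w2_total > w2_count:
        edges.append(SynapseEdge("f2", "r", w2_total - w2_count))
    c = aggregate(neurons, edges)
    return c, input_fractions(c)


class TestActivation:
    @pytest.mark.parametrize(
        "x,expected",
        [
            (0.0, 0.0),
            (0.03, 0.0),          # below onset
            (0.05, 0.0),          # continuity at the onset knot
            (0.275, 0.5),         # ramp midpoint: (0.275-0.05)/0.45
            (0.5, 1.0),           # continuity at the saturation knot
            (0.6, 1.0),
            (2.0, 1.0),
        ],
    )
    def test_default_ramp(self, x, expected):
        assert activation(x, P) == pytest.approx(expected, abs=1e-15)

    def test_continuity_at_knots(self):
        eps = 1e-13
        assert abs(activation(P.a + eps, P) - activation(P.a, P)) < 1e-12
        assert abs(activation(P.b - eps, P) - activation(P.b, P)) < 1e-12

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            activation(-0.1, P)

    @given(st.floats(min_value=0, max_value=5, allow_nan=False))
    def test_bounded_and_monotone(self, x):
        y = activation(x, P)
        assert 0.0 <= y <= 1.0
        assert activation(x + 0.01, P) >= y

    def test_invalid_params(self):
        with pytest.raises(ValidationError):
            FFNParams(a=0.5, b=0.5)
        with pytest.raises(ValidationError):
            FFNParams(activation_factor=-1)
        with pytest.raises(ValidationError):
            FFNParams(max_hops=3)


class TestBuildFFN:
    def test_chain_layers(self):
        c, wa = chain(5, 5, 4, 4)
        net = build_ffn(c, wa, {"s"}, {"r"})
        assert net.layers[0] == {"s"}
        assert net.layers[1] == {"i"}
        assert net.layers[2] == {"r"}
        assert set(net.forward_edges) == {("s", "i"), ("i", "r")}

    def test_intra_layer_edge_dropped_and_logged(self):
        neurons = [Neuron("s", cell_class="sensory", sensory_origin="CO2"),
                   Neuron("i1", cell_class="interneuron"),
                   Neuron("i2", cell_class="interneuron"),
                   Neuron("r", cell_class="rpn")]
        c = aggregate(neurons, [SynapseEdge("s", "i1", 5), SynapseEdge("s", "i2", 5),
                                SynapseEdge("i1", "i2", 7), SynapseEdge("i2", "r", 5)])
        net = build_ffn(c, input_fractions(c), {"s"}, {"r"})
        assert ("i1", "i2") not in net.forward_edges
        assert any(d[:2] == ("i1", "i2") for d in net.dropped_edges)

    def test_direct_sensory_rpn_edge_in_layer1(self):
        neurons = [Neuron("s", cell_class="sensory", sensory_origin="CO2"),
                   Neuron("r", cell_class="rpn")]
        c = aggregate(neurons, [SynapseEdge("s", "r", 6)])
        net = build_ffn(c, input_fractions(c), {"s"}, {"r"})
        assert "r" in net.layers[1] and ("s", "r") in net.forward_edges

    def test_no_sensory_edges_is_error(self):
        neurons = [Neuron("s", cell_class="sensory", sensory_origin="CO2"),
                   Neuron("i", cell_class="interneuron"),
                   Neuron("r", cell_class="rpn")]
        c = aggregate(neurons, [SynapseEdge("i", "r", 3)])
        with pytest.raises(ValidationError, match="empty network"):
            build_ffn(c, input_fractions(c), {"s"}, {"r"})

    def test_dual_depth_rpn_keeps_hop2_inputs(self):
        # r reached monosynaptically and via i: earliest layer, both routes kept
        neurons = [Neuron("s", cell_class="sensory", sensory_origin="CO2"),
                   Neuron("i", cell_class="interneuron"),
                   Neuron("r", cell_class="rpn")]
        c = aggregate(neurons, [SynapseEdge("s", "r", 4), SynapseEdge("s", "i", 5),
                                SynapseEdge("i", "r", 6)])
        net = build_ffn(c, input_fractions(c), {"s"}, {"r"})
        assert "r" in net.layers[1] and "r" not in net.layers[2]
        assert ("s", "r") in net.forward_edges and ("i", "r") in net.forward_edges


class TestPropagate:
    def test_hand_computed_ramp(self):
        # weight 0.1, source activity 2 -> x = 0.2 -> (0.2-0.05)/0.45 = 1/3
        c, wa = chain(1, 10, 1, 1)
        net = build_ffn(c, wa, {"s"}, {"r"})
        state = propagate(net, "CO2", P)
        assert state.x["i"] == pytest.approx(0.2)
        assert state.activities["i"] == pytest.approx(1 / 3)

    def test_silent_origin_gives_zero(self):
        neurons = [Neuron("s1", cell_class="sensory", sensory_origin="CO2"),
                   Neuron("s2", cell_class="sensory", sensory_origin="enteric"),
                   Neuron("i", cell_class="interneuron")]
        c = aggregate(neurons, [SynapseEdge("s1", "i", 5), SynapseEdge("s2", "i", 5)])
        state = propagate(build_ffn(c, input_fractions(c), {"s1", "s2"}, set()), "enteric", P)
        assert state.activities["s1"] == 0.0 and state.activities["s2"] == 2.0
        assert state.activities["i"] == pytest.approx(activation(1.0, P)) == 1.0

    def test_two_half_weight_sources_saturate(self):
        neurons = [Neuron("s1", cell_class="sensory", sensory_origin="CO2"),
                   Neuron("s2", cell_class="sensory", sensory_origin="CO2"),
                   Neuron("i", cell_class="interneuron")]
        c = aggregate(neurons, [SynapseEdge("s1", "i", 5), SynapseEdge("s2", "i", 5)])
        state = propagate(build_ffn(c, input_fractions(c), {"s1", "s2"}, set()), "CO2", P)
        assert state.x["i"] == pytest.approx(2.0)  # 0.5*2 + 0.5*2
        assert state.activities["i"] == 1.0

    def test_unknown_origin_lists_known(self, tiny):
        net = build_ffn(tiny, input_fractions(tiny), {"s1", "s2"}, {"r1"})
        with pytest.raises(ValidationError, match="CO2"):
            propagate(net, "gustatory", P)

    def test_chain_closed_form(self):
        for w1c, w1t, w2c, w2t in [(1, 10, 1, 2), (3, 20, 5, 8), (2, 5, 1, 10)]:
            c, wa = chain(w1c, w1t, w2c, w2t)
            net = build_ffn(c, wa, {"s"}, {"r"})
            state = propagate(net, "CO2", P)
            w1, w2 = w1c / w1t, w2c / w2t
            expected = activation(w2 * activation(2 * w1, P), P)
            assert state.activities["r"] == pytest.approx(expected, abs=1e-12)

    def test_non_sensory_activities_bounded(self):
        c = random_connectome(21)
        wa = input_fractions(c)
        net = build_ffn(c, wa, c.ids_of_class("sensory"), c.ids_of_class("rpn"))
        for origin in net.origins():
            state = propagate(net, origin, P)
            for nid, act in state.activities.items():
                if nid not in net.sensory:
                    assert 0.0 <= act <= 1.0

    def test_monotone_in_weight_and_factor(self):
        c, wa = chain(1, 10, 1, 2)
        net = build_ffn(c, wa, {"s"}, {"r"})
        base = propagate(net, "CO2", P).activities["r"]
        # larger first-hop weight
        c2, wa2 = chain(2, 10, 1, 2)
        net2 = build_ffn(c2, wa2, {"s"}, {"r"})
        assert propagate(net2, "CO2", P).activities["r"] >= base
        # larger activation factor
        stronger = propagate(net, "CO2", dataclasses.replace(P, activation_factor=3.0))
        assert stronger.activities["r"] >= base

    def test_superposition_bound(self):
        c = random_connectome(5)
        wa = input_fractions(c)
        net = build_ffn(c, wa, c.ids_of_class("sensory"), c.ids_of_class("rpn"))
        origins = net.origins()
        joint = propagate(net, origins[:2], P).activities
        for origin in origins[:2]:
            single = propagate(net, origin, P).activities
            for nid in joint:
                if nid not in net.sensory:
                    assert joint[nid] >= single[nid] - 1e-12

    def test_zero_factor_all_silent(self, tiny):
        net = build_ffn(tiny, input_fractions(tiny), {"s1", "s2"}, {"r1"})
        state = propagate(net, "CO2", dataclasses.replace(P, activation_factor=0.0))
        assert all(v == 0.0 for v in state.activities.values())


class TestGroupActivity:
    def test_mean_and_identity(self):
        c, wa = chain(1, 10, 1, 1)
        net = build_ffn(c, wa, {"s"}, {"r"})
        state = propagate(net, "CO2", P)
        gm = mean_group_activity(state, {"CRZ": {"r"}, "pair": {"r", "absent"}})
        vals = dict(zip(gm["group"], gm["mean_activity"]))
        assert vals["CRZ"] == pytest.approx(state.activities["r"])
        assert vals["pair"] == pytest.approx(state.activities["r"] / 2)  # absent member = 0

    def test_empty_group_rejected(self):
        c, wa = chain(1, 1, 1, 1)
        net = build_ffn(c, wa, {"s"}, {"r"})
        with pytest.raises(ValidationError, match="empty group"):
            mean_group_activity(propagate(net, "CO2", P), {"none": set()})


class TestSweep:
    def test_monotone_in_factor_and_saturation(self):
        c = random_connectome(8)
        wa = input_fractions(c)
        net = build_ffn(c, wa, c.ids_of_class("sensory"), c.ids_of_class("rpn"))
        groups = cluster_groups(c)
        table = sweep(net, net.origins(), [0.0, 0.5, 1.0, 2.0, 100.0], groups, P)
        for (origin, group), sub in table.groupby(["origin", "group"]):
            acts = sub.sort_values("factor")["mean_activity"].tolist()
            assert acts == sorted(acts)  # non-decreasing in factor
        assert (table[table["factor"] == 0.0]["mean_activity"] == 0.0).all()
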