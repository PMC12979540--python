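import numpy as np
import pytest

from lmppm.architectures import build_resnet101, small_omnet_config, \
    build_omnet
from lmppm.cost import count_params
from lmppm.graph import GraphError, LayerDescriptor, LayerGraph
from lmppm.nn import Network, expand_params, init_params, param_element_count
from lmppm.transform import (ExpandSpec, PruneSpec, TransformReport,
                             apply_lmp_pm, expand_paths, prune_channels,
                             to_depthwise_separable)


def _toy_conv_graph(cout=64, k=3, cin=3):
    layers = [
        LayerDescriptor(id="in", kind="input", out_channels=cin),
        LayerDescriptor(id="c", kind="conv", in_channels=cin,
                        out_channels=cout, kernel=k, padding=k // 2,
                        predecessors=["in"]),
        LayerDescriptor(id="gap", kind="globalavgpool", in_channels=cout,
                        out_channels=cout, predecessors=["c"]),
        LayerDescriptor(id="fl", kind="flatten", in_channels=cout,
                        out_channels=cout, predecessors=["gap"]),
        LayerDescriptor(id="fc", kind="dense", in_channels=cout,
                        out_channels=2, bias=True, predecessors=["fl"]),
    ]
    return LayerGraph.from_layers(layers, input_size=8, num_classes=2,
                                  classifier="fc", head_start="fl")


def test_prune_divides_width_and_repropagates():
    g = prune_channels(_toy_conv_graph(cout=64), PruneSpec(N=4))
    assert g.layers["c"].out_channels == 16
    assert g.layers["fc"].in_channels == 16


def test_prune_guard_keeps_small_layers():
    g = prune_channels(_toy_conv_graph(cout=3), PruneSpec(N=16))
    assert g.layers["c"].out_channels == 3          # 3/16 <= 1: untouched


def test_prune_n1_is_identity(micro_graph):
    out = prune_channels(micro_graph, PruneSpec(N=1))
    assert [l.to_dict() for l in out.layers.values()] == \
        [l.to_dict() for l in micro_graph.layers.values()]


def test_prune_never_touches_classifier(micro_graph):
    for n in (2, 4, 16, 64):
        out = prune_channels(micro_graph, PruneSpec(N=n))
        assert out.layers[out.classifier].out_channels == out.num_classes


def test_prune_guard_no_zero_width(micro_graph):
    for n in (2, 3, 5, 8, 16, 33, 100):
        out = prune_channels(micro_graph, PruneSpec(N=n))
        widths = [l.out_channels for l in out.layers.values()
                  if l.kind == "conv"]
        assert min(widths) >= 1


def test_depthwise_conversion_parameter_arithmetic():
    # 3x3 conv 64->128 bias-free: 73,728 -> dw 9*64 + pw 64*128 = 8,768
    layers = [
        LayerDescriptor(id="in", kind="input", out_channels=64),
        LayerDescriptor(id="c", kind="conv", in_channels=64, out_channels=128,
                        kernel=3, padding=1, predecessors=["in"]),
        LayerDescriptor(id="gap", kind="globalavgpool", in_channels=128,
                        out_channels=128, predecessors=["c"]),
        LayerDescriptor(id="fl", kind="flatten", in_channels=128,
                        out_channels=128, predecessors=["gap"]),
        LayerDescriptor(id="fc", kind="dense", in_channels=128,
                        out_channels=2, bias=True, predecessors=["fl"]),
    ]
    g = LayerGraph.from_layers(layers, input_size=8, num_classes=2,
                               classifier="fc", head_start="fl")
    before = count_params(g)
    out = to_depthwise_separable(g)
    conv_params = sum(
        l.kernel ** 2 * (l.in_channels // l.groups) * l.out_channels
        for l in out.layers.values() if l.kind == "conv")
    assert conv_params == 9 * 64 + 64 * 128 == 8768
    assert before - count_params(out) == 73728 - 8768


def test_depthwise_conversion_leaves_1x1_convs_alone():
    g = _toy_conv_graph(cout=32, k=1)
    out = to_depthwise_separable(g)
    assert "c" in out.layers and "c.dw" not in out.layers


def test_depthwise_conversion_rejects_grouped_convs():
    g = _toy_conv_graph(cout=32)
    g.layers["c"].in_channels = 3
    layers = list(g.layers.values())
    layers[1] = LayerDescriptor(id="c", kind="conv", in_channels=4,
                                out_channels=8, kernel=3, padding=1, groups=2,
                                predecessors=["in"])
    layers[0].out_channels = 4
    g2 = LayerGraph.from_layers(layers, input_size=8, num_classes=2,
                                classifier="fc")
    with pytest.raises(GraphError, match="groups"):
        to_depthwise_separable(g2)


def test_expand_e1_returns_graph_unchanged(micro_graph):
    out = expand_paths(micro_graph, ExpandSpec(E=1))
    assert [l.to_dict() for l in out.layers.values()] == \
        [l.to_dict() for l in micro_graph.layers.values()]


def test_expand_rejects_invalid_path_count():
    with pytest.raises(GraphError):
        ExpandSpec(E=0)


def test_pre_reinit_paths_numerically_identical(micro_graph, rng):
    """With re-initialisation disabled every path computes the same features."""
    g = micro_graph
    e3 = expand_paths(g, ExpandSpec(E=3, shared_stem=True))
    params = init_params(g, seed=3, zero_classifier=False)
    p3 = expand_params(g, params, e3, E=3, reinit=False)
    net = Network(e3, params=p3)
    x = rng.normal(size=(2, 3, 32, 32))
    net.forward(x, train=True)
    cat = e3.layers["paths.concat"]
    outs = [net._acts[p] for p in cat.predecessors]
    for o in outs[1:]:
        np.testing.assert_array_equal(outs[0], o)


def test_reinit_makes_paths_differ(micro_graph, rng):
    g = micro_graph
    e2 = expand_paths(g, ExpandSpec(E=2, shared_stem=True))
    params = init_params(g, seed=3, zero_classifier=False)
    p2 = expand_params(g, params, e2, E=2, reinit=True, reinit_seed=9)
    net = Network(e2, params=p2)
    x = rng.normal(size=(2, 3, 32, 32))
    net.forward(x, train=True)
    cat = e2.layers["paths.concat"]
    a, b = (net._acts[p] for p in cat.predecessors)
    assert not np.allclose(a, b)


def test_param_monotonicity_in_n_and_e():
    base = build_omnet(small_omnet_config())
    grid = {(n, e): count_params(apply_lmp_pm(base, N=n, E=e))
            for n in (1, 2, 4, 8) for e in (1, 2, 3)}
    for e in (1, 2, 3):
        seq = [grid[(n, e)] for n in (1, 2, 4, 8)]
        assert seq == sorted(seq, reverse=True)
    for n in (1, 2, 4, 8):
        seq = [grid[(n, e)] for e in (1, 2, 3)]
        assert seq == sorted(seq) and len(set(seq)) == 3


def test_affine_in_e_constant_increment():
    """With one shared head, each added path costs the same parameter count."""
    base = build_omnet(small_omnet_config())
    for n in (2, 4):
        counts = [count_params(apply_lmp_pm(base, N=n, E=e))
                  for e in (2, 3, 4, 5)]
        diffs = np.diff(counts)
        assert len(set(diffs.tolist())) == 1


def test_pipeline_order_prune_then_convert_then_expand():
    g = build_resnet101(10)
    manual = expand_paths(
        to_depthwise_separable(prune_channels(g, PruneSpec(4))),
        ExpandSpec(E=2))
    auto = apply_lmp_pm(g, N=4, E=2)
    assert count_params(manual) == count_params(auto)


def test_transform_report_cross_checks_against_oracle(micro_graph):
    out, rep = apply_lmp_pm(micro_graph, N=2, E=2, return_report=True)
    assert rep.params_after == count_params(out)
    assert rep.params_after == param_element_count(init_params(out, 0))
    assert rep.paths == 2
    assert rep.converted          # some k>1 convs were rewritten
    assert rep.channel_changes    # some channels were pruned
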