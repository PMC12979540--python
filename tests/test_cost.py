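import numpy as np
import pytest

from lmppm.architectures import build_omnet, small_omnet_config
from lmppm.cost import (cost_report, count_macs, count_params, format_millions,
                        layer_params, reduction_ratios, weight_histogram)
from lmppm.graph import LayerDescriptor, LayerGraph
from lmppm.nn import Network, init_params, param_element_count
from lmppm.transform import apply_lmp_pm


def _conv_chain(widths, input_size=8, kernel=3):
    layers = [LayerDescriptor(id="in", kind="input", out_channels=3)]
    prev, cin = "in", 3
    for i, w in enumerate(widths):
        layers.append(LayerDescriptor(
            id=f"c{i}", kind="conv", in_channels=cin, out_channels=w,
            kernel=kernel, padding=kernel // 2, predecessors=[prev]))
        prev, cin = f"c{i}", w
    layers += [
        LayerDescriptor(id="gap", kind="globalavgpool", in_channels=cin,
                        out_channels=cin, predecessors=[prev]),
        LayerDescriptor(id="fl", kind="flatten", in_channels=cin,
                        out_channels=cin, predecessors=["gap"]),
        LayerDescriptor(id="fc", kind="dense", in_channels=cin,
                        out_channels=2, bias=True, predecessors=["fl"]),
    ]
    return LayerGraph.from_layers(layers, input_size=input_size,
                                  num_classes=2, classifier="fc")


def test_dense_parameter_formula():
    d = LayerDescriptor(id="fc", kind="dense", in_channels=512,
                        out_channels=61, bias=True, predecessors=["x"])
    assert layer_params(d) == 512 * 61 + 61 == 31293


def test_1x1_conv_macs_formula():
    layers = [
        LayerDescriptor(id="in", kind="input", out_channels=8),
        LayerDescriptor(id="c", kind="conv", in_channels=8, out_channels=8,
                        kernel=1, predecessors=["in"]),
        LayerDescriptor(id="gap", kind="globalavgpool", in_channels=8,
                        out_channels=8, predecessors=["c"]),
        LayerDescriptor(id="fl", kind="flatten", in_channels=8,
                        out_channels=8, predecessors=["gap"]),
        LayerDescriptor(id="fc", kind="dense", in_channels=8, out_channels=2,
                        bias=True, predecessors=["fl"]),
    ]
    g = LayerGraph.from_layers(layers, input_size=4, num_classes=2,
                               classifier="fc")
    # 1*8*8 weights on a 4x4 output map = 1,024 MACs, plus the 16-MAC dense
    assert count_macs(g) == 1024 + 16


def test_macs_equal_weight_count_times_output_area_for_1x1():
    g = _conv_chain([8], kernel=1)
    rep = cost_report(g)
    conv = dict((i, (p, m)) for i, p, m in rep.per_layer)["c0"]
    assert conv[1] == conv[0] * 8 * 8


def test_report_totals_equal_per_layer_sums(micro_graph):
    rep = cost_report(micro_graph)
    assert rep.param_count == sum(p for _, p, _ in rep.per_layer)
    assert rep.mac_count == sum(m for _, _, m in rep.per_layer)


def test_reduction_ratios_identity_and_example():
    g = build_omnet(small_omnet_config())
    base = cost_report(g)
    assert reduction_ratios(base, base) == (100.0, 100.0)
    variant = cost_report(apply_lmp_pm(g, N=4, E=2))
    pr, mr = reduction_ratios(base, variant)
    assert 0 < pr < 100 and 0 < mr < 100


def test_format_millions_half_up():
    assert format_millions(42_625_149) == 42.63
    assert format_millions(405_000) == 0.41       # half-up at the boundary
    assert format_millions(110_640) == 0.11


def test_width_halving_scales_conv_params_by_quarter():
    big = _conv_chain([16, 32, 64])
    small = _conv_chain([8, 16, 32])
    for i in (1, 2):   # layers with internal in-channels; c0 has fixed cin=3
        pb = layer_params(big.layers[f"c{i}"])
        ps = layer_params(small.layers[f"c{i}"])
        assert pb == 4 * ps


@pytest.mark.parametrize("n,e", [(1, 1), (2, 1), (2, 2), (4, 3)])
def test_param_count_matches_brute_force_oracle(n, e):
    g = apply_lmp_pm(build_omnet(small_omnet_config()), N=n, E=e)
    assert count_params(g) == param_element_count(init_params(g, 0))


def test_histogram_conserves_element_counts(micro_graph):
    net = Network(micro_graph, seed=0)
    for lid in ("stem.conv1", "head.fc", "s3.se.dense"):
        h = weight_histogram(net.params, lid, bins=17)
        assert h.frequencies.sum() == net.params[lid]["w"].size


def test_histogram_all_zero_weights_single_bin():
    params = {"fc": {"w": np.zeros((10, 10))}}
    h = weight_histogram(params, "fc", bins=10)
    assert (h.frequencies > 0).sum() == 1
    assert h.frequencies.sum() == 100
    assert h.sparsity == 1.0


def test_final_dense_outweighs_first_conv_in_omnet_family():
    for n in (1, 4):
        g = apply_lmp_pm(build_omnet(small_omnet_config()), N=n, E=1)
        rep = dict((i, p) for i, p, _ in cost_report(g).per_layer)
        first_conv = next(p for i, p in rep.items()
                          if g.layers[i].kind == "conv")
        assert rep[g.classifier] > first_conv


def test_histogram_missing_layer_raises():
    with pytest.raises(KeyError):
        weight_histogram({}, "nope")
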