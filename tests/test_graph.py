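import pytest

from lmppm.graph import GraphError, LayerDescriptor, LayerGraph


def _chain(*descs):
    return LayerGraph.from_layers(list(descs), input_size=8, num_classes=2,
                                  classifier=descs[-1].id)


def test_shapes_propagate_through_conv_pool_dense():
    g = _chain(
        LayerDescriptor(id="in", kind="input", out_channels=3),
        LayerDescriptor(id="c", kind="conv", in_channels=3, out_channels=4,
                        kernel=3, stride=2, padding=1, predecessors=["in"]),
        LayerDescriptor(id="gap", kind="globalavgpool", in_channels=4,
                        out_channels=4, predecessors=["c"]),
        LayerDescriptor(id="fl", kind="flatten", in_channels=4,
                        out_channels=4, predecessors=["gap"]),
        LayerDescriptor(id="fc", kind="dense", in_channels=4, out_channels=2,
                        bias=True, predecessors=["fl"]),
    )
    s = g.shapes()
    assert s["c"] == (4, 4, 4)
    assert s["gap"] == (4, 1, 1)
    assert s["fc"] == (2, 1, 1)


def test_out_of_order_predecessor_rejected():
    with pytest.raises(GraphError, match="out of order"):
        _chain(
            LayerDescriptor(id="in", kind="input", out_channels=3),
            LayerDescriptor(id="a", kind="relu", in_channels=3,
                            out_channels=3, predecessors=["b"]),
            LayerDescriptor(id="b", kind="relu", in_channels=3,
                            out_channels=3, predecessors=["in"]),
        ).validate()


def test_add_junction_width_mismatch_rejected():
    g = _chain(
        LayerDescriptor(id="in", kind="input", out_channels=3),
        LayerDescriptor(id="c1", kind="conv", in_channels=3, out_channels=4,
                        predecessors=["in"]),
        LayerDescriptor(id="c2", kind="conv", in_channels=3, out_channels=5,
                        predecessors=["in"]),
        LayerDescriptor(id="add", kind="add", in_channels=4, out_channels=4,
                        predecessors=["c1", "c2"]),
    )
    with pytest.raises(GraphError, match="mismatch"):
        g.shapes()


def test_concat_sums_channels_and_checks_spatial():
    g = _chain(
        LayerDescriptor(id="in", kind="input", out_channels=3),
        LayerDescriptor(id="c1", kind="conv", in_channels=3, out_channels=4,
                        predecessors=["in"]),
        LayerDescriptor(id="c2", kind="conv", in_channels=3, out_channels=5,
                        predecessors=["in"]),
        LayerDescriptor(id="cat", kind="concat", in_channels=9,
                        out_channels=9, predecessors=["c1", "c2"]),
    )
    assert g.shapes()["cat"] == (9, 8, 8)


def test_repropagate_updates_downstream_widths(micro_graph):
    g = micro_graph.copy()
    # narrow the stage-4 conv and repropagate: its batchnorm, the SE dense
    # (channel-tied) and the head conv input must all follow
    g.layers["s4.conv"].out_channels = 4
    g.repropagate()
    g.validate()
    assert g.layers["s4.bn"].out_channels == 4
    assert g.layers["s4.se.dense"].in_channels == 4
    assert g.layers["s4.se.dense"].out_channels == 4
    assert g.layers["head.conv"].in_channels == 4
    assert g.shapes()[g.exit][0] == g.num_classes


def test_depthwise_groups_follow_repropagation():
    g = _chain(
        LayerDescriptor(id="in", kind="input", out_channels=3),
        LayerDescriptor(id="c", kind="conv", in_channels=3, out_channels=6,
                        kernel=3, padding=1, predecessors=["in"]),
        LayerDescriptor(id="dw", kind="conv", in_channels=6, out_channels=6,
                        kernel=3, padding=1, groups=6, predecessors=["c"]),
        LayerDescriptor(id="fl", kind="flatten", in_channels=6,
                        out_channels=6 * 64, predecessors=["dw"]),
        LayerDescriptor(id="fc", kind="dense", in_channels=6 * 64,
                        out_channels=2, bias=True, predecessors=["fl"]),
    )
    g.layers["c"].out_channels = 4
    g.repropagate()
    assert g.layers["dw"].groups == 4
    assert g.layers["dw"].out_channels == 4
    assert g.layers["fc"].in_channels == 4 * 64
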