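"""Layer graphs: the intermediate representation every transform operates on.

A :class:`LayerGraph` is an ordered, acyclic collection of
:class:`LayerDescriptor` nodes.  It carries enough information to

* propagate feature-map shapes from the input image to the logits,
* count parameters and multiply-accumulate operations exactly,
* be rewritten structurally (channel pruning, depthwise-separable
  conversion, multi-path expansion), and
* be instantiated as a runnable numpy network (:mod:`lmppm.nn`).

Descriptors are deliberately close to the constructor arguments of the
corresponding layers in mainstream deep-learning frameworks so that a graph
can be read off an existing model definition line by line.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field, asdict

KINDS = frozenset({
    "input", "conv", "batchnorm", "dense", "relu", "sigmoid",
    "maxpool", "globalavgpool", "adaptivepool", "flatten",
    "add", "concat", "mul", "output",
})

#: layer kinds that carry learnable weights
PARAMETRIC_KINDS = frozenset({"conv", "batchnorm", "dense"})


class GraphError(ValueError):
    """Raised when a graph violates a structural or shape invariant."""


@dataclass
class LayerDescriptor:
    """One layer of a network.

    ``kernel``/``stride``/``padding`` are only meaningful for convolutions and
    pooling layers (for ``adaptivepool`` the ``kernel`` field holds the target
    output side).  ``groups == in_channels`` marks a depthwise convolution.
    ``tie == "preserve"`` marks a layer whose output width must follow its
    input width when the graph is rewritten (e.g. the single dense layer of an
    SE block, which gates exactly as many channels as it reads).
    """

    id: str
    kind: str
    in_channels: int = 0
    out_channels: int = 0
    kernel: int = 1
    stride: int = 1
    padding: int = 0
    groups: int = 1
    bias: bool = False
    predecessors: list[str] = field(default_factory=list)
    tie: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise GraphError(f"layer {self.id!r}: unknown kind {self.kind!r}")
        if self.kind == "conv":
            if self.in_channels % self.groups:
                raise GraphError(
                    f"conv {self.id!r}: in_channels {self.in_channels} not divisible "
                    f"by groups {self.groups}")

    @property
    def is_depthwise(self) -> bool:
        return self.kind == "conv" and self.groups > 1 and self.groups == self.in_channels

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class LayerGraph:
    """Ordered DAG of layers with an entry (input) and exit (logits) node.

    ``layers`` must be in a topological order: every predecessor appears
    before its consumers.  ``classifier`` names the single dense layer whose
    output width is the class count; it is the one layer no transform may
    re-width.  ``stem_ids`` and ``head_start`` delimit the segments used by
    multi-path expansion: layers up to and including ``stem_ids`` may be
    shared across paths, and layers from ``head_start`` on form the head that
    is rebuilt over the concatenated features.
    """

    layers: dict[str, LayerDescriptor]
    entry: str
    exit: str
    input_size: int = 224
    num_classes: int = 2
    classifier: str | None = None
    stem_ids: list[str] = field(default_factory=list)
    head_start: str | None = None
    name: str = "graph"

    # ------------------------------------------------------------------ build
    @classmethod
    def from_layers(cls, layers: list[LayerDescriptor], **kw) -> "LayerGraph":
        entry = layers[0].id
        exit_ = layers[-1].id
        d = {l.id: l for l in layers}
        if len(d) != len(layers):
            raise GraphError("duplicate layer ids")
        return cls(layers=d, entry=entry, exit=exit_, **kw)

    def copy(self) -> "LayerGraph":
        return _copy.deepcopy(self)

    def order(self) -> list[LayerDescriptor]:
        return list(self.layers.values())

    def successors(self) -> dict[str, list[str]]:
        succ: dict[str, list[str]] = {lid: [] for lid in self.layers}
        for l in self.layers.values():
            for p in l.predecessors:
                succ[p].append(l.id)
        return succ

    # --------------------------------------------------------------- validate
    def validate(self) -> None:
        """Check ordering, connectivity and shape consistency."""
        seen: set[str] = set()
        for l in self.layers.values():
            if l.kind == "input":
                if l.id != self.entry:
                    raise GraphError("input layer must be the entry")
            elif not l.predecessors:
                raise GraphError(f"layer {l.id!r} has no predecessors")
            for p in l.predecessors:
                if p not in seen:
                    raise GraphError(
                        f"layer {l.id!r}: predecessor {p!r} missing or out of order "
                        "(graph must be topologically ordered and acyclic)")
            seen.add(l.id)
        if self.exit not in self.layers:
            raise GraphError("exit layer missing")
        if self.classifier is not None:
            c = self.layers[self.classifier]
            if c.kind != "dense":
                raise GraphError("classifier must be a dense layer")
            if c.out_channels != self.num_classes:
                raise GraphError(
                    f"classifier width {c.out_channels} != num_classes {self.num_classes}")
        self.shapes()  # raises on inconsistency

    # ----------------------------------------------------------------- shapes
    def shapes(self, input_size: int | None = None) -> dict[str, tuple[int, int, int]]:
        """Propagate (channels, height, width) from the entry to every layer."""
        size = input_size or self.input_size
        out: dict[str, tuple[int, int, int]] = {}
        for l in self.layers.values():
            if l.kind == "input":
                out[l.id] = (l.out_channels or 3, size, size)
                continue
            preds = [out[p] for p in l.predecessors]
            c, h, w = preds[0]
            if l.kind == "conv":
                if c != l.in_channels:
                    raise GraphError(
                        f"conv {l.id!r}: in_channels {l.in_channels} but predecessor "
                        f"provides {c}")
                h = (h + 2 * l.padding - l.kernel) // l.stride + 1
                w = (w + 2 * l.padding - l.kernel) // l.stride + 1
                if h < 1 or w < 1:
                    raise GraphError(f"conv {l.id!r}: output spatial size < 1")
                out[l.id] = (l.out_channels, h, w)
            elif l.kind == "maxpool":
                h = (h + 2 * l.padding - l.kernel) // l.stride + 1
                w = (w + 2 * l.padding - l.kernel) // l.stride + 1
                out[l.id] = (c, h, w)
            elif l.kind == "globalavgpool":
                out[l.id] = (c, 1, 1)
            elif l.kind == "adaptivepool":
                out[l.id] = (c, l.kernel, l.kernel)
            elif l.kind == "flatten":
                out[l.id] = (c * h * w, 1, 1)
            elif l.kind == "dense":
                if c != l.in_channels:
                    raise GraphError(
                        f"dense {l.id!r}: in_features {l.in_channels} but predecessor "
                        f"provides {c}")
                out[l.id] = (l.out_channels, 1, 1)
            elif l.kind in ("batchnorm", "relu", "sigmoid", "output"):
                out[l.id] = (c, h, w)
            elif l.kind == "add":
                for q in preds[1:]:
                    if q != preds[0]:
                        raise GraphError(
                            f"add {l.id!r}: mismatched branch shapes {preds}")
                out[l.id] = preds[0]
            elif l.kind == "concat":
                for q in preds[1:]:
                    if q[1:] != preds[0][1:]:
                        raise GraphError(
                            f"concat {l.id!r}: mismatched spatial shapes {preds}")
                out[l.id] = (sum(p[0] for p in preds), h, w)
            elif l.kind == "mul":
                feat, gate = preds[0], preds[1]
                if gate[0] != feat[0]:
                    raise GraphError(
                        f"mul {l.id!r}: gate width {gate[0]} != feature width {feat[0]}")
                out[l.id] = feat
            else:  # pragma: no cover
                raise GraphError(f"unhandled kind {l.kind!r}")
        return out

    # ------------------------------------------------------------ repropagate
    def repropagate(self) -> None:
        """Recompute every layer's widths from its predecessors.

        Called after surgery that changes ``out_channels`` of some layers
        (pruning) so that consumers, batchnorm widths, dense in-features and
        junction widths stay consistent.  The classifier's output width and
        any explicitly set conv output widths are left alone; channel-tied
        layers (``tie == "preserve"``) and depthwise convolutions follow their
        input width.
        """
        width: dict[str, int] = {}
        spatial: dict[str, tuple[int, int]] = {}
        size = self.input_size
        for l in self.layers.values():
            if l.kind == "input":
                width[l.id] = l.out_channels or 3
                spatial[l.id] = (size, size)
                continue
            c = width[l.predecessors[0]]
            h, w = spatial[l.predecessors[0]]
            if l.kind == "conv":
                was_dw = l.is_depthwise
                l.in_channels = c
                if was_dw:
                    l.groups = c
                    l.out_channels = c
                elif l.in_channels % l.groups:
                    raise GraphError(
                        f"conv {l.id!r}: repropagated in_channels {c} not divisible "
                        f"by groups {l.groups}")
                h = (h + 2 * l.padding - l.kernel) // l.stride + 1
                w = (w + 2 * l.padding - l.kernel) // l.stride + 1
                width[l.id], spatial[l.id] = l.out_channels, (h, w)
            elif l.kind == "batchnorm":
                l.in_channels = l.out_channels = c
                width[l.id], spatial[l.id] = c, (h, w)
            elif l.kind == "dense":
                l.in_channels = c
                if l.id != self.classifier and l.tie == "preserve":
                    l.out_channels = c
                width[l.id], spatial[l.id] = l.out_channels, (1, 1)
            elif l.kind == "maxpool":
                h = (h + 2 * l.padding - l.kernel) // l.stride + 1
                w = (w + 2 * l.padding - l.kernel) // l.stride + 1
                width[l.id], spatial[l.id] = c, (h, w)
            elif l.kind == "globalavgpool":
                width[l.id], spatial[l.id] = c, (1, 1)
            elif l.kind == "adaptivepool":
                width[l.id], spatial[l.id] = c, (l.kernel, l.kernel)
            elif l.kind == "flatten":
                width[l.id], spatial[l.id] = c * h * w, (1, 1)
            elif l.kind == "add":
                ws = {width[p] for p in l.predecessors}
                if len(ws) != 1:
                    raise GraphError(
                        f"add {l.id!r}: branch widths diverged to {sorted(ws)} after "
                        "rewriting (unsupported topology)")
                width[l.id], spatial[l.id] = c, (h, w)
            elif l.kind == "concat":
                width[l.id] = sum(width[p] for p in l.predecessors)
                spatial[l.id] = (h, w)
                l.in_channels = l.out_channels = width[l.id]
            elif l.kind == "mul":
                if width[l.predecessors[1]] != c:
                    raise GraphError(f"mul {l.id!r}: gate width diverged")
                width[l.id], spatial[l.id] = c, (h, w)
            else:  # relu, sigmoid, output
                width[l.id], spatial[l.id] = c, (h, w)
            if l.kind in ("relu", "sigmoid", "output", "mul", "add",
                          "maxpool", "globalavgpool", "adaptivepool", "flatten"):
                l.in_channels = c
                l.out_channels = width[l.id]

    # ------------------------------------------------------------------- misc
    def to_records(self) -> list[dict]:
        """One dict per layer, suitable for a CSV/JSON dump."""
        return [l.to_dict() for l in self.layers.values()]

    def __len__(self) -> int:
        return len(self.layers)
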