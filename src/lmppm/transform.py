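"""The LMP-PM engine: three composable structural rewrites of a LayerGraph.

1. :func:`prune_channels` — global channel pruning by an integer divisor N:
   every standard convolution whose output width C satisfies the guard
   C/N > 1 is re-widthed to floor(C/N), and all downstream widths
   (consumer in-channels, batchnorm widths, dense in-features, junctions)
   are repropagated.  The classifier output is never changed.
2. :func:`to_depthwise_separable` — every standard convolution with kernel
   k > 1 is replaced by a depthwise k x k convolution followed by a 1x1
   pointwise convolution.  This is an architecture rewrite, not a weight
   factorisation: the new layers are fresh.
3. :func:`expand_paths` — the feature extractor (everything between the
   optional shared stem and the head) is replicated into E parallel paths
   whose outputs are concatenated on the channel axis; a single head is
   rebuilt on the E-fold width.  Path 1 keeps the original weights, paths
   2..E are freshly initialised.

:func:`apply_lmp_pm` composes them in the order prune -> convert -> expand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .graph import LayerDescriptor, LayerGraph, GraphError
from .cost import count_params, layer_params

log = logging.getLogger(__name__)

__all__ = ["PruneSpec", "ExpandSpec", "TransformReport", "prune_channels",
           "to_depthwise_separable", "expand_paths", "apply_lmp_pm"]


@dataclass
class PruneSpec:
    """Pruning divisor N >= 1; N = 1 leaves all widths unchanged."""

    N: int = 1

    def __post_init__(self) -> None:
        if self.N < 1:
            raise GraphError("pruning divisor N must be >= 1")


@dataclass
class ExpandSpec:
    """Path count E >= 1; E = 1 is a no-op."""

    E: int = 1
    shared_stem: bool = False
    reinit_seed: int = 0

    def __post_init__(self) -> None:
        if self.E < 1:
            raise GraphError("path count E must be >= 1")


@dataclass
class TransformReport:
    """Audit trail of one transform pipeline run."""

    params_before: int = 0
    params_after: int = 0
    channel_changes: dict[str, tuple[int, int]] = field(default_factory=dict)
    converted: list[str] = field(default_factory=list)
    paths: int = 1
    degenerate: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "params_before": self.params_before,
            "params_after": self.params_after,
            "paths": self.paths,
            "channel_changes": {
                k: {"before": b, "after": a}
                for k, (b, a) in self.channel_changes.items()},
            "converted": list(self.converted),
            "degenerate": list(self.degenerate),
        }


# --------------------------------------------------------------------------
# 1. channel pruning
# --------------------------------------------------------------------------

def prune_channels(g: LayerGraph, spec: PruneSpec,
                   report: TransformReport | None = None) -> LayerGraph:
    """Divide every standard convolution's output width by N (guarded)."""
    out = g.copy()
    if spec.N == 1:
        return out
    for l in out.layers.values():
        if l.kind != "conv" or l.groups != 1:
            continue
        C = l.out_channels
        if C / spec.N > 1.0:
            l.out_channels = C // spec.N
            if report is not None:
                report.channel_changes[l.id] = (C, l.out_channels)
            if l.out_channels == 1 and report is not None:
                report.degenerate.append(l.id)
            log.info("pruned %s: %d -> %d channels", l.id, C, l.out_channels)
        else:
            log.info("guard kept %s at %d channels (C/N = %.3f <= 1)",
                     l.id, C, C / spec.N)
    out.repropagate()
    out.validate()
    return out


# --------------------------------------------------------------------------
# 2. depthwise-separable conversion
# --------------------------------------------------------------------------

def to_depthwise_separable(g: LayerGraph,
                           report: TransformReport | None = None,
                           dw_bias: bool = False,
                           skip_stem: bool = False) -> LayerGraph:
    """Replace every standard k>1 convolution with depthwise + pointwise.

    The depthwise stage keeps the original kernel, stride and padding and is
    bias-free by default (``dw_bias=True`` gives it a bias, the
    framework-default construction); the pointwise stage is a 1x1 stride-1
    convolution inheriting the original bias flag.  1x1 convolutions are left
    unchanged (converting them would add parameters); grouped convolutions
    with 1 < groups < in_channels are rejected as unsupported.
    ``skip_stem`` leaves the stem convolutions alone, for families whose
    compression targets only the main feature-extraction structure.
    """
    out = g.copy()
    skipped = set(out.stem_ids) if skip_stem else set()
    new_layers: dict[str, LayerDescriptor] = {}
    renamed: dict[str, str] = {}
    for l in out.layers.values():
        l.predecessors = [renamed.get(p, p) for p in l.predecessors]
        if l.kind == "conv" and 1 < l.groups < l.in_channels:
            raise GraphError(
                f"conv {l.id!r}: grouped convolutions with 1 < groups < C_in "
                "are not supported by the conversion")
        if l.kind != "conv" or l.kernel <= 1 or l.groups != 1 \
                or l.id in skipped:
            new_layers[l.id] = l
            continue
        dw = LayerDescriptor(
            id=f"{l.id}.dw", kind="conv", in_channels=l.in_channels,
            out_channels=l.in_channels, kernel=l.kernel, stride=l.stride,
            padding=l.padding, groups=l.in_channels, bias=dw_bias,
            predecessors=l.predecessors)
        pw = LayerDescriptor(
            id=f"{l.id}.pw", kind="conv", in_channels=l.in_channels,
            out_channels=l.out_channels, kernel=1, stride=1, padding=0,
            groups=1, bias=l.bias, predecessors=[dw.id])
        new_layers[dw.id] = dw
        new_layers[pw.id] = pw
        renamed[l.id] = pw.id
        if report is not None:
            report.converted.append(l.id)
        log.info("converted %s (k=%d, %d->%d) to depthwise+pointwise",
                 l.id, l.kernel, l.in_channels, l.out_channels)
    out.layers = new_layers
    for attr in ("entry", "exit", "classifier", "head_start"):
        v = getattr(out, attr)
        if v in renamed:
            setattr(out, attr, renamed[v])
    stem_ids: list[str] = []
    for i in out.stem_ids:
        if i in renamed:  # converted stem conv contributes both halves
            stem_ids += [f"{i}.dw", f"{i}.pw"]
        else:
            stem_ids.append(i)
    out.stem_ids = stem_ids
    out.validate()
    return out


# --------------------------------------------------------------------------
# 3. multi-path expansion
# --------------------------------------------------------------------------

def _segments(g: LayerGraph, shared_stem: bool):
    """Split the graph into (pre, feature, head) id lists."""
    ids = list(g.layers)
    head_start = g.head_start
    if head_start is None:
        if g.classifier is None:
            raise GraphError("expansion needs head_start or classifier metadata")
        head_start = g.classifier
    hs = ids.index(head_start)
    pre = [g.entry]
    if shared_stem:
        if not g.stem_ids:
            raise GraphError("shared_stem requested but the graph has no stem_ids")
        pre = [g.entry] + list(g.stem_ids)
    feature = [i for i in ids[:hs] if i not in pre]
    head = ids[hs:]
    if not feature:
        raise GraphError("empty feature segment; nothing to expand")
    return pre, feature, head


def expand_paths(g: LayerGraph, spec: ExpandSpec,
                 report: TransformReport | None = None) -> LayerGraph:
    """Replicate the feature extractor into E parallel concatenated paths."""
    if spec.E == 1:
        return g.copy()
    pre, feature, head = _segments(g, spec.shared_stem)
    featset = set(feature)
    join = g.layers[head[0]].predecessors[0]  # single tail feeding the head
    out_layers: dict[str, LayerDescriptor] = {
        i: g.layers[i] for i in pre}
    tails: list[str] = []
    for e in range(1, spec.E + 1):
        suffix = f".p{e}"
        for i in feature:
            l = g.layers[i]
            nl = LayerDescriptor(**{**l.to_dict(),
                                    "id": i + suffix,
                                    "predecessors": [
                                        p + suffix if p in featset else p
                                        for p in l.predecessors]})
            out_layers[nl.id] = nl
        tails.append(join + suffix)
    concat_width = sum(g.layers[join].out_channels for _ in tails)
    cat = LayerDescriptor(id="paths.concat", kind="concat",
                          in_channels=concat_width, out_channels=concat_width,
                          predecessors=tails)
    out_layers[cat.id] = cat
    prev = cat.id
    for i in head:
        l = g.layers[i].to_dict()
        l["predecessors"] = [prev if p == join or p in featset else p
                             for p in g.layers[i].predecessors]
        nl = LayerDescriptor(**l)
        out_layers[nl.id] = nl
        prev = nl.id
    out = LayerGraph(layers=out_layers, entry=g.entry, exit=g.exit,
                     input_size=g.input_size, num_classes=g.num_classes,
                     classifier=g.classifier, stem_ids=list(g.stem_ids),
                     head_start=head[0], name=f"{g.name}.E{spec.E}")
    out.repropagate()
    out.validate()
    if report is not None:
        report.paths = spec.E
    log.info("expanded into %d paths (%s stem), head rebuilt on %d channels",
             spec.E, "shared" if spec.shared_stem else "replicated",
             concat_width)
    return out


# --------------------------------------------------------------------------
# pipeline
# --------------------------------------------------------------------------

def apply_lmp_pm(g: LayerGraph, N: int = 1, E: int = 1, *,
                 depthwise: bool = True, shared_stem: bool = False,
                 dw_bias: bool = False, skip_stem: bool = False,
                 reinit_seed: int = 0,
                 return_report: bool = False):
    """Prune -> depthwise-convert -> expand, the full compression pipeline.

    ``depthwise`` is explicit because the untransformed baseline and the
    merely-converted model both correspond to N = 1, E = 1.
    """
    report = TransformReport(params_before=count_params(g))
    out = prune_channels(g, PruneSpec(N=N), report)
    if depthwise:
        out = to_depthwise_separable(out, report, dw_bias=dw_bias,
                                     skip_stem=skip_stem)
    out = expand_paths(out, ExpandSpec(E=E, shared_stem=shared_stem,
                                       reinit_seed=reinit_seed), report)
    out.name = f"{g.name}.N{N}.E{E}"
    report.params_after = count_params(out)
    if return_report:
        return out, report
    return out
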