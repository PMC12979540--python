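"""Exact parameter and multiply-accumulate accounting for layer graphs.

Conventions (the ones under which the published cost tables reproduce):

* conv parameters: ``k^2 * (C_in / groups) * C_out`` plus ``C_out`` if biased;
* batchnorm: ``2 * C`` (the affine scale and shift);
* dense: ``in * out`` plus ``out`` if biased;
* conv MACs: parameters-of-the-weight-tensor times output spatial positions,
  ``k^2 * (C_in / groups) * C_out * H_out * W_out``;
* dense MACs: ``in * out``;
* activations, pooling, batchnorm and junctions contribute zero MACs
  (switchable via ``include_norm_macs`` for other profiler conventions);
* batch size 1 at a stated input resolution.

All counts are exact integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import LayerDescriptor, LayerGraph

__all__ = ["CostReport", "WeightHistogram", "layer_params", "count_params",
           "count_macs", "cost_report", "reduction_ratios", "format_millions",
           "weight_histogram"]


@dataclass
class CostReport:
    """Exact integer cost of a graph at a stated input resolution."""

    param_count: int
    mac_count: int
    input_size: int
    class_count: int
    per_layer: list[tuple[str, int, int]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "param_count": self.param_count,
            "mac_count": self.mac_count,
            "input_size": self.input_size,
            "class_count": self.class_count,
            "per_layer": [
                {"id": i, "params": p, "macs": m} for i, p, m in self.per_layer],
        }


@dataclass
class WeightHistogram:
    layer_id: str
    bin_edges: np.ndarray
    frequencies: np.ndarray
    minimum: float
    maximum: float
    sparsity: float

    def to_dict(self) -> dict:
        return {
            "layer_id": self.layer_id,
            "bin_edges": self.bin_edges.tolist(),
            "frequencies": self.frequencies.tolist(),
            "min": self.minimum, "max": self.maximum,
            "sparsity": self.sparsity,
        }


def layer_params(l: LayerDescriptor) -> int:
    """Learnable parameter count of a single layer."""
    if l.kind == "conv":
        n = l.kernel * l.kernel * (l.in_channels // l.groups) * l.out_channels
        return n + (l.out_channels if l.bias else 0)
    if l.kind == "batchnorm":
        return 2 * l.out_channels
    if l.kind == "dense":
        return l.in_channels * l.out_channels + (l.out_channels if l.bias else 0)
    return 0


def count_params(g: LayerGraph) -> int:
    """Exact total parameter count of a graph."""
    return sum(layer_params(l) for l in g.layers.values())


def count_macs(g: LayerGraph, input_size: int | None = None,
               include_norm_macs: bool = False) -> int:
    """Exact multiply-accumulate count at batch 1 and the given resolution."""
    shapes = g.shapes(input_size)
    total = 0
    for l in g.layers.values():
        total += _layer_macs(l, shapes, include_norm_macs)
    return total


def _layer_macs(l: LayerDescriptor, shapes: dict, include_norm: bool) -> int:
    c, h, w = shapes[l.id]
    if l.kind == "conv":
        return l.kernel * l.kernel * (l.in_channels // l.groups) * l.out_channels * h * w
    if l.kind == "dense":
        return l.in_channels * l.out_channels
    if include_norm and l.kind in ("batchnorm", "relu", "sigmoid", "mul"):
        return c * h * w
    return 0


def cost_report(g: LayerGraph, input_size: int | None = None,
                include_norm_macs: bool = False) -> CostReport:
    shapes = g.shapes(input_size)
    per_layer = [
        (l.id, layer_params(l), _layer_macs(l, shapes, include_norm_macs))
        for l in g.layers.values()]
    return CostReport(
        param_count=sum(p for _, p, _ in per_layer),
        mac_count=sum(m for _, _, m in per_layer),
        input_size=input_size or g.input_size,
        class_count=g.num_classes,
        per_layer=per_layer)


def reduction_ratios(base: CostReport, variant: CostReport) -> tuple[float, float]:
    """Percentage of the base cost retained by the variant, two decimals."""
    if base.param_count <= 0 or base.mac_count <= 0:
        raise ValueError("base report must have positive counts")
    return (round(100.0 * variant.param_count / base.param_count, 2),
            round(100.0 * variant.mac_count / base.mac_count, 2))


def format_millions(count: int) -> float:
    """Half-up rounding of a count to two decimals in millions (42.63 style)."""
    import decimal
    return float(decimal.Decimal(count).scaleb(-6).quantize(
        decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP))


def weight_histogram(params: dict[str, dict[str, np.ndarray]], layer_id: str,
                     bins: int = 100, zero_tol: float = 1e-8) -> WeightHistogram:
    """Histogram of one layer's weight values (the main weight tensor).

    ``params`` is the parameter dictionary produced by :mod:`lmppm.nn`.
    Frequencies sum to the layer's weight-element count; ``sparsity`` is the
    fraction of elements whose magnitude is below ``zero_tol``.
    """
    if layer_id not in params or "w" not in params[layer_id]:
        raise KeyError(f"no weighted layer {layer_id!r}")
    w = np.asarray(params[layer_id]["w"]).ravel()
    freq, edges = np.histogram(w, bins=bins)
    return WeightHistogram(
        layer_id=layer_id, bin_edges=edges, frequencies=freq,
        minimum=float(w.min()), maximum=float(w.max()),
        sparsity=float(np.mean(np.abs(w) < zero_tol)))
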