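# lmppm

Structural compression of convolutional leaf-disease classifiers: global
channel pruning, depthwise-separable conversion, and multi-path expansion,
with exact parameter/MAC accounting, a synthetic leaf-image generator, and a
desk-scale training harness.

## The problem

High-accuracy CNNs for plant leaf-disease recognition are usually too large
for the field hardware they would be most useful on. A practical route to
small models is structural rewriting of an existing architecture, governed
by two integers:

* **N** — a pruning divisor: every convolution's output width C becomes
  ⌊C/N⌋ when the guard C/N > 1 holds, with all downstream widths
  repropagated. A k×k convolution's parameters scale as ≈1/N².
* **E** — a path count: the slimmed feature extractor is replicated into E
  parallel paths (one keeping the original weights, the rest re-initialised),
  their outputs concatenated, and a single classifier attached to the
  widened features. Parameters are affine in E: each added path costs a
  constant increment.

Between the two sits depthwise-separable conversion, which rewrites each
k×k convolution (k>1) as a depthwise k×k plus a pointwise 1×1 layer,
cutting k²·C_in·C_out weights to k²·C_in + C_in·C_out.

The package represents models as explicit layer graphs
(`lmppm.graph.LayerGraph`), so the three rewrites are composable,
inspectable graph transforms rather than framework-specific surgery, and all
cost accounting is exact integer arithmetic. Built-in architectures: a
four-stage multi-branch classifier family (three-branch parallel blocks,
residual units, single-dense squeeze-and-excitation gates), its compressed
two-path variant, and a canonical 101-layer bottleneck residual classifier.
A numpy runtime (`lmppm.nn`) instantiates and trains any graph.

## Worked example

```python
from lmppm import build_resnet101, apply_lmp_pm, count_params, format_millions

base = build_resnet101(61)                      # 61-class head
print(count_params(base), format_millions(count_params(base)))
# 42625149 42.63

slim = apply_lmp_pm(base, N=4, E=4)             # prune /4, convert, 4 paths
print(count_params(slim), format_millions(count_params(slim)))
# 6157449 6.16
```

The first pair is the exact weight count of the uncompressed 61-class
classifier and its two-decimal rounding in millions; the second shows that
pruning by 4, converting to depthwise-separable form and expanding to four
concatenated paths leaves 6.16 M parameters — about one seventh of the
baseline — while the classifier's 61-way output is untouched.

The same pipeline runs end to end on synthetic data from the shell:

```bash
lmp synth --classes 4 --per-class 50 --size 64 --seed 7 --out data/
lmp train --model small --classes 4 --data data/ --epochs 15 --size 64 \
    --seed 7 --out run/
lmp eval --model small --classes 4 --weights run/best.npz --data data/ \
    --split test --size 64 --json metrics.json
```

`lmp cost`, `lmp describe`, `lmp hist`, `lmp transform` and `lmp grid`
report costs, dump layer graphs, plot weight histograms, rewrite models and
sweep (N, E) grids; see `lmp --help`.

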