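"""A small numpy runtime that instantiates and trains LayerGraphs.

The graphs built by :mod:`lmppm.architectures` are symbolic; this module
gives them weights and a forward/backward pass so that the desk-scale
training and evaluation harness (:mod:`lmppm.train_eval`) can run them.
Convolutions are evaluated via im2col (``sliding_window_view``); gradients
are hand-derived per layer kind; optimisation is AdamW with decoupled weight
decay.

Initialisation: He-normal for convolution and dense weights, zeros for
biases; the classifier dense layer is zero-initialised so that training
starts from uniform class probabilities.  Batchnorm starts at the identity
(gamma 1, beta 0) and keeps running statistics for evaluation mode.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .graph import LayerGraph

__all__ = ["Network", "init_params", "param_element_count", "softmax",
           "cross_entropy"]

_BN_EPS = 1e-5
_BN_MOMENTUM = 0.1


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

def init_params(g: LayerGraph, seed: int = 0,
                zero_classifier: bool = True) -> dict[str, dict[str, np.ndarray]]:
    """Fresh parameter arrays for every weighted layer of ``g``."""
    rng = np.random.default_rng(seed)
    params: dict[str, dict[str, np.ndarray]] = {}
    for l in g.layers.values():
        if l.kind == "conv":
            fan_in = l.kernel * l.kernel * (l.in_channels // l.groups)
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           (l.out_channels, l.in_channels // l.groups,
                            l.kernel, l.kernel))
            p = {"w": w.astype(np.float64)}
            if l.bias:
                p["b"] = np.zeros(l.out_channels)
            params[l.id] = p
        elif l.kind == "dense":
            if zero_classifier and l.id == g.classifier:
                w = np.zeros((l.out_channels, l.in_channels))
            else:
                w = rng.normal(0.0, np.sqrt(2.0 / l.in_channels),
                               (l.out_channels, l.in_channels))
            p = {"w": w}
            if l.bias:
                p["b"] = np.zeros(l.out_channels)
            params[l.id] = p
        elif l.kind == "batchnorm":
            params[l.id] = {"gamma": np.ones(l.out_channels),
                            "beta": np.zeros(l.out_channels)}
    return params


def param_element_count(params: dict[str, dict[str, np.ndarray]]) -> int:
    """Brute-force enumeration of instantiated weight elements.

    Serves as the independent oracle for :func:`lmppm.cost.count_params`.
    """
    return int(sum(int(np.prod(a.shape))
                   for d in params.values() for a in d.values()))


# --------------------------------------------------------------------------
# functional pieces
# --------------------------------------------------------------------------

def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy loss and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.log(p[np.arange(n), y] + 1e-12).mean())
    d = p.copy()
    d[np.arange(n), y] -= 1.0
    return loss, d / n


def _conv_forward(x, w, b, stride, padding, groups):
    B, C, H, W = x.shape
    O, Cg, k, _ = w.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2))
    cols = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    # cols: (B, C, Ho, Wo, k, k)
    if groups == 1:
        out = np.einsum("bchwij,ocij->bohw", cols, w, optimize=True)
    else:
        Bc = cols.reshape(B, groups, C // groups, *cols.shape[2:])
        wg = w.reshape(groups, O // groups, Cg, k, k)
        out = np.einsum("bgchwij,gocij->bgohw", Bc, wg, optimize=True)
        out = out.reshape(B, O, *out.shape[3:])
    if b is not None:
        out = out + b[None, :, None, None]
    return out, (x, cols)


def _conv_backward(dout, cache, w, stride, padding, groups, in_shape):
    xp, cols = cache
    B, C = in_shape[0], in_shape[1]
    O, Cg, k, _ = w.shape
    Ho, Wo = dout.shape[2], dout.shape[3]
    if groups == 1:
        dw = np.einsum("bohw,bchwij->ocij", dout, cols, optimize=True)
        dcols = np.einsum("bohw,ocij->bchwij", dout, w, optimize=True)
    else:
        dg = dout.reshape(B, groups, O // groups, Ho, Wo)
        cg = cols.reshape(B, groups, C // groups, Ho, Wo, k, k)
        wg = w.reshape(groups, O // groups, Cg, k, k)
        dw = np.einsum("bgohw,bgchwij->gocij", dg, cg,
                       optimize=True).reshape(O, Cg, k, k)
        dcols = np.einsum("bgohw,gocij->bgchwij", dg, wg, optimize=True)
        dcols = dcols.reshape(B, C, Ho, Wo, k, k)
    dxp = np.zeros_like(xp)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i:i + stride * Ho:stride,
                j:j + stride * Wo:stride] += dcols[:, :, :, :, i, j]
    if padding:
        dx = dxp[:, :, padding:padding + in_shape[2],
                 padding:padding + in_shape[3]]
    else:
        dx = dxp
    db = dout.sum(axis=(0, 2, 3))
    return dx, dw, db


def _pool_regions(n_in: int, n_out: int) -> list[tuple[int, int]]:
    return [(int(np.floor(i * n_in / n_out)),
             int(np.ceil((i + 1) * n_in / n_out))) for i in range(n_out)]


# --------------------------------------------------------------------------
# the network
# --------------------------------------------------------------------------

class Network:
    """Runnable instantiation of a LayerGraph."""

    def __init__(self, graph: LayerGraph, seed: int = 0,
                 params: dict | None = None):
        graph.validate()
        self.graph = graph
        self.params = params if params is not None else init_params(graph, seed)
        self.state = {l.id: {"mean": np.zeros(l.out_channels),
                             "var": np.ones(l.out_channels)}
                      for l in graph.layers.values() if l.kind == "batchnorm"}
        self._opt: dict | None = None

    # ------------------------------------------------------------ forward
    def forward(self, x: np.ndarray, train: bool = False):
        """Return logits; caches activations when ``train`` for backward."""
        acts: dict[str, np.ndarray] = {}
        caches: dict[str, tuple] = {}
        g = self.graph
        for l in g.layers.values():
            if l.kind == "input":
                acts[l.id] = np.asarray(x, dtype=np.float64)
                continue
            a = acts[l.predecessors[0]]
            p = self.params.get(l.id, {})
            if l.kind == "conv":
                out, cache = _conv_forward(a, p["w"], p.get("b"), l.stride,
                                           l.padding, l.groups)
                caches[l.id] = (a.shape, cache)
            elif l.kind == "dense":
                z = a.reshape(a.shape[0], -1)
                out = z @ p["w"].T
                if "b" in p:
                    out = out + p["b"]
                out = out[:, :, None, None]
                caches[l.id] = (a.shape, z)
            elif l.kind == "batchnorm":
                out, cache = self._bn_forward(l.id, a, train)
                caches[l.id] = cache
            elif l.kind == "relu":
                out = np.maximum(a, 0.0)
                caches[l.id] = (out > 0,)
            elif l.kind == "sigmoid":
                out = 1.0 / (1.0 + np.exp(-a))
                caches[l.id] = (out,)
            elif l.kind == "maxpool":
                out, cache = self._maxpool_forward(a, l)
                caches[l.id] = cache
            elif l.kind == "globalavgpool":
                out = a.mean(axis=(2, 3), keepdims=True)
                caches[l.id] = (a.shape,)
            elif l.kind == "adaptivepool":
                out, cache = self._adaptive_forward(a, l.kernel)
                caches[l.id] = cache
            elif l.kind == "flatten":
                out = a.reshape(a.shape[0], -1, 1, 1)
                caches[l.id] = (a.shape,)
            elif l.kind == "add":
                out = sum(acts[q] for q in l.predecessors)
            elif l.kind == "concat":
                out = np.concatenate([acts[q] for q in l.predecessors], axis=1)
            elif l.kind == "mul":
                feat, gate = acts[l.predecessors[0]], acts[l.predecessors[1]]
                out = feat * gate
            else:  # output
                out = a
            acts[l.id] = out
        logits = acts[g.exit].reshape(x.shape[0], -1)
        if train:
            self._acts, self._caches = acts, caches
        return logits

    def _bn_forward(self, lid, a, train):
        p, st = self.params[lid], self.state[lid]
        axes = (0, 2, 3) if a.ndim == 4 else (0,)
        if train:
            mean = a.mean(axis=axes)
            var = a.var(axis=axes)
            st["mean"] = (1 - _BN_MOMENTUM) * st["mean"] + _BN_MOMENTUM * mean
            st["var"] = (1 - _BN_MOMENTUM) * st["var"] + _BN_MOMENTUM * var
        else:
            mean, var = st["mean"], st["var"]
        shape = (1, -1, 1, 1) if a.ndim == 4 else (1, -1)
        inv = 1.0 / np.sqrt(var + _BN_EPS)
        xhat = (a - mean.reshape(shape)) * inv.reshape(shape)
        out = xhat * p["gamma"].reshape(shape) + p["beta"].reshape(shape)
        return out, (xhat, inv, shape, train)

    @staticmethod
    def _maxpool_forward(a, l):
        k, s, pd = l.kernel, l.stride, l.padding
        ap = np.pad(a, ((0, 0), (0, 0), (pd,) * 2, (pd,) * 2),
                    constant_values=-np.inf) if pd else a
        win = sliding_window_view(ap, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        flat = win.reshape(*win.shape[:4], k * k)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        return out, (a.shape, ap.shape, idx, k, s, pd)

    @staticmethod
    def _adaptive_forward(a, p):
        rh = _pool_regions(a.shape[2], p)
        rw = _pool_regions(a.shape[3], p)
        out = np.empty((a.shape[0], a.shape[1], p, p))
        for i, (h0, h1) in enumerate(rh):
            for j, (w0, w1) in enumerate(rw):
                out[:, :, i, j] = a[:, :, h0:h1, w0:w1].mean(axis=(2, 3))
        return out, (a.shape, rh, rw)

    # ----------------------------------------------------------- backward
    def backward(self, dlogits: np.ndarray) -> dict[str, dict[str, np.ndarray]]:
        """Gradients for every parameter given d(loss)/d(logits)."""
        g = self.graph
        acts, caches = self._acts, self._caches
        grads: dict[str, dict[str, np.ndarray]] = {}
        dacc: dict[str, np.ndarray] = {
            g.exit: dlogits.reshape(acts[g.exit].shape)}
        for l in reversed(list(g.layers.values())):
            if l.kind == "input" or l.id not in dacc:
                continue
            d = dacc.pop(l.id)
            p = self.params.get(l.id, {})

            def send(pid, val):
                if pid in dacc:
                    dacc[pid] = dacc[pid] + val
                else:
                    dacc[pid] = val

            if l.kind == "conv":
                in_shape, cache = caches[l.id]
                dx, dw, db = _conv_backward(d, cache, p["w"], l.stride,
                                            l.padding, l.groups, in_shape)
                grads[l.id] = {"w": dw}
                if "b" in p:
                    grads[l.id]["b"] = db
                send(l.predecessors[0], dx)
            elif l.kind == "dense":
                in_shape, z = caches[l.id]
                d2 = d.reshape(z.shape[0], -1)
                grads[l.id] = {"w": d2.T @ z}
                if "b" in p:
                    grads[l.id]["b"] = d2.sum(axis=0)
                send(l.predecessors[0], (d2 @ p["w"]).reshape(in_shape))
            elif l.kind == "batchnorm":
                xhat, inv, shape, trained = caches[l.id]
                axes = (0, 2, 3) if xhat.ndim == 4 else (0,)
                dgamma = (d * xhat).sum(axis=axes)
                dbeta = d.sum(axis=axes)
                grads[l.id] = {"gamma": dgamma, "beta": dbeta}
                gamma = p["gamma"].reshape(shape)
                dxhat = d * gamma
                if trained:
                    m = xhat.size / xhat.shape[1]
                    dx = (inv.reshape(shape) / m) * (
                        m * dxhat
                        - dxhat.sum(axis=axes, keepdims=True)
                        - xhat * (dxhat * xhat).sum(axis=axes, keepdims=True))
                else:
                    dx = dxhat * inv.reshape(shape)
                send(l.predecessors[0], dx)
            elif l.kind == "relu":
                send(l.predecessors[0], d * caches[l.id][0])
            elif l.kind == "sigmoid":
                s = caches[l.id][0]
                send(l.predecessors[0], d * s * (1 - s))
            elif l.kind == "maxpool":
                send(l.predecessors[0], self._maxpool_backward(d, caches[l.id]))
            elif l.kind == "globalavgpool":
                (in_shape,) = caches[l.id]
                scale = in_shape[2] * in_shape[3]
                send(l.predecessors[0],
                     np.broadcast_to(d / scale, in_shape).copy())
            elif l.kind == "adaptivepool":
                in_shape, rh, rw = caches[l.id]
                dx = np.zeros(in_shape)
                for i, (h0, h1) in enumerate(rh):
                    for j, (w0, w1) in enumerate(rw):
                        area = (h1 - h0) * (w1 - w0)
                        dx[:, :, h0:h1, w0:w1] += d[:, :, i:i + 1, j:j + 1] / area
                send(l.predecessors[0], dx)
            elif l.kind == "flatten":
                (in_shape,) = caches[l.id]
                send(l.predecessors[0], d.reshape(in_shape))
            elif l.kind == "add":
                for q in l.predecessors:
                    send(q, d)
            elif l.kind == "concat":
                off = 0
                for q in l.predecessors:
                    c = acts[q].shape[1]
                    send(q, d[:, off:off + c])
                    off += c
            elif l.kind == "mul":
                feat, gate = acts[l.predecessors[0]], acts[l.predecessors[1]]
                send(l.predecessors[0], d * gate)
                dg = d * feat
                # gate is (B, C, 1, 1); reduce over broadcast axes
                send(l.predecessors[1], dg.sum(axis=(2, 3), keepdims=True))
            else:  # output
                send(l.predecessors[0], d)
        return grads

    @staticmethod
    def _maxpool_backward(d, cache):
        in_shape, ap_shape, idx, k, s, pd = cache
        dxp = np.zeros(ap_shape)
        Ho, Wo = idx.shape[2], idx.shape[3]
        for f in range(k * k):
            i, j = divmod(f, k)
            mask = idx == f
            sub = dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s]
            sub += d * mask
        if pd:
            return dxp[:, :, pd:pd + in_shape[2], pd:pd + in_shape[3]]
        return dxp

    # ---------------------------------------------------------- optimiser
    def adamw_step(self, grads, lr=1e-4, weight_decay=5e-2,
                   betas=(0.9, 0.999), eps=1e-8):
        """One decoupled-weight-decay Adam update over all parameters."""
        if self._opt is None:
            self._opt = {"t": 0, "m": {}, "v": {}}
        o = self._opt
        o["t"] += 1
        b1, b2 = betas
        for lid, d in self.params.items():
            for key, w in d.items():
                gkey = (lid, key)
                gval = grads.get(lid, {}).get(key)
                if gval is None:
                    continue
                m = o["m"].get(gkey, 0.0)
                v = o["v"].get(gkey, 0.0)
                m = b1 * m + (1 - b1) * gval
                v = b2 * v + (1 - b2) * gval * gval
                o["m"][gkey], o["v"][gkey] = m, v
                mhat = m / (1 - b1 ** o["t"])
                vhat = v / (1 - b2 ** o["t"])
                decay = weight_decay if key in ("w", "gamma") else 0.0
                d[key] = w - lr * (mhat / (np.sqrt(vhat) + eps) + decay * w)

    # ---------------------------------------------------------- weight IO
    def state_dict(self) -> dict:
        out = {}
        for lid, d in self.params.items():
            for key, w in d.items():
                out[f"{lid}/{key}"] = w
        for lid, d in self.state.items():
            for key, w in d.items():
                out[f"{lid}/state/{key}"] = w
        return out

    def load_state_dict(self, flat: dict) -> None:
        for name, w in flat.items():
            parts = name.split("/")
            if len(parts) == 3:
                self.state[parts[0]][parts[2]] = np.asarray(w)
            else:
                self.params[parts[0]][parts[1]] = np.asarray(w)


# --------------------------------------------------------------------------
# weight-level path expansion
# --------------------------------------------------------------------------

def expand_params(original: LayerGraph, params: dict, expanded: LayerGraph,
                  E: int, reinit_seed: int = 0,
                  reinit: bool = True) -> dict:
    """Weights for an expanded graph: path 1 copies, paths 2..E fresh.

    With ``reinit=False`` every path receives a copy of the original weights
    (the configuration in which all path outputs are numerically identical).
    The head is freshly initialised in either case, because its input width
    changed.
    """
    fresh = init_params(expanded, seed=reinit_seed)
    out = {}
    for lid in fresh:
        base, _, suffix = lid.rpartition(".p")
        if suffix.isdigit() and base in params:
            e = int(suffix)
            if e == 1 or not reinit:
                out[lid] = {k: v.copy() for k, v in params[base].items()}
            else:
                out[lid] = fresh[lid]
        elif lid in params and lid not in (expanded.classifier,) and \
                params[lid]["w" if "w" in params[lid] else "gamma"].shape == \
                fresh[lid]["w" if "w" in fresh[lid] else "gamma"].shape:
            out[lid] = {k: v.copy() for k, v in params[lid].items()}
        else:
            out[lid] = fresh[lid]
    return out
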