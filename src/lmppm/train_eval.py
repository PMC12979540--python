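"""Training recipe and evaluation metrics for image-folder classifiers.

The recipe is fixed-budget supervised training from scratch: AdamW
(learning rate 1e-4, weight decay 5e-2), cross-entropy loss, and the
augmentation triple random-resized-crop / random rotation in [-10, 10]
degrees / horizontal flip at probability 0.5, with inputs scaled to
[0, 1] (no mean/std standardisation).  No pre-trained weights anywhere.

Evaluation reports overall accuracy plus macro-averaged precision, recall
and F1 from one-vs-rest per-class counts, a confusion matrix, and
per-class ROC and PR curves from the softmax scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from scipy import ndimage
from sklearn import metrics as skm

from .graph import LayerGraph
from .nn import Network, cross_entropy
from . import cost as costmod
from .transform import apply_lmp_pm

log = logging.getLogger(__name__)

__all__ = ["TrainConfig", "MetricsReport", "load_image_folder", "augment_batch",
           "train", "evaluate", "compute_metrics", "grid_experiment",
           "TrainResult"]


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    weight_decay: float = 5e-2
    optimizer: str = "adamw"
    epochs: int = 100
    batch_size: int = 32
    loss: str = "cross_entropy"
    image_size: int = 224
    rotation_degrees: float = 10.0
    hflip_prob: float = 0.5
    crop_scale: tuple[float, float] = (0.5, 1.0)
    seed: int = 0

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "TrainConfig":
        d = yaml.safe_load(text)
        if "crop_scale" in d:
            d["crop_scale"] = tuple(d["crop_scale"])
        return cls(**d)


@dataclass
class MetricsReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class: pd.DataFrame            # TP/FP/FN/TN/precision/recall/f1
    confusion: np.ndarray
    roc: dict[int, dict[str, np.ndarray]]
    pr: dict[int, dict[str, np.ndarray]]
    n_samples: int

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "n_samples": self.n_samples,
            "per_class": self.per_class.to_dict(orient="index"),
            "confusion": self.confusion.tolist(),
            "auc": {c: float(v["auc"]) for c, v in self.roc.items()},
        }


# --------------------------------------------------------------------------
# data
# --------------------------------------------------------------------------

def load_image_folder(data_dir: str | Path, split: str,
                      image_size: int | None = None):
    """Load a directory-per-class split into (images, labels, class names).

    Images come back as float arrays in [0, 1], shape (n, 3, H, W).
    """
    root = Path(data_dir) / split
    if not root.is_dir():
        raise FileNotFoundError(f"no such split directory: {root}")
    classes = sorted(d.name for d in root.iterdir() if d.is_dir())
    if not classes:
        raise ValueError(f"no class folders under {root}")
    xs, ys = [], []
    for ci, cname in enumerate(classes):
        files = sorted((root / cname).glob("*"))
        files = [f for f in files if f.suffix.lower() in (".png", ".jpg", ".jpeg")]
        if not files:
            raise ValueError(f"empty class folder: {root / cname}")
        for f in files:
            img = Image.open(f).convert("RGB")
            if image_size and img.size != (image_size, image_size):
                img = img.resize((image_size, image_size), Image.BILINEAR)
            xs.append(np.asarray(img, dtype=np.float64).transpose(2, 0, 1) / 255.0)
            ys.append(ci)
    return np.stack(xs), np.array(ys), classes


def _random_resized_crop(img, rng, out_size, scale):
    c, H, W = img.shape
    for _ in range(10):
        area = rng.uniform(*scale) * H * W
        ratio = np.exp(rng.uniform(np.log(3 / 4), np.log(4 / 3)))
        h = int(round(np.sqrt(area / ratio)))
        w = int(round(np.sqrt(area * ratio)))
        if 0 < h <= H and 0 < w <= W:
            top = rng.integers(0, H - h + 1)
            left = rng.integers(0, W - w + 1)
            crop = img[:, top:top + h, left:left + w]
            break
    else:
        crop = img
    zh = out_size / crop.shape[1]
    zw = out_size / crop.shape[2]
    return ndimage.zoom(crop, (1, zh, zw), order=1)[:, :out_size, :out_size]


def augment_batch(x: np.ndarray, rng: np.random.Generator,
                  cfg: TrainConfig) -> np.ndarray:
    """Random resized crop + rotation + horizontal flip, per image."""
    out = np.empty((x.shape[0], 3, cfg.image_size, cfg.image_size))
    for i, img in enumerate(x):
        a = _random_resized_crop(img, rng, cfg.image_size, cfg.crop_scale)
        deg = rng.uniform(-cfg.rotation_degrees, cfg.rotation_degrees)
        a = ndimage.rotate(a, deg, axes=(1, 2), reshape=False, order=1,
                           mode="nearest")
        if rng.random() < cfg.hflip_prob:
            a = a[:, :, ::-1]
        out[i] = a
    return np.clip(out, 0.0, 1.0)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass
class TrainResult:
    network: Network
    log: pd.DataFrame
    best_val_accuracy: float
    best_state: dict = field(repr=False, default_factory=dict)


def _eval_loss_acc(net: Network, x, y, batch_size: int):
    losses, correct = [], 0
    for s in range(0, len(x), batch_size):
        xb, yb = x[s:s + batch_size], y[s:s + batch_size]
        logits = net.forward(xb, train=False)
        loss, _ = cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        correct += int((logits.argmax(axis=1) == yb).sum())
    return float(np.sum(losses) / len(x)), correct / len(x)


def train(graph: LayerGraph, data_dir: str | Path, cfg: TrainConfig,
          out_dir: str | Path | None = None) -> TrainResult:
    """Run the fixed recipe on train/ with per-epoch validation on val/.

    Returns the trained network, a per-epoch log (also written to
    ``log.csv`` under ``out_dir``), and the best-validation-accuracy
    checkpoint.  A zero-epoch call returns the freshly initialised network
    and an empty (header-only) log.
    """
    xtr, ytr, classes = load_image_folder(data_dir, "train", cfg.image_size)
    xva, yva, vclasses = load_image_folder(data_dir, "val", cfg.image_size)
    if classes != vclasses:
        raise ValueError(f"class mismatch between splits: {classes} vs {vclasses}")
    if graph.num_classes != len(classes):
        raise ValueError(
            f"model has {graph.num_classes} classes, data has {len(classes)}")
    rng = np.random.default_rng(cfg.seed)
    net = Network(graph, seed=cfg.seed)
    cols = ["epoch", "train_loss", "train_acc", "val_loss", "val_acc"]
    rows: list[dict] = []
    best_acc, best_state = -1.0, net.state_dict()
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(xtr))
        losses, correct = [], 0
        for s in range(0, len(order), cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            xb = augment_batch(xtr[idx], rng, cfg)
            yb = ytr[idx]
            logits = net.forward(xb, train=True)
            loss, dl = cross_entropy(logits, yb)
            grads = net.backward(dl)
            net.adamw_step(grads, lr=cfg.learning_rate,
                           weight_decay=cfg.weight_decay)
            losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == yb).sum())
        tr_loss = float(np.sum(losses) / len(xtr))
        tr_acc = correct / len(xtr)
        va_loss, va_acc = _eval_loss_acc(net, xva, yva, cfg.batch_size)
        rows.append(dict(zip(cols, [epoch, tr_loss, tr_acc, va_loss, va_acc])))
        log.info("epoch %d: train loss %.4f acc %.3f | val loss %.4f acc %.3f",
                 epoch, tr_loss, tr_acc, va_loss, va_acc)
        if va_acc > best_acc:
            best_acc = va_acc
            best_state = {k: v.copy() for k, v in net.state_dict().items()}
    logdf = pd.DataFrame(rows, columns=cols)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        logdf.to_csv(out / "log.csv", index=False)
        np.savez(out / "best.npz", **best_state)
        (out / "train_config.yaml").write_text(cfg.to_yaml())
    return TrainResult(network=net, log=logdf,
                       best_val_accuracy=max(best_acc, 0.0),
                       best_state=best_state)


# --------------------------------------------------------------------------
# evaluation
# --------------------------------------------------------------------------

def compute_metrics(y: np.ndarray, probs: np.ndarray,
                    n_classes: int) -> MetricsReport:
    """Metrics from labels and class-probability scores.

    Per-class counts are one-vs-rest; precision, recall and F1 follow the
    standard binary definitions per class and are macro-averaged; accuracy
    is overall sample accuracy.
    """
    k = n_classes
    pred = probs.argmax(axis=1)
    conf = skm.confusion_matrix(y, pred, labels=np.arange(k))
    per = {}
    for c in range(k):
        tp = int(conf[c, c])
        fp = int(conf[:, c].sum() - tp)
        fn = int(conf[c, :].sum() - tp)
        tn = int(conf.sum() - tp - fp - fn)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per[c] = dict(TP=tp, FP=fp, FN=fn, TN=tn,
                      precision=prec, recall=rec, f1=f1)
    per_df = pd.DataFrame(per).T
    roc, pr = {}, {}
    for c in range(k):
        yc = (y == c).astype(int)
        if 0 < yc.sum() < len(yc):
            fpr, tpr, _ = skm.roc_curve(yc, probs[:, c])
            auc = skm.auc(fpr, tpr)
            p, r, _ = skm.precision_recall_curve(yc, probs[:, c])
        else:
            fpr = tpr = p = r = np.array([])
            auc = float("nan")
        roc[c] = {"fpr": fpr, "tpr": tpr, "auc": auc}
        pr[c] = {"precision": p, "recall": r}
    return MetricsReport(
        accuracy=float((pred == y).mean()),
        macro_precision=float(per_df["precision"].mean()),
        macro_recall=float(per_df["recall"].mean()),
        macro_f1=float(per_df["f1"].mean()),
        per_class=per_df, confusion=conf, roc=roc, pr=pr, n_samples=len(y))


def evaluate(net: Network, data_dir: str | Path, split: str = "test",
             batch_size: int = 32, image_size: int | None = None) -> MetricsReport:
    """Accuracy, macro precision/recall/F1, confusion matrix, ROC/PR curves."""
    size = image_size or net.graph.input_size
    x, y, classes = load_image_folder(data_dir, split, size)
    k = net.graph.num_classes
    if len(classes) > k:
        raise ValueError(
            f"{len(classes)} classes in data but model head has {k}")
    scores = np.vstack([
        net.forward(x[s:s + batch_size], train=False)
        for s in range(0, len(x), batch_size)])
    exp = np.exp(scores - scores.max(axis=1, keepdims=True))
    probs = exp / exp.sum(axis=1, keepdims=True)
    return compute_metrics(y, probs, k)


# --------------------------------------------------------------------------
# the (N, E) grid
# --------------------------------------------------------------------------

def grid_experiment(base: LayerGraph, n_values, e_values,
                    data_dir: str | Path, cfg: TrainConfig,
                    depthwise: bool = True) -> pd.DataFrame:
    """Transform/train/evaluate over an (N, E) grid; one CSV-shaped row each."""
    rows = []
    for N in n_values:
        for E in e_values:
            g = apply_lmp_pm(base, N=N, E=E, depthwise=depthwise)
            rep = costmod.cost_report(g)
            res = train(g, data_dir, cfg)
            m = evaluate(res.network, data_dir, "test",
                         image_size=cfg.image_size)
            rows.append({
                "N": N, "E": E,
                "test_acc": m.accuracy, "precision": m.macro_precision,
                "f1": m.macro_f1, "recall": m.macro_recall,
                "parameters": rep.param_count, "flops": rep.mac_count,
            })
            log.info("grid N=%d E=%d: acc %.3f, %d params",
                     N, E, m.accuracy, rep.param_count)
    return pd.DataFrame(rows)
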