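"""Deterministic generator of leaf-like disease-classification image folders.

Real leaf-disease benchmarks are directory-per-class collections of
photographs in which classes differ by local lesion morphology and colour on
top of a shared green-leaf background.  This module emulates exactly that
statistical structure — an elliptical leaf over a textured background, vein
strokes, and class-specific lesion motifs (count, radius, hue, ring vs
blotch) — so the whole training and evaluation pipeline can run with no
external download.  It makes no attempt at photorealism.

Determinism contract: an identical :class:`SyntheticSpec` (including the
seed) produces a bit-identical image set.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb
from PIL import Image
from scipy import ndimage

__all__ = ["ClassMotif", "SyntheticSpec", "generate_dataset",
           "class_separability", "default_motifs", "render_image"]


@dataclass
class ClassMotif:
    """Lesion parameters that characterise one disease class."""

    spot_count_mean: float = 6.0
    radius_range: tuple[float, float] = (2.0, 5.0)
    hue: float = 0.08          # lesion hue in [0, 1)
    saturation: float = 0.8
    ring: bool = False         # ring-shaped vs filled blotch
    amplitude: float = 1.0     # lesion contrast; 0 erases the class signal

    def vector(self) -> np.ndarray:
        return np.array([self.spot_count_mean, *self.radius_range, self.hue,
                         self.saturation, float(self.ring), self.amplitude])


def default_motifs(n_classes: int) -> list[ClassMotif]:
    """Well-separated motifs: distinct hues, sizes and shapes per class.

    Lesion hues are spread over the non-green part of the colour circle so
    that no class's lesions blend into the leaf background, and lesion
    coverage is high enough that class identity is expressed in global
    colour statistics as well as local morphology — the property that makes
    the default set learnable by a small classifier on a short budget.
    """
    motifs = []
    for c in range(n_classes):
        frac = c / max(n_classes - 1, 1)
        motifs.append(ClassMotif(
            spot_count_mean=8.0 + 4.0 * (c % 3),
            radius_range=(3.0 + 1.0 * (c % 2), 6.0 + 1.5 * (c % 2)),
            hue=(0.50 + 0.55 * frac) % 1.0,   # blue .. violet .. red, skips green
            saturation=0.9,
            ring=bool(c % 2),
        ))
    return motifs


@dataclass
class SyntheticSpec:
    n_classes: int = 4
    images_per_class: int = 50
    image_size: int = 64
    seed: int = 7
    motifs: list[ClassMotif] | None = None
    leaf_hue: tuple[float, float] = (0.28, 0.36)
    vein_count: int = 5
    noise_amplitude: float = 0.08
    splits: dict[str, float] = field(
        default_factory=lambda: {"train": 0.7, "val": 0.15, "test": 0.15})
    class_counts: list[int] | None = None   # per-class totals (imbalance)

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if abs(sum(self.splits.values()) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.motifs is None:
            self.motifs = default_motifs(self.n_classes)
        if len(self.motifs) != self.n_classes:
            raise ValueError("one motif per class required")

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _value_noise(rng: np.random.Generator, size: int, cells: int = 8) -> np.ndarray:
    """Seeded lattice value-noise in [0, 1]: coarse grid, smooth upsampling."""
    lattice = rng.random((cells, cells))
    zoom = size / cells
    out = ndimage.zoom(lattice, zoom, order=3, mode="reflect")
    out = out[:size, :size]
    lo, hi = out.min(), out.max()
    return (out - lo) / (hi - lo + 1e-12)


def render_image(spec: SyntheticSpec, cls: int,
                 rng: np.random.Generator) -> np.ndarray:
    """One uint8 RGB leaf image with the class's lesion motif."""
    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    cy, cx = s / 2 + rng.normal(0, s * 0.02, 2)
    ry = s * rng.uniform(0.34, 0.42)
    rx = s * rng.uniform(0.24, 0.34)
    theta = rng.uniform(-0.5, 0.5)
    ys, xs = (yy - cy), (xx - cx)
    yr = ys * np.cos(theta) - xs * np.sin(theta)
    xr = ys * np.sin(theta) + xs * np.cos(theta)
    leaf = (yr / ry) ** 2 + (xr / rx) ** 2 <= 1.0

    hue = np.full((s, s), rng.uniform(*spec.leaf_hue))
    sat = np.full((s, s), 0.75)
    val = 0.45 + 0.35 * _value_noise(rng, s)
    val += spec.noise_amplitude * rng.standard_normal((s, s))

    # vein strokes: darker lines through the leaf centre
    for v in range(spec.vein_count):
        ang = rng.uniform(0, np.pi)
        dist = np.abs((yy - cy) * np.cos(ang) - (xx - cx) * np.sin(ang))
        val -= 0.10 * np.exp(-(dist / 0.8) ** 2)

    m = spec.motifs[cls]
    n_spots = max(1, int(rng.poisson(m.spot_count_mean)))  # a diseased leaf shows >= 1 lesion
    for _ in range(n_spots):
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, 0.8)
        py = cy + rad * ry * np.sin(ang)
        px = cx + rad * rx * np.cos(ang)
        r = rng.uniform(*m.radius_range)
        d = np.sqrt((yy - py) ** 2 + (xx - px) ** 2)
        if m.ring:
            mask = np.exp(-((d - r) / (0.35 * r + 0.5)) ** 2)
        else:
            mask = np.clip(1.0 - d / r, 0.0, 1.0)
        mask = m.amplitude * mask * leaf
        hue = hue * (1 - mask) + m.hue * mask
        sat = sat * (1 - mask) + m.saturation * mask
        val = val * (1 - mask) + 0.62 * mask

    hsv = np.stack([hue % 1.0, np.clip(sat, 0, 1), np.clip(val, 0, 1)],
                   axis=-1)
    rgb = hsv_to_rgb(hsv)
    bg = 0.15 + 0.1 * _value_noise(rng, s, cells=4)
    rgb = np.where(leaf[..., None], rgb, np.stack([bg * 0.8, bg * 0.6,
                                                   bg * 0.4], axis=-1))
    return (np.clip(rgb, 0, 1) * 255).astype(np.uint8)


def generate_dataset(spec: SyntheticSpec, out_dir: str | Path) -> pd.DataFrame:
    """Write train/val/test class folders of PNGs; return the manifest.

    The manifest (also written to ``manifest.csv``) lists path, class, split
    and the generation seed, one row per image.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    counts = spec.class_counts or [spec.images_per_class] * spec.n_classes
    if len(counts) != spec.n_classes:
        raise ValueError("class_counts must have one entry per class")
    for cls in range(spec.n_classes):
        total = counts[cls]
        n_train = int(round(spec.splits["train"] * total))
        n_val = int(round(spec.splits["val"] * total))
        split_of = (["train"] * n_train + ["val"] * n_val
                    + ["test"] * (total - n_train - n_val))
        for i in range(total):
            rng = np.random.default_rng(
                np.random.SeedSequence([spec.seed, cls, i]))
            img = render_image(spec, cls, rng)
            split = split_of[i]
            rel = Path(split) / f"class{cls:02d}" / f"img{i:04d}.png"
            path = out / rel
            path.parent.mkdir(parents=True, exist_ok=True)
            Image.fromarray(img).save(path)
            rows.append({"path": str(rel), "class": f"class{cls:02d}",
                         "split": split, "seed": spec.seed})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def class_separability(spec: SyntheticSpec) -> float:
    """Mean pairwise distance between class motif vectors, scaled to [0, 1].

    Each motif parameter is scaled by its physically attainable range before
    distances are taken, so 0 means all classes share one motif and 1 means
    maximal spread in every parameter.  Hue is treated as circular.
    """
    vs = np.array([m.vector() for m in spec.motifs])
    # scale: spot count (0..20), radii (0..size/4), hue circular (max 0.5),
    # saturation (0..1), ring flag (0..1), amplitude (0..1)
    r_max = spec.image_size / 4
    scale = np.array([20.0, r_max, r_max, 0.5, 1.0, 1.0, 1.0])
    n = len(vs)
    if n < 2:
        return 0.0
    total, pairs = 0.0, 0
    for i in range(n):
        for j in range(i + 1, n):
            d = np.abs(vs[i] - vs[j])
            d[3] = min(d[3], 1.0 - d[3])          # circular hue distance
            z = np.clip(d / scale, 0.0, 1.0)
            total += float(np.sqrt((z ** 2).mean()))
            pairs += 1
    return min(1.0, total / pairs)


def dataset_checksum(out_dir: str | Path) -> str:
    """SHA-256 over all PNG bytes (sorted paths): the determinism witness."""
    h = hashlib.sha256()
    for p in sorted(Path(out_dir).rglob("*.png")):
        h.update(p.read_bytes())
    return h.hexdigest()
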