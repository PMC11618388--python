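"""Synthetic berry-scene generator and dataset plumbing.

The real quarry is a red, densely clustered berry umbel sitting on a stem
above green canopy: visually, small clumps of bright red ellipses on a
green/brown background, frequently occluded by leaves, at varying scale
and illumination.  The generator renders exactly that structure — it makes
no attempt at photorealism, but it reproduces the properties the detector
must cope with (dense clustering, partial occlusion, scale and lighting
variation) and emits pixel-accurate boxes by construction.

Annotation rule: a fruit cluster whose visible fraction falls below 10%
(i.e. more than 90% occluded) is not labelled.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, replace
from typing import Dict, List, Sequence

import numpy as np
from scipy import ndimage
from skimage.draw import disk, ellipse, line

__all__ = [
    "SceneSpec", "LabeledImage", "generate_scene", "augment",
    "split_dataset", "write_yolo_dataset", "read_yolo_dataset",
    "CLASS_NAME",
]

CLASS_NAME = "RSZ"
MIN_VISIBLE_FRACTION = 0.1


@dataclass
class SceneSpec:
    """Parameters of one rendered scene; fully deterministic given seed."""

    img_size: int = 640
    n_plants: int = 4
    plant_spacing: float = 0.22        # fraction of image width
    berries_per_umbel: tuple = (15, 40)
    berry_radius: tuple = (2.0, 6.0)   # px at 640; scaled with img_size
    cluster_radius: float = 14.0       # px at 640
    occlusion_fraction: float = 0.3    # mean occluded fraction per umbel
    illumination: tuple = (0.5, 1.5)   # multiplicative gain range
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.occlusion_fraction < 1):
            raise ValueError("occlusion fraction must lie in [0, 1)")


@dataclass
class LabeledImage:
    """HxWx3 uint8 image plus normalised (class, cx, cy, w, h) labels."""

    image: np.ndarray
    labels: np.ndarray                  # (K, 5) float
    name: str = ""

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=float).reshape(-1, 5)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _background(rng, s):
    img = np.empty((s, s, 3), dtype=np.float32)
    base = np.array([46, 88, 38], dtype=np.float32)
    img[:] = base
    noise = rng.normal(0, 1, (s // 8 + 1, s // 8 + 1, 3)).astype(np.float32)
    noise = ndimage.zoom(noise, (8, 8, 1), order=1)[:s, :s]
    img += noise * 12.0
    # soil patches near the bottom
    for _ in range(rng.integers(2, 5)):
        cy = rng.uniform(0.75, 0.98) * s
        cx = rng.uniform(0, 1) * s
        rr, cc = ellipse(cy, cx, rng.uniform(0.04, 0.1) * s,
                         rng.uniform(0.1, 0.3) * s, shape=(s, s))
        img[rr, cc] = np.array([101, 78, 52]) + rng.normal(0, 6, 3)
    # canopy leaves
    for _ in range(rng.integers(25, 45)):
        cy = rng.uniform(0, 1) * s
        cx = rng.uniform(0, 1) * s
        g = rng.uniform(60, 130)
        col = np.array([g * 0.45, g, g * 0.4]) + rng.normal(0, 5, 3)
        rr, cc = ellipse(cy, cx, rng.uniform(0.015, 0.05) * s,
                         rng.uniform(0.03, 0.09) * s,
                         rotation=rng.uniform(0, np.pi), shape=(s, s))
        img[rr, cc] = col
    return img


def _draw_umbel(img, mask, rng, cy, cx, scale, spec):
    s = spec.img_size
    k = s / 640.0
    n_berries = int(rng.integers(*spec.berries_per_umbel))
    cluster_r = max(spec.cluster_radius * k * scale, 2.5)
    for _ in range(n_berries):
        ang = rng.uniform(0, 2 * np.pi)
        rad = cluster_r * np.sqrt(rng.uniform(0, 1))
        by = cy + rad * np.sin(ang) * 0.8
        bx = cx + rad * np.cos(ang)
        r = max(rng.uniform(*spec.berry_radius) * k * scale, 1.2)
        rr, cc = ellipse(by, bx, r, r * rng.uniform(0.8, 1.0),
                         rotation=rng.uniform(0, np.pi), shape=(s, s))
        col = np.array([rng.uniform(185, 235), rng.uniform(25, 60),
                        rng.uniform(25, 55)])
        img[rr, cc] = col
        mask[rr, cc] = True
        # specular highlight
        if len(rr):
            hr, hc = disk((by - r * 0.3, bx - r * 0.2), max(r * 0.25, 0.8),
                          shape=(s, s))
            img[hr, hc] = np.minimum(img[hr, hc] + 60, 255)


def _occlude_umbel(img, mask, occ, rng, target, s):
    """Cover ~``target`` of the True pixels in ``mask`` with leaf ellipses,
    accumulating into the global occluder mask ``occ``."""
    total = int(mask.sum())
    if total == 0 or target <= 0:
        return
    ys, xs = np.nonzero(mask)
    extent = max(np.ptp(ys), np.ptp(xs), 4)
    tries = 0
    while (occ & mask).sum() / total < target and tries < 200:
        tries += 1
        i = rng.integers(len(ys))
        g = rng.uniform(70, 120)
        col = np.array([g * 0.45, g, g * 0.4])
        rr, cc = ellipse(ys[i], xs[i],
                         rng.uniform(0.15, 0.45) * extent + 1.5,
                         rng.uniform(0.3, 0.8) * extent + 2.5,
                         rotation=rng.uniform(0, np.pi), shape=(s, s))
        img[rr, cc] = col
        occ[rr, cc] = True


def _visible_box(mask, min_fill=0.5):
    """Tight box over the visible fruit pixels, greedily trimmed from the
    sparsest edge until at least ``min_fill`` of its pixels are fruit."""
    ys, xs = np.nonzero(mask)
    if len(ys) == 0:
        return None
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
        ys, xs = np.nonzero(mask)
    y1, y2, x1, x2 = ys.min(), ys.max() + 1, xs.min(), xs.max() + 1
    for _ in range(64):
        sub = mask[y1:y2, x1:x2]
        if sub.mean() >= min_fill or min(y2 - y1, x2 - x1) <= 2:
            break
        # drop whichever border row/column is emptiest
        edges = [sub[0].mean(), sub[-1].mean(), sub[:, 0].mean(),
                 sub[:, -1].mean()]
        k = int(np.argmin(edges))
        if k == 0:
            y1 += 1
        elif k == 1:
            y2 -= 1
        elif k == 2:
            x1 += 1
        else:
            x2 -= 1
    return y1, y2, x1, x2


def generate_scene(spec: SceneSpec) -> LabeledImage:
    """Render one scene with its labels; a pure function of the spec."""
    rng = np.random.default_rng(spec.seed)
    s = spec.img_size
    img = _background(rng, s)
    n_plants = spec.n_plants
    if n_plants <= 0:
        warnings.warn("scene spec draws zero fruits: emitting empty labels",
                      stacklevel=2)
    masks = []
    # pass 1: stems and fruit clusters
    for p in (rng.permutation(n_plants) if n_plants > 0 else []):
        col_x = ((p + 0.5) / max(n_plants, 1)
                 + rng.uniform(-0.3, 0.3) * spec.plant_spacing) * s
        top_y = rng.uniform(0.15, 0.6) * s
        scale = rng.uniform(0.6, 1.4)
        base_y = min(top_y + rng.uniform(0.25, 0.45) * s, s - 1)
        rr, cc = line(int(base_y), int(col_x), int(top_y), int(col_x))
        ok = (rr >= 0) & (rr < s) & (cc >= 0) & (cc < s)
        img[rr[ok], cc[ok]] = np.array([70, 90, 45])
        mask = np.zeros((s, s), dtype=bool)
        _draw_umbel(img, mask, rng, top_y, col_x, scale, spec)
        masks.append(mask)
    # pass 2: leaf occluders (shared across the scene)
    occ = np.zeros((s, s), dtype=bool)
    if spec.occlusion_fraction > 0:
        for mask in masks:
            target = float(np.clip(
                rng.normal(spec.occlusion_fraction, 0.12), 0.0, 0.97))
            _occlude_umbel(img, mask, occ, rng, target, s)
    # pass 3: visibility rule and box fitting
    labels = []
    for mask in masks:
        total = mask.sum()
        if total == 0:
            continue
        visible = mask & ~occ
        if visible.sum() / total < MIN_VISIBLE_FRACTION:
            continue                        # annotation rule: >90% occluded
        box = _visible_box(visible)
        if box is None:
            continue
        y1, y2, x1, x2 = box
        labels.append([0, (x1 + x2) / (2 * s), (y1 + y2) / (2 * s),
                       (x2 - x1) / s, (y2 - y1) / s])
    if n_plants > 0 and not labels:
        warnings.warn("all fruits failed the visibility rule: empty labels",
                      stacklevel=2)
    gain = rng.uniform(*spec.illumination)
    img = np.clip(img * gain, 0, 255).astype(np.uint8)
    return LabeledImage(img, np.asarray(labels, dtype=float).reshape(-1, 5),
                        name=f"scene_{spec.seed:06d}")


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _affine_boxes(labels, mat, size):
    """Map normalised boxes through a 2x3 affine (pixel coords), re-fit
    axis-aligned, clip to frame, drop boxes below 10% of original area."""
    out = []
    for cls, cx, cy, w, h in labels:
        corners = np.array([
            [cx - w / 2, cy - h / 2], [cx + w / 2, cy - h / 2],
            [cx - w / 2, cy + h / 2], [cx + w / 2, cy + h / 2]]) * size
        pts = corners @ mat[:, :2].T + mat[:, 2]
        x1, y1 = pts.min(axis=0)
        x2, y2 = pts.max(axis=0)
        area0 = (x2 - x1) * (y2 - y1)
        x1c, y1c = max(x1, 0), max(y1, 0)
        x2c, y2c = min(x2, size), min(y2, size)
        if x2c <= x1c or y2c <= y1c:
            continue
        if area0 > 0 and (x2c - x1c) * (y2c - y1c) / area0 < 0.1:
            continue
        out.append([cls, (x1c + x2c) / (2 * size), (y1c + y2c) / (2 * size),
                    (x2c - x1c) / size, (y2c - y1c) / size])
    return np.asarray(out, dtype=float).reshape(-1, 5)


def augment(item, op: str, seed: int = 0, **params):
    """Apply one augmentation; images and labels transform consistently.

    ``op`` is one of ``rotate``, ``translate``, ``brightness``, ``occlude``
    or ``concat4`` (which takes a list of exactly four items).
    """
    rng = np.random.default_rng(seed)
    if op == "concat4":
        if not isinstance(item, (list, tuple)) or len(item) != 4:
            raise ValueError("concat4 requires exactly four inputs")
        return _concat4(item)
    if isinstance(item, (list, tuple)):
        raise ValueError(f"op {op!r} takes a single labelled image")
    img, labels = item.image, item.labels
    size = img.shape[0]
    if op == "rotate":
        angle = params.get("angle", float(rng.uniform(-15, 15)))
        if angle == 0:
            return replace(item, image=img.copy(), labels=labels.copy())
        out = ndimage.rotate(img, angle, reshape=False, order=1,
                             mode="nearest")
        th = np.deg2rad(-angle)   # image rows grow downward
        c, s_ = np.cos(th), np.sin(th)
        cx0 = size / 2
        mat = np.array([[c, -s_, cx0 - c * cx0 + s_ * cx0],
                        [s_, c, cx0 - s_ * cx0 - c * cx0]])
        return replace(item, image=out.astype(np.uint8),
                       labels=_affine_boxes(labels, mat, size))
    if op == "translate":
        dx = params.get("dx", int(rng.integers(-size // 10, size // 10 + 1)))
        dy = params.get("dy", int(rng.integers(-size // 10, size // 10 + 1)))
        if dx == 0 and dy == 0:
            return replace(item, image=img.copy(), labels=labels.copy())
        out = ndimage.shift(img, (dy, dx, 0), order=0, mode="nearest")
        mat = np.array([[1.0, 0.0, dx], [0.0, 1.0, dy]])
        return replace(item, image=out.astype(np.uint8),
                       labels=_affine_boxes(labels, mat, size))
    if op == "brightness":
        gain = params.get("gain", float(rng.uniform(0.5, 1.5)))
        out = np.clip(img.astype(np.float32) * gain, 0, 255).astype(np.uint8)
        return replace(item, image=out, labels=labels.copy())
    if op == "occlude":
        out = img.copy()
        occ = np.zeros(img.shape[:2], dtype=bool)
        for _ in range(params.get("n", 4)):
            y = rng.integers(0, size)
            x = rng.integers(0, size)
            hh = int(rng.uniform(0.03, 0.12) * size)
            ww = int(rng.uniform(0.03, 0.12) * size)
            g = rng.uniform(60, 110)
            out[y:y + hh, x:x + ww] = (g * 0.45, g, g * 0.4)
            occ[y:y + hh, x:x + ww] = True
        kept = []
        for row in labels:
            _, cx, cy, w, h = row
            x1 = int(max((cx - w / 2) * size, 0))
            x2 = int(min((cx + w / 2) * size, size))
            y1 = int(max((cy - h / 2) * size, 0))
            y2 = int(min((cy + h / 2) * size, size))
            region = occ[y1:y2, x1:x2]
            if region.size and region.mean() > 0.9:
                continue                     # fully hidden: unlabel it
            kept.append(row)
        return replace(item, image=out,
                       labels=np.asarray(kept, dtype=float).reshape(-1, 5))
    raise ValueError(f"unknown augmentation op {op!r}")


def _concat4(items):
    size = items[0].image.shape[0]
    for it in items:
        if it.image.shape[0] != size or it.image.shape[1] != size:
            raise ValueError("concat4 inputs must share one square size")
    mosaic = np.zeros((2 * size, 2 * size, 3), dtype=np.uint8)
    labels = []
    offsets = [(0, 0), (0, 1), (1, 0), (1, 1)]
    for it, (ry, rx) in zip(items, offsets):
        mosaic[ry * size:(ry + 1) * size, rx * size:(rx + 1) * size] = it.image
        for cls, cx, cy, w, h in it.labels:
            labels.append([cls, (cx + rx) / 2, (cy + ry) / 2, w / 2, h / 2])
    # rescale back to the original size (2x2 box mean)
    small = mosaic.reshape(size, 2, size, 2, 3).mean(axis=(1, 3))
    out_labels = [row for row in labels
                  if row[3] * size >= 2 and row[4] * size >= 2]
    return LabeledImage(small.astype(np.uint8),
                        np.asarray(out_labels, dtype=float).reshape(-1, 5),
                        name="mosaic")


# ---------------------------------------------------------------------------
# dataset plumbing
# ---------------------------------------------------------------------------

def split_dataset(items: Sequence, ratios=(7, 2, 1), seed: int = 0):
    """Random disjoint train/val/test partition with sizes apportioned by
    largest-remainder rounding of the given ratios."""
    total = sum(ratios)
    if total <= 0:
        raise ValueError("ratios must sum to a positive value")
    n = len(items)
    n_parts = sum(1 for r in ratios if r > 0)
    if n < n_parts:
        raise ValueError(f"{n} items cannot fill {n_parts} partitions")
    quotas = [n * r / total for r in ratios]
    sizes = [int(q) for q in quotas]
    rem = n - sum(sizes)
    order = sorted(range(len(ratios)), key=lambda i: quotas[i] - sizes[i],
                   reverse=True)
    for i in order[:rem]:
        sizes[i] += 1
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    parts, start = [], 0
    for sz in sizes:
        parts.append([items[i] for i in perm[start:start + sz]])
        start += sz
    return tuple(parts)


def write_yolo_dataset(splits, root):
    """Write the standard YOLO layout.

    ``splits`` is a dict mapping split name -> list of labelled images (a
    bare list is treated as a single ``train`` split).  Empty-label images
    get an empty txt file (negative sample), never a missing one.
    """
    import imageio.v3 as iio
    import yaml as _yaml

    if not isinstance(splits, dict):
        splits = {"train": list(splits)}
    for split, items in splits.items():
        img_dir = os.path.join(root, "images", split)
        lbl_dir = os.path.join(root, "labels", split)
        os.makedirs(img_dir, exist_ok=True)
        os.makedirs(lbl_dir, exist_ok=True)
        for i, it in enumerate(items):
            stem = it.name or f"im_{i:06d}"
            iio.imwrite(os.path.join(img_dir, stem + ".png"), it.image)
            with open(os.path.join(lbl_dir, stem + ".txt"), "w") as fh:
                for cls, cx, cy, w, h in it.labels:
                    fh.write(f"{int(cls)} {cx:.6f} {cy:.6f} "
                             f"{w:.6f} {h:.6f}\n")
    meta = {"path": root, "nc": 1, "names": [CLASS_NAME]}
    for split in splits:
        meta[split] = f"images/{split}"
    with open(os.path.join(root, "dataset.yaml"), "w") as fh:
        _yaml.safe_dump(meta, fh)


def read_yolo_dataset(root) -> Dict[str, List[LabeledImage]]:
    """Read a YOLO-layout dataset back; image/label stems must align."""
    import imageio.v3 as iio

    out = {}
    img_root = os.path.join(root, "images")
    orphans = []
    for split in sorted(os.listdir(img_root)):
        img_dir = os.path.join(img_root, split)
        lbl_dir = os.path.join(root, "labels", split)
        items = []
        stems_i = {os.path.splitext(f)[0] for f in os.listdir(img_dir)}
        stems_l = ({os.path.splitext(f)[0] for f in os.listdir(lbl_dir)}
                   if os.path.isdir(lbl_dir) else set())
        orphans += [f"{split}/{s}" for s in sorted(stems_i ^ stems_l)]
        for stem in sorted(stems_i & stems_l):
            img = iio.imread(os.path.join(img_dir, stem + ".png"))
            rows = []
            with open(os.path.join(lbl_dir, stem + ".txt")) as fh:
                for ln in fh:
                    if ln.strip():
                        v = ln.split()
                        rows.append([int(v[0])] + [float(x) for x in v[1:]])
            items.append(LabeledImage(img,
                                      np.asarray(rows, float).reshape(-1, 5),
                                      name=stem))
        out[split] = items
    if orphans:
        raise ValueError("unpaired image/label stems: " + ", ".join(orphans))
    return out
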