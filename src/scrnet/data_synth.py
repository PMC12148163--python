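"""Synthetic underwater scenes, YOLO-format label I/O and image transforms.

The generator emulates the statistics of shallow-water benthic survey imagery
(the DUO/UDD setting): a blue-green textured seafloor with four object
archetypes --

* ``urchin``   -- spiky dark disc (radial cosine spikes),
* ``cucumber`` -- elongated olive-brown blob,
* ``starfish`` -- five-armed orange star,
* ``scallop``  -- ribbed tan fan (half disc with radial ribs),

-- rendered at random positions/scales/orientations with a configurable
object-count range and pairwise IoU cap.  Everything is deterministic given a
seed: the same seed reproduces byte-identical images and labels.

Labels follow the YOLO txt dialect: one file per image, rows
``class cx cy w h`` normalised to [0, 1], six decimals.  Degradation
transforms (hazing, blur, low contrast, imbalanced light) change pixels only
and never touch labels.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

CLASS_NAMES = ("urchin", "cucumber", "starfish", "scallop")

DEGRADATIONS = ("hazing", "blur", "low_contrast", "imbalanced_light")


class LabelFormatError(ValueError):
    """Raised for malformed or out-of-range YOLO label rows."""


@dataclass(frozen=True)
class GTBox:
    """A ground-truth box in normalised center-x/center-y/width/height form."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def validate(self) -> "GTBox":
        if self.class_id < 0:
            raise LabelFormatError(f"negative class id {self.class_id}")
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise LabelFormatError(f"box centre outside [0,1]: ({self.cx}, {self.cy})")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise LabelFormatError(f"box size outside (0,1]: ({self.w}, {self.h})")
        return self

    def to_xyxy(self, img_w: int, img_h: int) -> tuple[float, float, float, float]:
        return ((self.cx - self.w / 2) * img_w, (self.cy - self.h / 2) * img_h,
                (self.cx + self.w / 2) * img_w, (self.cy + self.h / 2) * img_h)

    @classmethod
    def from_xyxy(cls, class_id, x1, y1, x2, y2, img_w, img_h) -> "GTBox":
        return cls(class_id, (x1 + x2) / 2 / img_w, (y1 + y2) / 2 / img_h,
                   (x2 - x1) / img_w, (y2 - y1) / img_h)


@dataclass
class Scene:
    image: np.ndarray  # (H, W, 3) uint8
    boxes: list[GTBox]
    meta: dict = field(default_factory=dict)


@dataclass
class SceneSpec:
    """What the generator draws."""

    img_size: int = 640
    num_classes: int = 4
    count_range: tuple[int, int] = (1, 10)
    obj_frac_range: tuple[float, float] = (0.06, 0.22)  # object radius / image side
    iou_cap: float = 0.4
    max_tries: int = 40


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _background(rng: np.random.Generator, s: int) -> np.ndarray:
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float32) / s
    base = np.empty((s, s, 3), dtype=np.float32)
    # blue-green water column with smooth low-frequency variation
    for c, (lo, hi) in enumerate(((20, 70), (80, 140), (90, 150))):
        phase = rng.uniform(0, 2 * np.pi, size=3)
        freq = rng.uniform(1.0, 3.0, size=3)
        wave = (np.sin(2 * np.pi * freq[0] * xx + phase[0])
                + np.sin(2 * np.pi * freq[1] * yy + phase[1])
                + np.sin(2 * np.pi * freq[2] * (xx + yy) + phase[2])) / 3.0
        base[:, :, c] = (lo + hi) / 2 + (hi - lo) / 2 * wave
    grain = rng.normal(0.0, 6.0, size=(s, s, 1)).astype(np.float32)
    return np.clip(base + grain, 0, 255)


def _object_mask(kind: int, rng: np.random.Generator, s: int, cx: float,
                 cy: float, r0: float) -> tuple[np.ndarray, np.ndarray]:
    """Boolean mask + per-pixel brightness modulation for one archetype."""
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float32)
    dx, dy = xx - cx, yy - cy
    ang = rng.uniform(0, 2 * np.pi)
    ca, sa = np.cos(ang), np.sin(ang)
    u, v = ca * dx + sa * dy, -sa * dx + ca * dy
    rr = np.sqrt(u * u + v * v) + 1e-6
    th = np.arctan2(v, u)
    shade = np.ones((s, s), dtype=np.float32)
    if kind == 0:  # urchin: spiky disc
        spikes = rng.integers(14, 22)
        edge = r0 * (0.72 + 0.28 * np.cos(spikes * th))
        mask = rr <= edge
        shade = 0.75 + 0.25 * (rr / r0)
    elif kind == 1:  # cucumber: elongated blob with gentle lobes
        elong = rng.uniform(2.2, 3.0)
        edge = r0 * (1.0 + 0.08 * np.cos(3 * th))
        mask = (u / elong) ** 2 + v ** 2 <= edge ** 2
        shade = 0.85 + 0.15 * np.cos(2 * np.pi * u / (elong * r0))
    elif kind == 2:  # starfish: five arms
        edge = r0 * (0.55 + 0.45 * np.cos(5 * th))
        mask = rr <= edge
        shade = 0.8 + 0.2 * (1.0 - rr / r0)
    else:  # scallop: ribbed fan (half disc)
        mask = (rr <= r0) & (np.abs(th) <= np.pi / 2.2)
        ribs = 0.5 + 0.5 * np.cos(9 * th)
        shade = 0.7 + 0.3 * ribs
    return mask, shade


_PALETTE = (  # per-class mean RGB
    np.array([45, 30, 50], dtype=np.float32),     # urchin: dark purple
    np.array([110, 100, 60], dtype=np.float32),   # cucumber: olive brown
    np.array([210, 120, 60], dtype=np.float32),   # starfish: orange
    np.array([205, 180, 150], dtype=np.float32),  # scallop: tan
)


def iou_xyxy(a, b) -> float:
    ix1, iy1 = max(a[0], b[0]), max(a[1], b[1])
    ix2, iy2 = min(a[2], b[2]), min(a[3], b[3])
    iw, ih = max(0.0, ix2 - ix1), max(0.0, iy2 - iy1)
    inter = iw * ih
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    union = area_a + area_b - inter
    return inter / union if union > 0 else 0.0


def generate_scene(seed: int, spec: SceneSpec | None = None) -> Scene:
    """Render one deterministic synthetic scene.

    Labels exactly enumerate the rendered objects (boxes are tight mask
    extents).  Objects overlap at most up to ``spec.iou_cap``.
    """
    spec = spec or SceneSpec()
    s = spec.img_size
    if s <= 0:
        raise ValueError(f"image size must be positive, got {spec.img_size}")
    rng = np.random.default_rng(seed)
    img = _background(rng, s)
    lo, hi = spec.count_range
    n_obj = int(rng.integers(lo, hi + 1)) if hi >= lo else 0
    boxes: list[GTBox] = []
    placed: list[tuple] = []
    for _ in range(n_obj):
        for _try in range(spec.max_tries):
            kind = int(rng.integers(0, spec.num_classes))
            r0 = rng.uniform(*spec.obj_frac_range) * s
            cx = rng.uniform(1.2 * r0, s - 1.2 * r0)
            cy = rng.uniform(1.2 * r0, s - 1.2 * r0)
            mask, shade = _object_mask(kind, rng, s, cx, cy, r0)
            if not mask.any():
                continue
            ys, xs = np.nonzero(mask)
            bb = (xs.min(), ys.min(), xs.max() + 1, ys.max() + 1)
            if all(iou_xyxy(bb, p) <= spec.iou_cap for p in placed):
                color = _PALETTE[kind % len(_PALETTE)]
                jitter = rng.uniform(0.8, 1.2, size=3).astype(np.float32)
                paint = color * jitter * shade[:, :, None]
                img[mask] = 0.15 * img[mask] + 0.85 * paint[mask]
                placed.append(bb)
                boxes.append(GTBox.from_xyxy(kind, *bb, s, s).validate())
                break
    return Scene(np.clip(img, 0, 255).astype(np.uint8), boxes,
                 meta={"seed": seed, "degradations": []})


# ---------------------------------------------------------------------------
# YOLO label I/O
# ---------------------------------------------------------------------------

def write_yolo_labels(boxes: list[GTBox], path: str) -> None:
    with open(path, "w") as fh:
        for b in boxes:
            fh.write(f"{b.class_id} {b.cx:.6f} {b.cy:.6f} {b.w:.6f} {b.h:.6f}\n")


def read_yolo_labels(path: str) -> list[GTBox]:
    boxes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise LabelFormatError(
                    f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            try:
                cid = int(parts[0])
                vals = [float(p) for p in parts[1:]]
            except ValueError as e:
                raise LabelFormatError(f"{path}:{lineno}: {e}") from None
            try:
                boxes.append(GTBox(cid, *vals).validate())
            except LabelFormatError as e:
                raise LabelFormatError(f"{path}:{lineno}: {e}") from None
    return boxes


@dataclass
class DatasetManifest:
    class_names: tuple[str, ...]
    splits: dict[str, list[str]]  # split name -> image paths
    ratios: tuple[float, float, float] = (0.70, 0.15, 0.15)

    def all_images(self) -> list[str]:
        return [p for split in self.splits.values() for p in split]


def split_dataset(images: list[str], ratios=(0.70, 0.15, 0.15),
                  seed: int = 0,
                  class_names=CLASS_NAMES) -> DatasetManifest:
    """Random train/val/test split: floor allocation, remainder to train."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"split ratios must sum to 1, got {ratios}")
    rng = np.random.default_rng(seed)
    order = list(np.array(images, dtype=object)[rng.permutation(len(images))])
    n = len(order)
    n_val = int(np.floor(ratios[1] * n))
    n_test = int(np.floor(ratios[2] * n))
    n_train = n - n_val - n_test
    return DatasetManifest(tuple(class_names),
                           {"train": order[:n_train],
                            "val": order[n_train:n_train + n_val],
                            "test": order[n_train + n_val:]},
                           tuple(ratios))


# ---------------------------------------------------------------------------
# geometric / photometric transforms
# ---------------------------------------------------------------------------

def normalize_pixels(image: np.ndarray) -> np.ndarray:
    """uint8 HWC -> float32 CHW scaled to [0, 1] (model input convention)."""
    return (image.astype(np.float32) / 255.0).transpose(2, 0, 1)


@dataclass(frozen=True)
class LetterboxTransform:
    scale: float
    pad_x: int
    pad_y: int

    def apply_box(self, b: GTBox, src_w: int, src_h: int, target: int) -> GTBox:
        x1, y1, x2, y2 = b.to_xyxy(src_w, src_h)
        x1, x2 = x1 * self.scale + self.pad_x, x2 * self.scale + self.pad_x
        y1, y2 = y1 * self.scale + self.pad_y, y2 * self.scale + self.pad_y
        return GTBox.from_xyxy(b.class_id, x1, y1, x2, y2, target, target)

    def invert_xyxy(self, x1, y1, x2, y2):
        return ((x1 - self.pad_x) / self.scale, (y1 - self.pad_y) / self.scale,
                (x2 - self.pad_x) / self.scale, (y2 - self.pad_y) / self.scale)


def letterbox(image: np.ndarray, target: int,
              fill: int = 114) -> tuple[np.ndarray, LetterboxTransform]:
    """Aspect-preserving resize plus symmetric padding to target x target."""
    if target <= 0:
        raise ValueError(f"target size must be positive, got {target}")
    h, w = image.shape[:2]
    scale = min(target / w, target / h)
    nw, nh = round(w * scale), round(h * scale)
    resized = np.asarray(
        Image.fromarray(image).resize((nw, nh), Image.BILINEAR))
    out = np.full((target, target, 3), fill, dtype=np.uint8)
    pad_x, pad_y = (target - nw) // 2, (target - nh) // 2
    out[pad_y:pad_y + nh, pad_x:pad_x + nw] = resized
    return out, LetterboxTransform(scale, pad_x, pad_y)


def flip_horizontal(scene: Scene) -> Scene:
    img = scene.image[:, ::-1].copy()
    boxes = [replace(b, cx=1.0 - b.cx) for b in scene.boxes]
    return Scene(img, boxes, dict(scene.meta))


def crop(scene: Scene, x1: int, y1: int, x2: int, y2: int,
         min_area_frac: float = 0.25) -> Scene:
    """Crop a window; re-clip boxes, dropping those with <25% area remaining."""
    h, w = scene.image.shape[:2]
    img = scene.image[y1:y2, x1:x2].copy()
    cw, ch = x2 - x1, y2 - y1
    boxes = []
    for b in scene.boxes:
        bx1, by1, bx2, by2 = b.to_xyxy(w, h)
        nx1, ny1 = max(bx1 - x1, 0), max(by1 - y1, 0)
        nx2, ny2 = min(bx2 - x1, cw), min(by2 - y1, ch)
        if nx2 <= nx1 or ny2 <= ny1:
            continue
        if (nx2 - nx1) * (ny2 - ny1) < min_area_frac * (bx2 - bx1) * (by2 - by1):
            continue
        boxes.append(GTBox.from_xyxy(b.class_id, nx1, ny1, nx2, ny2, cw, ch))
    return Scene(img, boxes, dict(scene.meta))


def color_jitter(scene: Scene, gains: np.ndarray) -> Scene:
    img = np.clip(scene.image.astype(np.float32) * gains[None, None, :],
                  0, 255).astype(np.uint8)
    return Scene(img, list(scene.boxes), dict(scene.meta))


def augment(scene: Scene, seed: int, p_flip: float = 0.5, p_crop: float = 0.5,
            p_jitter: float = 0.5, crop_frac: tuple[float, float] = (0.6, 1.0)
            ) -> Scene:
    """Random horizontal flip, crop and colour jitter; boxes stay consistent."""
    rng = np.random.default_rng(seed)
    out = scene
    if rng.uniform() < p_flip:
        out = flip_horizontal(out)
    if rng.uniform() < p_crop:
        h, w = out.image.shape[:2]
        fw, fh = rng.uniform(*crop_frac), rng.uniform(*crop_frac)
        cw, ch = max(1, round(w * fw)), max(1, round(h * fh))
        x1 = int(rng.integers(0, w - cw + 1))
        y1 = int(rng.integers(0, h - ch + 1))
        out = crop(out, x1, y1, x1 + cw, y1 + ch)
    if rng.uniform() < p_jitter:
        out = color_jitter(out, rng.uniform(0.7, 1.3, size=3).astype(np.float32))
    return out


# ---------------------------------------------------------------------------
# degradations (Fig-11-style underwater image deterioration)
# ---------------------------------------------------------------------------

_AIRLIGHT = np.array([150, 180, 190], dtype=np.float32)  # grey-blue haze colour


def degrade(image: np.ndarray, kind: str, strength: float) -> np.ndarray:
    """Apply an underwater degradation; dimensions (and labels) unchanged.

    strength 0 is the identity for every kind.
    """
    if kind not in DEGRADATIONS:
        raise ValueError(f"unknown degradation {kind!r}; choose from {DEGRADATIONS}")
    if not 0.0 <= strength <= 1.0:
        raise ValueError(f"strength must be in [0,1], got {strength}")
    img = image.astype(np.float32)
    if strength == 0.0:
        return image.copy()
    if kind == "hazing":
        alpha = 0.75 * strength
        img = (1 - alpha) * img + alpha * _AIRLIGHT[None, None, :]
    elif kind == "blur":
        sigma = 4.0 * strength
        for c in range(3):
            img[:, :, c] = gaussian_filter(img[:, :, c], sigma, mode="nearest")
    elif kind == "low_contrast":
        mean = img.mean(axis=(0, 1), keepdims=True)
        img = mean + (img - mean) * (1.0 - 0.85 * strength)
    elif kind == "imbalanced_light":
        w = img.shape[1]
        ramp = np.linspace(1.0 - 0.7 * strength, 1.0 + 0.7 * strength, w,
                           dtype=np.float32)
        img = img * ramp[None, :, None]
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# dataset materialisation (used by the CLI)
# ---------------------------------------------------------------------------

def write_dataset(out_dir: str, n: int, seed: int, spec: SceneSpec | None = None,
                  ratios=(0.70, 0.15, 0.15),
                  degradations: list[tuple[str, float]] | None = None
                  ) -> DatasetManifest:
    """Render `n` scenes to ``images/`` + ``labels/`` and write ``data.yaml``."""
    import yaml
    spec = spec or SceneSpec()
    img_dir = os.path.join(out_dir, "images")
    lbl_dir = os.path.join(out_dir, "labels")
    os.makedirs(img_dir, exist_ok=True)
    os.makedirs(lbl_dir, exist_ok=True)
    paths = []
    for i in range(n):
        scene = generate_scene(seed * 100003 + i, spec)
        img = scene.image
        for kind, strength in (degradations or []):
            img = degrade(img, kind, strength)
        name = f"scene_{i:05d}"
        ipath = os.path.join(img_dir, name + ".png")
        Image.fromarray(img).save(ipath)
        write_yolo_labels(scene.boxes, os.path.join(lbl_dir, name + ".txt"))
        paths.append(ipath)
    manifest = split_dataset(paths, ratios, seed)
    with open(os.path.join(out_dir, "data.yaml"), "w") as fh:
        yaml.safe_dump({"names": list(manifest.class_names),
                        "nc": len(manifest.class_names),
                        "splits": manifest.splits}, fh)
    return manifest
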