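"""Synthetic bark-beetle scenes with Pascal-VOC annotations.

The generator emulates the statistical structure of trap-tray pest imagery:
six object classes, a bimodal size distribution (small pests 2-6% of the
image side, large pests 10-25%), inter-class colour/texture similarity
controlled by a confusability knob, and varying illumination.  Objects are
oriented elliptical bodies with class-dependent base colour and stripe
texture on a mottled background; bounding boxes are the tight axis-aligned
hulls of the ellipses.  Everything is a pure function of (spec, seed).

The classes are named after the six categories of the public Scolytinae trap
dataset: Boerner, Leconte, Linnaeus, Acuminatus, Armandi, Coleoptera.  The
rendering is deliberately schematic — a knob-driven emulation, not a claim
about real beetle appearance.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .metrics import GroundTruthBox

__all__ = [
    "CLASS_NAMES",
    "SceneSpec",
    "AnnotatedImage",
    "generate_scene",
    "write_voc_xml",
    "read_voc_xml",
    "mosaic",
    "mixup",
    "make_dataset",
    "load_split",
]

logger = logging.getLogger(__name__)

CLASS_NAMES = ("Boerner", "Leconte", "Linnaeus", "Acuminatus", "Armandi", "Coleoptera")

# per-class visual prototypes: (hue base RGB, stripe frequency, elongation)
_PROTOTYPES = (
    ((0.45, 0.30, 0.16), 0.55, 2.2),   # Boerner — chestnut, coarse stripes
    ((0.30, 0.22, 0.12), 0.25, 2.8),   # Leconte — dark brown, sparse
    ((0.55, 0.42, 0.20), 0.85, 1.9),   # Linnaeus — tawny, fine stripes
    ((0.38, 0.33, 0.25), 1.10, 1.6),   # Acuminatus — grey-brown, very fine
    ((0.50, 0.26, 0.22), 0.70, 2.4),   # Armandi — reddish
    ((0.28, 0.28, 0.30), 0.95, 1.4),   # Coleoptera — slate, rounded
)

_SMALL_RANGE = (0.02, 0.06)   # fraction of min image side
_LARGE_RANGE = (0.10, 0.25)


@dataclass(frozen=True)
class SceneSpec:
    image_size: tuple[int, int] = (256, 256)
    n_objects: int = 8
    class_weights: tuple = (1 / 6,) * 6
    size_mix: float = 0.5
    illumination_gain: float = 1.0
    texture_confusability: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        w = np.asarray(self.class_weights, dtype=float)
        if w.size != 6 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("class_weights must be 6 non-negative values summing to 1")
        if not 0.0 <= self.size_mix <= 1.0:
            raise ValueError("size_mix must be in [0, 1]")
        if self.illumination_gain <= 0:
            raise ValueError("illumination_gain must be positive")
        if not 0.0 <= self.texture_confusability <= 1.0:
            raise ValueError("texture_confusability must be in [0, 1]")


@dataclass
class AnnotatedImage:
    pixels: np.ndarray                       # (H, W, 3) uint8
    boxes: list[GroundTruthBox]
    provenance: dict = field(default_factory=dict)
    box_weights: list[float] | None = None   # set by mixup

    def __post_init__(self):
        for b in self.boxes:
            if not 0 <= b.class_id < 6:
                raise ValueError(f"class_id out of range: {b.class_id}")


def _background(rng: np.random.Generator, H: int, W: int) -> np.ndarray:
    base = np.array([0.52, 0.48, 0.40]) + rng.uniform(-0.06, 0.06, 3)
    coarse = rng.uniform(-1, 1, (H // 8 + 1, W // 8 + 1))
    noise = np.kron(coarse, np.ones((8, 8)))[:H, :W]
    # light separable smoothing to avoid blocky seams
    k = np.ones(5) / 5
    noise = np.apply_along_axis(lambda r: np.convolve(r, k, mode="same"), 1, noise)
    noise = np.apply_along_axis(lambda c: np.convolve(c, k, mode="same"), 0, noise)
    gy, gx = np.mgrid[0:H, 0:W]
    grad = 0.12 * ((gx / W - 0.5) * rng.uniform(-1, 1) + (gy / H - 0.5) * rng.uniform(-1, 1))
    img = base[None, None, :] * (1.0 + 0.10 * noise + grad)[..., None]
    speck = rng.uniform(-0.03, 0.03, (H, W, 1))
    return np.clip(img + speck, 0, 1)


def _render_object(img: np.ndarray, rng: np.random.Generator, cls: int,
                   half_len: float, confus: float):
    """Draw one oriented ellipse; returns its tight box or None if unplaced."""
    H, W = img.shape[:2]
    colour, freq, elong = _PROTOTYPES[cls]
    mean_colour = np.mean([p[0] for p in _PROTOTYPES], axis=0)
    mean_freq = float(np.mean([p[1] for p in _PROTOTYPES]))
    colour = (1 - confus) * np.asarray(colour) + confus * mean_colour
    freq = (1 - confus) * freq + confus * mean_freq

    a = half_len
    b = max(1.5, half_len / elong * rng.uniform(0.85, 1.15))
    theta = rng.uniform(0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    # tight axis-aligned hull of the rotated ellipse
    ex = np.sqrt((a * ct) ** 2 + (b * st) ** 2)
    ey = np.sqrt((a * st) ** 2 + (b * ct) ** 2)
    cx = rng.uniform(ex + 1, W - ex - 1) if W - 2 * ex - 2 > 0 else None
    cy = rng.uniform(ey + 1, H - ey - 1) if H - 2 * ey - 2 > 0 else None
    if cx is None or cy is None:
        return None
    x0, x1 = int(np.floor(cx - ex)), int(np.ceil(cx + ex)) + 1
    y0, y1 = int(np.floor(cy - ey)), int(np.ceil(cy + ey)) + 1
    yy, xx = np.mgrid[y0:y1, x0:x1]
    u = (xx - cx) * ct + (yy - cy) * st
    v = -(xx - cx) * st + (yy - cy) * ct
    mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if not mask.any():
        return None
    stripes = 0.5 + 0.5 * np.sin(2 * np.pi * freq * u / max(a / 2.5, 1.0))
    shade = 1.0 - 0.55 * ((u / a) ** 2 + (v / b) ** 2)
    tex = (0.55 + 0.45 * stripes) * shade
    body = colour[None, None, :] * tex[..., None]
    body += rng.normal(0, 0.02, body.shape)
    patch = img[y0:y1, x0:x1]
    patch[mask] = np.clip(body[mask], 0, 1)
    return (float(cx - ex), float(cy - ey), float(cx + ex), float(cy + ey))


def generate_scene(spec: SceneSpec) -> AnnotatedImage:
    """Render one annotated scene, deterministic under ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.image_size
    img = _background(rng, H, W)
    side = min(H, W)
    boxes: list[GroundTruthBox] = []
    placed: list[tuple] = []
    attempts = 0
    while len(boxes) < spec.n_objects and attempts < spec.n_objects * 20:
        attempts += 1
        cls = int(rng.choice(6, p=np.asarray(spec.class_weights)))
        lo, hi = _SMALL_RANGE if rng.uniform() < spec.size_mix else _LARGE_RANGE
        half_len = rng.uniform(lo, hi) * side / 2
        box = _render_object(img, rng, cls, half_len, spec.texture_confusability)
        if box is None:
            continue
        # avoid near-total overlap with earlier objects
        ok = True
        for pb in placed:
            ix = max(0.0, min(box[2], pb[2]) - max(box[0], pb[0]))
            iy = max(0.0, min(box[3], pb[3]) - max(box[1], pb[1]))
            area = (box[2] - box[0]) * (box[3] - box[1])
            if ix * iy > 0.7 * area:
                ok = False
                break
        if not ok:
            continue
        placed.append(box)
        boxes.append(GroundTruthBox(cls, box))
    if len(boxes) < spec.n_objects:
        logger.info("placed %d of %d objects after bounded retries", len(boxes), spec.n_objects)
    img = np.clip(img * spec.illumination_gain, 0, 1)
    pixels = (img * 255).round().astype(np.uint8)
    return AnnotatedImage(pixels, boxes, {"seed": spec.seed, "spec": spec})


# ---------------------------------------------------------------------------
# Pascal-VOC XML I/O (1-based inclusive integer pixel coordinates)
# ---------------------------------------------------------------------------

def write_voc_xml(annotated: AnnotatedImage, path, image_filename: str | None = None) -> None:
    path = Path(path)
    H, W = annotated.pixels.shape[:2]
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = "images"
    ET.SubElement(root, "filename").text = image_filename or path.with_suffix(".png").name
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(W)
    ET.SubElement(size, "height").text = str(H)
    ET.SubElement(size, "depth").text = "3"
    for b in annotated.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = CLASS_NAMES[b.class_id]
        ET.SubElement(obj, "pose").text = "Unspecified"
        ET.SubElement(obj, "truncated").text = "0"
        ET.SubElement(obj, "difficult").text = "0"
        bnd = ET.SubElement(obj, "bndbox")
        x1, y1, x2, y2 = b.box
        # internal 0-based half-open -> VOC 1-based inclusive
        ET.SubElement(bnd, "xmin").text = str(int(round(x1)) + 1)
        ET.SubElement(bnd, "ymin").text = str(int(round(y1)) + 1)
        ET.SubElement(bnd, "xmax").text = str(int(round(x2)))
        ET.SubElement(bnd, "ymax").text = str(int(round(y2)))
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode")


def read_voc_xml(path) -> tuple[list[GroundTruthBox], tuple[int, int]]:
    """Parse a VOC file; returns (boxes 0-based, (H, W))."""
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise ValueError(f"malformed VOC XML in {path}: {exc}") from exc
    size = root.find("size")
    shape = (int(size.findtext("height")), int(size.findtext("width")))
    boxes = []
    for i, obj in enumerate(root.iter("object")):
        name = obj.findtext("name")
        if name not in CLASS_NAMES:
            raise ValueError(f"unknown class name {name!r} in {path} (object {i})")
        bnd = obj.find("bndbox")
        if bnd is None:
            raise ValueError(f"object {i} in {path} lacks a bndbox element")
        x1 = int(bnd.findtext("xmin")) - 1
        y1 = int(bnd.findtext("ymin")) - 1
        x2 = int(bnd.findtext("xmax"))
        y2 = int(bnd.findtext("ymax"))
        boxes.append(GroundTruthBox(CLASS_NAMES.index(name), (x1, y1, x2, y2)))
    return boxes, shape


# ---------------------------------------------------------------------------
# augmentations
# ---------------------------------------------------------------------------

def _resize_nearest(pixels: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    H, W = pixels.shape[:2]
    rows = np.clip((np.arange(out_h) + 0.5) * H / out_h, 0, H - 1).astype(int)
    cols = np.clip((np.arange(out_w) + 0.5) * W / out_w, 0, W - 1).astype(int)
    return pixels[rows][:, cols]


def mosaic(images: list[AnnotatedImage], out_size: tuple[int, int],
           seed: int = 0, centre: tuple[int, int] | None = None,
           min_area_frac: float = 0.10) -> AnnotatedImage:
    """Combine four annotated images into one canvas split at a random centre.

    Each input is scaled to cover its quadrant (and cropped); boxes are
    transformed, clipped to the quadrant, and dropped when the clipped area
    falls below ``min_area_frac`` of the transformed original.
    """
    if len(images) != 4:
        raise ValueError(f"mosaic needs exactly 4 images, got {len(images)}")
    H, W = out_size
    rng = np.random.default_rng(seed)
    if centre is None:
        centre = (int(rng.uniform(0.25, 0.75) * H), int(rng.uniform(0.25, 0.75) * W))
    cy, cx = centre
    canvas = np.zeros((H, W, 3), dtype=np.uint8)
    quads = [(0, 0, cy, cx), (0, cx, cy, W), (cy, 0, H, cx), (cy, cx, H, W)]
    boxes: list[GroundTruthBox] = []
    for img, (qy0, qx0, qy1, qx1) in zip(images, quads):
        qh, qw = qy1 - qy0, qx1 - qx0
        if qh <= 0 or qw <= 0:
            continue
        ih, iw = img.pixels.shape[:2]
        scale = max(qh / ih, qw / iw)
        sh, sw = int(np.ceil(ih * scale)), int(np.ceil(iw * scale))
        resized = _resize_nearest(img.pixels, sh, sw)
        canvas[qy0:qy1, qx0:qx1] = resized[:qh, :qw]
        for b in img.boxes:
            x1, y1, x2, y2 = (np.asarray(b.box) * scale)
            area = (x2 - x1) * (y2 - y1)
            cx1, cy1 = max(x1, 0) + qx0, max(y1, 0) + qy0
            cx2, cy2 = min(x2, qw) + qx0, min(y2, qh) + qy0
            clipped = max(0.0, cx2 - cx1) * max(0.0, cy2 - cy1)
            if area <= 0 or clipped < min_area_frac * area:
                continue
            boxes.append(GroundTruthBox(b.class_id, (cx1, cy1, cx2, cy2)))
    return AnnotatedImage(canvas, boxes, {"augmentation": "mosaic", "centre": centre})


def mixup(a: AnnotatedImage, b: AnnotatedImage, lam: float) -> AnnotatedImage:
    """Convex pixel blend of two images; boxes are the union of both inputs,
    each carrying its source mixing weight."""
    if a.pixels.shape != b.pixels.shape:
        raise ValueError(
            f"mixup requires equal image sizes, got {a.pixels.shape} vs {b.pixels.shape}"
        )
    if not 0.0 < lam < 1.0 and lam not in (0.0, 1.0):
        raise ValueError(f"lam must be in [0, 1], got {lam}")
    pixels = np.clip(
        lam * a.pixels.astype(np.float64) + (1 - lam) * b.pixels.astype(np.float64),
        0, 255,
    ).round().astype(np.uint8)
    boxes = list(a.boxes) + list(b.boxes)
    weights = [lam] * len(a.boxes) + [1 - lam] * len(b.boxes)
    return AnnotatedImage(pixels, boxes, {"augmentation": "mixup", "lam": lam}, weights)


# ---------------------------------------------------------------------------
# dataset materialisation
# ---------------------------------------------------------------------------

def make_dataset(out_dir, n_train: int = 64, n_val: int = 8, n_test: int = 8,
                 template: SceneSpec | None = None, seed: int = 0) -> dict:
    """Write a split dataset (PNG images, VOC XMLs, manifest files).

    Counts default to 64/8/8, the desk-scale analogue of the 1693/245/245
    split proportions.  Illumination gain is drawn per image in [0.6, 1.4] to
    emulate varying lighting.
    """
    out_dir = Path(out_dir)
    template = template or SceneSpec()
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "annotations").mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    index = {}
    counter = 0
    for split, n in (("train", n_train), ("val", n_val), ("test", n_test)):
        ids = []
        for _ in range(n):
            image_id = f"scene_{counter:05d}"
            counter += 1
            gain = float(master.uniform(0.6, 1.4))
            spec = SceneSpec(
                template.image_size, template.n_objects, template.class_weights,
                template.size_mix, gain, template.texture_confusability,
                seed=int(master.integers(0, 2**31 - 1)),
            )
            scene = generate_scene(spec)
            Image.fromarray(scene.pixels).save(out_dir / "images" / f"{image_id}.png")
            write_voc_xml(scene, out_dir / "annotations" / f"{image_id}.xml",
                          image_filename=f"{image_id}.png")
            ids.append(image_id)
        (out_dir / f"{split}.txt").write_text("\n".join(ids) + ("\n" if ids else ""))
        index[split] = ids
    return index


def load_split(dataset_dir, split: str) -> list[tuple[str, np.ndarray, list[GroundTruthBox]]]:
    """Load (image_id, pixels, boxes) for every image of a split manifest."""
    dataset_dir = Path(dataset_dir)
    manifest = dataset_dir / f"{split}.txt"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest for split {split!r} in {dataset_dir}")
    out = []
    for image_id in manifest.read_text().split():
        pixels = np.asarray(Image.open(dataset_dir / "images" / f"{image_id}.png"))
        boxes, _ = read_voc_xml(dataset_dir / "annotations" / f"{image_id}.xml")
        out.append((image_id, pixels, boxes))
    return out
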