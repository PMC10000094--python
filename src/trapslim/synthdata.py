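"""Synthetic camera-trap scenes with a controllable animal-background confound.

Camera traps sit at fixed sites, so every image from one site shares a
near-constant background signature.  When a species is photographed mostly at
its "home" sites, the background alone predicts the label in the training
distribution — the shortcut a classifier will happily learn — while a test
set that pairs species and sites uniformly breaks the correlation.  This
module manufactures exactly that statistical structure from scratch:

* each *site* has a distinct background signature (base hue plus an oriented
  sinusoidal texture) with per-image noise, strong enough that a linear probe
  can read the site off the pixels;
* each *species* is a parametric silhouette (a lobed radial blob whose lobe
  count is species-specific) filled with a species hue whose visibility is
  scaled by ``foreground_contrast``;
* a training manifest couples species to home sites with probability
  ``confound_strength``; the test manifest pairs them uniformly.

Exact instance masks and tight bounding boxes come for free, which is what
the augmentation stage consumes.  Coordinates are 0-based, half-open
``(x0, y0, x1, y1)``.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SceneConfig",
    "AnnotatedImage",
    "InstanceCutout",
    "generate_background",
    "generate_instance",
    "compose_scene",
    "generate_dataset",
    "write_coco_manifest",
    "read_coco_manifest",
]


@dataclass
class SceneConfig:
    """Study conditions for one synthetic camera-trap dataset.

    ``confound_strength`` is the probability that a *training* image of
    species ``s`` comes from its home site; 1.0 is the fully confounded
    regime.  ``foreground_contrast`` in [0, 1] scales how far the animal's
    fill departs from neutral grey — 0 renders it invisible.
    ``instances_per_class`` is (train, test) per species; the default keeps
    the conventional 7:3 split ratio.
    """

    n_sites: int = 4
    n_species: int = 4
    image_side: int = 96
    confound_strength: float = 1.0
    instances_per_class: tuple[int, int] = (28, 12)
    foreground_contrast: float = 0.35
    backgrounds_per_site: int = 8
    cutouts_per_species: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confound_strength <= 1.0:
            raise ValueError("confound_strength must lie in [0, 1]")
        if self.confound_strength == 1.0 and self.n_sites < self.n_species:
            raise ValueError(
                "a full confound needs n_sites >= n_species so each species "
                "gets a distinct home site")
        if self.n_sites < 1 or self.n_species < 2:
            raise ValueError("need at least 1 site and 2 species")


@dataclass
class AnnotatedImage:
    """One labelled frame: pixels, class, tight box, optional exact mask."""

    pixels: np.ndarray  # uint8 (H, W, 3)
    label: int
    bbox: tuple[int, int, int, int]  # (x0, y0, x1, y1), 0-based half-open
    mask: np.ndarray | None = None  # bool (H, W), aligned with pixels
    site: int = -1
    provenance: str = "real_composite"

    def validate(self) -> None:
        h, w = self.pixels.shape[:2]
        x0, y0, x1, y1 = self.bbox
        if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
            raise ValueError(f"bbox {self.bbox} invalid for image {w}x{h}")
        if self.pixels.dtype != np.uint8 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be uint8 RGB")
        if self.mask is not None:
            if self.mask.shape != (h, w):
                raise ValueError("mask must align with pixels")
            ys, xs = np.nonzero(self.mask)
            if len(ys) and not (
                xs.min() >= x0 and xs.max() < x1 and ys.min() >= y0 and ys.max() < y1
            ):
                raise ValueError("mask pixels fall outside bbox")


@dataclass
class InstanceCutout:
    """An extracted animal instance: patch plus its exact binary mask."""

    patch: np.ndarray  # uint8 (h, w, 3)
    mask: np.ndarray  # bool (h, w)
    label: int

    def validate(self) -> None:
        if self.patch.shape[:2] != self.mask.shape:
            raise ValueError("patch and mask shapes differ")
        if not self.mask.any():
            raise ValueError("mask has no on-pixel")


def _site_palette(site: int, n_sites: int) -> tuple[np.ndarray, float, float]:
    hue = (site / n_sites) % 1.0
    base = np.array(colorsys.hsv_to_rgb(hue, 0.55, 0.55)) * 255.0
    freq = 2.0 + 1.5 * site  # cycles across the frame, site-specific
    angle = (site * 0.9) % np.pi
    return base, freq, angle


def generate_background(site: int, rng: np.random.Generator, cfg: SceneConfig) -> np.ndarray:
    """One background frame for a site: hue + oriented texture + noise."""
    if not 0 <= site < cfg.n_sites:
        raise ValueError(f"site {site} out of range")
    n = cfg.image_side
    base, freq, angle = _site_palette(site, cfg.n_sites)
    yy, xx = np.mgrid[0:n, 0:n] / n
    phase = rng.uniform(0, 2 * np.pi)
    wave = np.sin(2 * np.pi * freq * (np.cos(angle) * xx + np.sin(angle) * yy) + phase)
    img = base[None, None, :] * (1.0 + 0.18 * wave[:, :, None])
    img += rng.normal(0.0, 8.0, size=(n, n, 3))
    img += rng.normal(0.0, 6.0)  # per-frame exposure jitter
    return np.clip(img, 0, 255).astype(np.uint8)


def _species_color(label: int, n_species: int) -> np.ndarray:
    # offset by half a bin so species hues interleave the site hues
    hue = ((label + 0.5) / n_species) % 1.0
    return np.array(colorsys.hsv_to_rgb(hue, 0.8, 0.8)) * 255.0


def species_lobes(label: int) -> int:
    """Lobe count of a species' silhouette (its shape descriptor)."""
    return label + 2


def generate_instance(label: int, rng: np.random.Generator, cfg: SceneConfig) -> InstanceCutout:
    """A species-specific silhouette cutout.

    The silhouette boundary is ``r(theta) = r0 * (1 + 0.30 cos(k theta + phase))``
    with lobe count ``k = label + 2``, so species are separable by shape
    alone; the fill is neutral grey pulled toward the species hue by
    ``foreground_contrast`` (0 leaves pure grey).
    """
    if not 0 <= label < cfg.n_species:
        raise ValueError(f"label {label} out of range")
    side = max(12, int(round(0.40 * cfg.image_side)))
    k = species_lobes(label)
    phase = rng.uniform(0, 2 * np.pi)
    r0 = 0.33 * side * rng.uniform(0.9, 1.1)
    cy = cx = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    theta = np.arctan2(yy - cy, xx - cx)
    rr = np.hypot(yy - cy, xx - cx)
    boundary = r0 * (1.0 + 0.30 * np.cos(k * theta + phase))
    mask = rr <= boundary
    c = cfg.foreground_contrast
    color = _species_color(label, cfg.n_species)
    fill = 128.0 + c * (color[None, None, :] - 128.0)
    fill = fill + c * rng.normal(0.0, 10.0, size=(side, side, 3))
    patch = np.zeros((side, side, 3))
    patch[mask] = fill[mask]
    # tight-crop so the patch/mask pair is its own bounding box
    ys, xs = np.nonzero(mask)
    y0, y1, x0, x1 = ys.min(), ys.max() + 1, xs.min(), xs.max() + 1
    cut = InstanceCutout(
        patch=np.clip(patch[y0:y1, x0:x1], 0, 255).astype(np.uint8),
        mask=mask[y0:y1, x0:x1],
        label=label,
    )
    cut.validate()
    return cut


def compose_scene(
    background: np.ndarray,
    cutout: InstanceCutout,
    position: tuple[int, int],
    rng: np.random.Generator | None = None,
    site: int = -1,
    provenance: str = "real_composite",
) -> AnnotatedImage:
    """Paste a cutout's mask-on pixels onto a background at (x, y) top-left."""
    x, y = position
    h, w = cutout.mask.shape
    H, W = background.shape[:2]
    if x < 0 or y < 0 or x + w > W or y + h > H:
        raise ValueError(f"cutout {w}x{h} at {(x, y)} does not fit in {W}x{H}")
    pixels = background.copy()
    region = pixels[y:y + h, x:x + w]
    region[cutout.mask] = cutout.patch[cutout.mask]
    full_mask = np.zeros((H, W), dtype=bool)
    full_mask[y:y + h, x:x + w] = cutout.mask
    ys, xs = np.nonzero(full_mask)
    bbox = (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
    img = AnnotatedImage(pixels=pixels, label=cutout.label, bbox=bbox,
                         mask=full_mask, site=site, provenance=provenance)
    img.validate()
    return img


def _place(rng: np.random.Generator, side: int, h: int, w: int) -> tuple[int, int]:
    return int(rng.integers(0, side - w + 1)), int(rng.integers(0, side - h + 1))


def home_site(label: int, cfg: SceneConfig) -> int:
    return label % cfg.n_sites


def generate_dataset(
    cfg: SceneConfig,
) -> tuple[list[AnnotatedImage], list[AnnotatedImage], list[InstanceCutout], list[tuple[int, np.ndarray]]]:
    """Build (train, test, cutout library, background library) from the seed.

    Training images pair species ``s`` with ``home_site(s)`` with probability
    ``confound_strength`` and with a uniform site otherwise; test images draw
    sites uniformly, decorrelating background from label.  The standalone
    cutout and background libraries feed the augmentation stage.
    """
    rng = np.random.default_rng(cfg.seed)
    n_train, n_test = cfg.instances_per_class
    train: list[AnnotatedImage] = []
    test: list[AnnotatedImage] = []
    for label in range(cfg.n_species):
        for split, count in (("train", n_train), ("test", n_test)):
            for _ in range(count):
                if split == "train" and rng.uniform() < cfg.confound_strength:
                    site = home_site(label, cfg)
                else:
                    site = int(rng.integers(0, cfg.n_sites))
                bg = generate_background(site, rng, cfg)
                cut = generate_instance(label, rng, cfg)
                pos = _place(rng, cfg.image_side, *cut.mask.shape)
                img = compose_scene(bg, cut, pos, site=site)
                (train if split == "train" else test).append(img)
    cutouts = [
        generate_instance(label, rng, cfg)
        for label in range(cfg.n_species)
        for _ in range(cfg.cutouts_per_species)
    ]
    backgrounds = [
        (site, generate_background(site, rng, cfg))
        for site in range(cfg.n_sites)
        for _ in range(cfg.backgrounds_per_site)
    ]
    return train, test, cutouts, backgrounds


# ---------------------------------------------------------------------------
# COCO-style disk round trip (PNG images + JSON manifest)

def write_coco_manifest(records: list[AnnotatedImage], out_dir: str | Path,
                        name: str = "manifest") -> Path:
    """Write PNGs plus a COCO-style JSON; bbox stored as [x, y, w, h]."""
    from PIL import Image

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    images, annotations = [], []
    labels = sorted({r.label for r in records})
    for i, r in enumerate(records):
        fn = f"{name}_{i:05d}.png"
        Image.fromarray(r.pixels).save(out / "images" / fn)
        entry = {"id": i, "file_name": fn,
                 "height": int(r.pixels.shape[0]), "width": int(r.pixels.shape[1])}
        if r.mask is not None:
            mfn = f"{name}_{i:05d}_mask.png"
            Image.fromarray((r.mask * 255).astype(np.uint8)).save(out / "masks" / mfn)
            entry["mask_file"] = mfn
        images.append(entry)
        x0, y0, x1, y1 = r.bbox
        annotations.append({
            "id": i, "image_id": i, "category_id": int(r.label),
            "bbox": [int(x0), int(y0), int(x1 - x0), int(y1 - y0)],
            "site": int(r.site), "provenance": r.provenance,
        })
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": int(c), "name": f"species_{c}"} for c in labels],
    }
    path = out / f"{name}.json"
    path.write_text(json.dumps(doc, indent=1, sort_keys=True))
    return path


def read_coco_manifest(path: str | Path) -> list[AnnotatedImage]:
    from PIL import Image

    path = Path(path)
    doc = json.loads(path.read_text())
    root = path.parent
    by_image = {a["image_id"]: a for a in doc["annotations"]}
    records = []
    for entry in doc["images"]:
        pixels = np.asarray(Image.open(root / "images" / entry["file_name"]).convert("RGB"))
        ann = by_image[entry["id"]]
        x, y, w, h = ann["bbox"]
        mask = None
        if "mask_file" in entry:
            mask = np.asarray(Image.open(root / "masks" / entry["mask_file"])) > 127
        records.append(AnnotatedImage(
            pixels=pixels, label=int(ann["category_id"]),
            bbox=(x, y, x + w, y + h), mask=mask,
            site=int(ann.get("site", -1)),
            provenance=ann.get("provenance", "real_composite"),
        ))
    return records
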