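"""Mixed data augmentation against background shortcuts.

Two complementary transforms:

* **Image synthesis (IS)** — an extracted animal instance is randomly
  rotated, rescaled and pasted onto a different background frame, breaking
  the coupling between a species and its home site's scenery.
* **Regional background suppression (RBS)** — a random rectangle strictly
  outside the animal's bounding box is filled with a constant (raw pixel 0
  by default), removing background evidence while guaranteeing that no
  foreground pixel is touched (the rectangle and the box are disjoint).

``build_augmented_set`` mixes both into a training manifest.  A plain
``cutout`` transform (rectangle anywhere, foreground included) is provided
as the standard point of comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from PIL import Image

from .synthdata import AnnotatedImage, InstanceCutout, compose_scene

__all__ = [
    "PasteParams",
    "RBSMask",
    "RBSParams",
    "random_paste",
    "sample_rbs_mask",
    "apply_rbs",
    "apply_cutout",
    "build_augmented_set",
]

log = logging.getLogger(__name__)


@dataclass
class PasteParams:
    rotation_range: tuple[float, float] = (0.0, 360.0)
    scale_range: tuple[float, float] = (0.6, 1.4)
    n_instances: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.scale_range
        if lo <= 0 or hi <= 0 or lo > hi:
            raise ValueError("scale_range bounds must be positive and ordered")
        rlo, rhi = self.rotation_range
        if not (0.0 <= rlo <= rhi <= 360.0):
            raise ValueError("rotation_range must lie within [0, 360]")


@dataclass
class RBSMask:
    rect: tuple[int, int, int, int]  # (x0, y0, x1, y1), half-open
    fill_value: int = 0


@dataclass
class RBSParams:
    area_range: tuple[float, float] = (0.05, 0.25)
    aspect_range: tuple[float, float] = (1 / 3, 3.0)
    n_masks: int = 1
    max_tries: int = 100
    fill_value: int = 0


def _transform_cutout(cutout: InstanceCutout, angle: float, scale: float) -> InstanceCutout:
    """Rotate about the center then rescale; re-rasterize mask (nearest)."""
    patch = Image.fromarray(cutout.patch)
    mask = Image.fromarray(cutout.mask.astype(np.uint8) * 255)
    if angle % 360.0 != 0.0:
        patch = patch.rotate(angle, resample=Image.BILINEAR, expand=True)
        mask = mask.rotate(angle, resample=Image.NEAREST, expand=True)
    if scale != 1.0:
        w, h = patch.size
        nw, nh = max(1, round(w * scale)), max(1, round(h * scale))
        patch = patch.resize((nw, nh), resample=Image.BILINEAR)
        mask = mask.resize((nw, nh), resample=Image.NEAREST)
    m = np.asarray(mask) > 127
    p = np.asarray(patch)
    if not m.any():
        # degenerate rasterization (tiny scale): keep the center pixel
        m = np.zeros_like(m)
        m[m.shape[0] // 2, m.shape[1] // 2] = True
    ys, xs = np.nonzero(m)
    y0, y1, x0, x1 = ys.min(), ys.max() + 1, xs.min(), xs.max() + 1
    return InstanceCutout(patch=p[y0:y1, x0:x1], mask=m[y0:y1, x0:x1],
                          label=cutout.label)


def random_paste(
    cutout: InstanceCutout,
    background: np.ndarray,
    rng: np.random.Generator,
    params: PasteParams | None = None,
    position: tuple[int, int] | None = None,
    site: int = -1,
) -> AnnotatedImage:
    """Rotate, rescale and paste an instance at a uniform in-bounds position."""
    params = params or PasteParams()
    cutout.validate()
    rlo, rhi = params.rotation_range
    angle = float(rng.uniform(rlo, rhi))
    scale = float(rng.uniform(*params.scale_range))
    t = _transform_cutout(cutout, angle, scale)
    h, w = t.mask.shape
    H, W = background.shape[:2]
    if h > H or w > W:
        raise ValueError(
            f"transformed cutout {w}x{h} does not fit background {W}x{H}")
    if position is None:
        position = (int(rng.integers(0, W - w + 1)), int(rng.integers(0, H - h + 1)))
    img = compose_scene(background, t, position, site=site, provenance="synthesized")
    return img


def sample_rbs_mask(
    image_size: tuple[int, int],
    bbox: tuple[int, int, int, int],
    rng: np.random.Generator,
    area_range: tuple[float, float] = (0.05, 0.25),
    aspect_range: tuple[float, float] = (1 / 3, 3.0),
    max_tries: int = 100,
    fill_value: int = 0,
) -> RBSMask | None:
    """Rejection-sample a rectangle disjoint from the bounding box.

    Area fraction is uniform over ``area_range``, the height/width ratio is
    log-uniform over ``aspect_range`` and the top-left corner uniform over
    in-bounds positions.  Returns ``None`` after ``max_tries`` rejections.
    """
    H, W = image_size
    bx0, by0, bx1, by1 = bbox
    for _ in range(max_tries):
        area = rng.uniform(*area_range) * H * W
        aspect = float(np.exp(rng.uniform(np.log(aspect_range[0]),
                                          np.log(aspect_range[1]))))
        rh = int(round(np.sqrt(area * aspect)))
        rw = int(round(np.sqrt(area / aspect)))
        rh, rw = min(max(rh, 1), H), min(max(rw, 1), W)
        x0 = int(rng.integers(0, W - rw + 1))
        y0 = int(rng.integers(0, H - rh + 1))
        x1, y1 = x0 + rw, y0 + rh
        disjoint = x1 <= bx0 or x0 >= bx1 or y1 <= by0 or y0 >= by1
        if disjoint:
            return RBSMask(rect=(x0, y0, x1, y1), fill_value=fill_value)
    return None


def apply_rbs(
    image: AnnotatedImage,
    rng: np.random.Generator,
    params: RBSParams | None = None,
) -> AnnotatedImage:
    """Suppress random background rectangles; foreground pixels untouched."""
    params = params or RBSParams()
    pixels = image.pixels.copy()
    applied = 0
    for _ in range(params.n_masks):
        m = sample_rbs_mask(pixels.shape[:2], image.bbox, rng,
                            params.area_range, params.aspect_range,
                            params.max_tries, params.fill_value)
        if m is None:
            log.warning("RBS: no disjoint rectangle found; image left unmodified")
            continue
        x0, y0, x1, y1 = m.rect
        pixels[y0:y1, x0:x1] = m.fill_value
        applied += 1
    if applied == 0 and params.n_masks > 0:
        return image
    return AnnotatedImage(pixels=pixels, label=image.label, bbox=image.bbox,
                          mask=image.mask, site=image.site, provenance="suppressed")


def apply_cutout(
    image: AnnotatedImage,
    rng: np.random.Generator,
    params: RBSParams | None = None,
) -> AnnotatedImage:
    """Classic cutout: rectangles placed anywhere, foreground included."""
    params = params or RBSParams()
    H, W = image.pixels.shape[:2]
    pixels = image.pixels.copy()
    for _ in range(params.n_masks):
        area = rng.uniform(*params.area_range) * H * W
        aspect = float(np.exp(rng.uniform(np.log(params.aspect_range[0]),
                                          np.log(params.aspect_range[1]))))
        rh = min(max(int(round(np.sqrt(area * aspect))), 1), H)
        rw = min(max(int(round(np.sqrt(area / aspect))), 1), W)
        x0 = int(rng.integers(0, W - rw + 1))
        y0 = int(rng.integers(0, H - rh + 1))
        pixels[y0:y0 + rh, x0:x0 + rw] = params.fill_value
    return AnnotatedImage(pixels=pixels, label=image.label, bbox=image.bbox,
                          mask=image.mask, site=image.site, provenance="suppressed")


def build_augmented_set(
    train: list[AnnotatedImage],
    cutouts: list[InstanceCutout],
    backgrounds: list[tuple[int, np.ndarray]],
    rng: np.random.Generator,
    is_fraction: float = 0.5,
    rbs_fraction: float = 0.5,
    paste_params: PasteParams | None = None,
    rbs_params: RBSParams | None = None,
) -> list[AnnotatedImage]:
    """Original records plus synthesized and suppressed additions.

    Adds ``round(is_fraction * N)`` pasted records (random cutout of a class
    x random background) and ``round(rbs_fraction * N)`` suppressed records;
    the class balance of additions follows the original manifest.
    """
    n = len(train)
    n_is = int(round(is_fraction * n))
    n_rbs = int(round(rbs_fraction * n))
    if n_is > 0 and not backgrounds:
        raise ValueError("image synthesis requested with an empty background pool")
    if n_rbs > 0 and not train:
        raise ValueError("RBS requested on an empty manifest")
    out = list(train)

    by_label: dict[int, list[InstanceCutout]] = {}
    for c in cutouts:
        by_label.setdefault(c.label, []).append(c)

    # additions follow the original class balance: walk a shuffled copy
    order = rng.permutation(n)
    for i in range(n_is):
        src = train[order[i % n]]
        pool = by_label.get(src.label)
        if not pool:
            raise ValueError(f"no cutout available for class {src.label}")
        cut = pool[int(rng.integers(len(pool)))]
        site, bg = backgrounds[int(rng.integers(len(backgrounds)))]
        out.append(random_paste(cut, bg, rng, paste_params, site=site))
    order = rng.permutation(n)
    for i in range(n_rbs):
        out.append(apply_rbs(train[order[i % n]], rng, rbs_params))
    return out
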