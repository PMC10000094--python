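"""Evaluation suite: accuracy, confusion matrices, Grad-CAM, FRoH.

FRoH — the *foreground ratio of the heatmap* — quantifies how much of a
model's class-attention falls on the animal rather than the scenery: it is
the Grad-CAM heat summed inside the labelled bounding box divided by the
heat summed over the whole image.  A model that recognizes the species from
background shortcuts scores low; one attending to the animal scores high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from PIL import Image

from .model import Classifier, activations_and_gradients, records_to_arrays
from .synthdata import AnnotatedImage

__all__ = [
    "ConfusionMatrix",
    "HeatMap",
    "acc_cls",
    "confusion",
    "grad_cam",
    "froh",
    "dataset_froh",
    "save_heatmap_overlay",
]


def acc_cls(predictions, labels) -> float:
    """Micro accuracy: sum of per-class true positives over all predictions."""
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    if pred.shape != lab.shape or pred.size == 0:
        raise ValueError("predictions and labels must be equal-length and non-empty")
    return float((pred == lab).mean())


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: np.ndarray  # (C, C); entry (i, j): true class i predicted as j

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1] or (c < 0).any():
            raise ValueError("counts must be a square non-negative table")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def row_normalized(self) -> np.ndarray:
        """Class-wise accuracy view: each row divided by its class count."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = self.counts / sums
        return np.nan_to_num(out)


def confusion(predictions, labels, C: int) -> ConfusionMatrix:
    pred = np.asarray(predictions, dtype=np.int64)
    lab = np.asarray(labels, dtype=np.int64)
    if ((lab < 0) | (lab >= C)).any() or ((pred < 0) | (pred >= C)).any():
        raise ValueError("labels/predictions out of range")
    counts = np.zeros((C, C), dtype=np.int64)
    np.add.at(counts, (lab, pred), 1)
    return ConfusionMatrix(counts=counts)


@dataclass(frozen=True)
class HeatMap:
    values: np.ndarray  # non-negative, at input spatial resolution
    source: tuple = ("", "", -1)  # (model id, image id, class id)

    def __post_init__(self) -> None:
        if (np.asarray(self.values) < 0).any():
            raise ValueError("heatmap values must be non-negative")


def _bilinear_resize(a: np.ndarray, hw: tuple[int, int]) -> np.ndarray:
    img = Image.fromarray(a.astype(np.float32), mode="F")
    return np.asarray(img.resize((hw[1], hw[0]), resample=Image.BILINEAR))


def grad_cam(model: Classifier, image: np.ndarray, class_index: int,
             image_id: str = "") -> HeatMap:
    """Gradient-weighted class activation map for one normalized image.

    Channel weights are the spatial means of d(logit_c)/dA over the last
    convolutional stage's activations A; the map is ReLU(sum_k alpha_k A_k),
    bilinearly upsampled to the input resolution.  The raw (unnormalized)
    map is returned — FRoH is a ratio of sums, so any positive rescaling
    cancels.
    """
    A, dA = activations_and_gradients(model, image, class_index)
    alpha = dA.mean(axis=(1, 2))
    cam = np.maximum((alpha[:, None, None] * A).sum(axis=0), 0.0)
    side = model.spec.input_side
    up = np.maximum(_bilinear_resize(cam, (side, side)), 0.0)
    return HeatMap(values=up, source=("classifier", image_id, class_index))


def froh(heatmap: HeatMap | np.ndarray, bbox: tuple[int, int, int, int]) -> float:
    """Fraction of total heat inside the half-open box (x0, y0, x1, y1)."""
    values = heatmap.values if isinstance(heatmap, HeatMap) else np.asarray(heatmap)
    h, w = values.shape
    x0, y0, x1, y1 = bbox
    if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
        raise ValueError(f"bbox {bbox} invalid for heatmap {w}x{h}")
    total = float(values.sum())
    if total == 0.0:
        return 0.0
    return float(values[y0:y1, x0:x1].sum()) / total


def dataset_froh(
    model: Classifier,
    records: list[AnnotatedImage],
    class_source: str = "true",
) -> tuple[float, pd.DataFrame]:
    """Mean FRoH over a manifest plus the per-image table.

    Heatmaps target each record's true class by default
    (``class_source='predicted'`` switches to the model's own prediction).
    Records whose heatmap is identically zero contribute 0 and are flagged.
    """
    if class_source not in ("true", "predicted"):
        raise ValueError("class_source must be 'true' or 'predicted'")
    X, y = records_to_arrays(records)
    rows = []
    for i, rec in enumerate(records):
        if class_source == "true":
            target = int(y[i])
        else:
            target = int(model.forward(X[i:i + 1], train=False).argmax())
        hm = grad_cam(model, X[i], target, image_id=str(i))
        zero = float(hm.values.sum()) == 0.0
        rows.append({"image": i, "label": int(y[i]), "target": target,
                     "froh": froh(hm, rec.bbox), "zero_heat": zero})
    table = pd.DataFrame(rows)
    return float(table["froh"].mean()), table


def save_heatmap_overlay(record: AnnotatedImage, heatmap: HeatMap, path,
                         alpha: float = 0.45) -> None:
    """Write the image with its attention map and bounding box overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Rectangle

    fig, ax = plt.subplots(figsize=(3, 3), dpi=120)
    ax.imshow(record.pixels)
    ax.imshow(heatmap.values, cmap="jet", alpha=alpha)
    x0, y0, x1, y1 = record.bbox
    ax.add_patch(Rectangle((x0 - 0.5, y0 - 0.5), x1 - x0, y1 - y0,
                           fill=False, edgecolor="white", linewidth=1.2))
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", pad_inches=0)
    plt.close(fig)
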