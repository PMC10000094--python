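"""Knowledge-distillation fine-tuning of a pruned student.

The frozen teacher supervises the student through one of three signals:

* ``mse`` — mean squared difference between the two softmax output
  distributions (the primary method);
* ``soft_kl`` — KL(teacher || student) on temperature-softened
  distributions, scaled by T^2;
* ``hard_kl`` — cross-entropy of the student against the teacher's argmax
  pseudo-labels (KL up to the zero entropy of a one-hot target).

The training objective is ``CE(student, labels) + lambda * kd`` with the
usual optimizer settings; the teacher's weights are never updated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .model import Classifier, TrainConfig, records_to_arrays, train_classifier
from .synthdata import AnnotatedImage

__all__ = ["KDConfig", "kd_loss", "finetune_with_kd"]

_EPS = 1e-12


@dataclass
class KDConfig:
    method: str = "mse"  # mse | soft_kl | hard_kl
    kd_weight: float = 1.0
    temperature: float = 1.0
    on_logits: bool = False  # mse on raw logits instead of probabilities
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.method not in ("mse", "soft_kl", "hard_kl"):
            raise ValueError(f"unknown KD method {self.method!r}")
        if self.kd_weight < 0:
            raise ValueError("kd_weight must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


def _soften(p: np.ndarray, T: float) -> np.ndarray:
    """Temperature-soften a probability vector: p^(1/T), renormalized."""
    if T == 1.0:
        return p
    q = np.clip(p, _EPS, None) ** (1.0 / T)
    return q / q.sum(axis=1, keepdims=True)


def kd_loss(
    student_probs: np.ndarray,
    teacher_probs: np.ndarray,
    teacher_labels: np.ndarray | None = None,
    cfg: KDConfig | None = None,
) -> float:
    """Distillation loss between matching batches of output distributions."""
    cfg = cfg or KDConfig()
    ps = np.atleast_2d(np.asarray(student_probs, dtype=float))
    pt = np.atleast_2d(np.asarray(teacher_probs, dtype=float))
    if ps.shape != pt.shape:
        raise ValueError(f"class counts differ: {ps.shape} vs {pt.shape}")
    if cfg.method == "mse":
        return float(((ps - pt) ** 2).mean())
    if cfg.method == "soft_kl":
        T = cfg.temperature
        ps_t, pt_t = _soften(ps, T), _soften(pt, T)
        kl = (pt_t * (np.log(np.clip(pt_t, _EPS, None))
                      - np.log(np.clip(ps_t, _EPS, None)))).sum(axis=1)
        return float(T * T * kl.mean())
    # hard_kl
    if teacher_labels is None:
        teacher_labels = pt.argmax(axis=1)
    picked = ps[np.arange(len(ps)), teacher_labels]
    return float(-np.log(np.clip(picked, _EPS, None)).mean())


def _kd_grad(logits_s: np.ndarray, probs_t: np.ndarray, cfg: KDConfig) -> tuple[float, np.ndarray]:
    """KD loss and its gradient with respect to the student logits."""
    B, C = logits_s.shape
    ps = nn.softmax(logits_s)
    if cfg.method == "mse":
        if cfg.on_logits:
            # distance on raw scores; teacher probs stand in for its logits'
            # softmax, so compare in probability space anyway unless the
            # caller supplies logits — handled by finetune_with_kd
            raise AssertionError("on_logits handled upstream")
        loss = float(((ps - probs_t) ** 2).mean())
        u = 2.0 * (ps - probs_t) / (B * C)
        g = ps * (u - (u * ps).sum(axis=1, keepdims=True))
        return loss, g.astype(np.float32)
    if cfg.method == "soft_kl":
        T = cfg.temperature
        ps_t = nn.softmax(logits_s / T)
        pt_t = _soften(probs_t, T)
        kl = (pt_t * (np.log(np.clip(pt_t, _EPS, None))
                      - np.log(np.clip(ps_t, _EPS, None)))).sum(axis=1)
        loss = float(T * T * kl.mean())
        g = T * (ps_t - pt_t) / B
        return loss, g.astype(np.float32)
    # hard_kl
    hard = probs_t.argmax(axis=1)
    loss = float(-np.log(np.clip(ps[np.arange(B), hard], _EPS, None)).mean())
    g = ps.copy()
    g[np.arange(B), hard] -= 1.0
    return loss, (g / B).astype(np.float32)


def _mse_logits_grad(logits_s: np.ndarray, logits_t: np.ndarray) -> tuple[float, np.ndarray]:
    B, C = logits_s.shape
    diff = logits_s - logits_t
    return float((diff ** 2).mean()), (2.0 * diff / (B * C)).astype(np.float32)


def finetune_with_kd(
    student: Classifier,
    teacher: Classifier,
    train_records: list[AnnotatedImage],
    valid_records: list[AnnotatedImage],
    cfg: KDConfig,
) -> dict:
    """Train the student on CE + lambda*KD against the frozen teacher.

    Teacher outputs are precomputed once in inference mode.  The history's
    per-epoch ``extra`` entries log the two loss components.
    """
    if student.spec.num_classes != teacher.spec.num_classes:
        raise ValueError("student and teacher class counts differ")
    X, _y = records_to_arrays(train_records)
    t_logits = teacher.forward(X, train=False)
    t_probs = nn.softmax(t_logits)

    def loss_grad(logits, labels, idx):
        ce, dce = nn.cross_entropy(logits, labels)
        if cfg.method == "mse" and cfg.on_logits:
            kd, dkd = _mse_logits_grad(logits, t_logits[idx])
        else:
            kd, dkd = _kd_grad(logits, t_probs[idx], cfg)
        total = ce + cfg.kd_weight * kd
        return total, dce + cfg.kd_weight * dkd, {"ce_loss": ce, "kd_loss": kd}

    return train_classifier(student, train_records, valid_records, cfg.train,
                            loss_grad=loss_grad)
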