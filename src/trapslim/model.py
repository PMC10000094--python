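"""Configurable small convolutional classifier.

The desk-scale stand-in for a full-size backbone: stacked conv-BN-ReLU
stages (optionally with identity residual additions), global average
pooling and a linear head, implemented on the package's numpy engine so
that channel pruning can slice weight tensors directly and attention
methods can read activations and their gradients.

Each classifier carries an exact architecture descriptor
(:mod:`trapslim.archspec`), and its enumerated trainable tensors always
agree with the descriptor's analytic parameter count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .archspec import ArchDescriptor, LayerSpec
from .synthdata import AnnotatedImage

__all__ = [
    "ClassifierSpec",
    "TrainConfig",
    "Classifier",
    "build_classifier",
    "train_classifier",
    "predict",
    "activations_and_gradients",
    "records_to_arrays",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class ClassifierSpec:
    """Backbone shape: one stride-2 conv opens each stage, the rest keep size.

    With ``with_residual`` the size-preserving blocks become identity-skip
    residual units, which ties every conv of a stage into one prune group;
    without it every conv prunes independently.
    """

    stage_widths: tuple[int, ...] = (16, 32, 64)
    blocks_per_stage: tuple[int, ...] = (1, 1, 1)
    num_classes: int = 4
    input_side: int = 96
    with_residual: bool = False

    def __post_init__(self) -> None:
        if len(self.stage_widths) != len(self.blocks_per_stage) or not self.stage_widths:
            raise ValueError("stage_widths and blocks_per_stage must align and be non-empty")
        if any(w < 1 for w in self.stage_widths) or any(b < 1 for b in self.blocks_per_stage):
            raise ValueError("widths and block counts must be positive")
        object.__setattr__(self, "stage_widths", tuple(self.stage_widths))
        object.__setattr__(self, "blocks_per_stage", tuple(self.blocks_per_stage))

    def block_table(self) -> list[tuple[int, int, int, bool, str]]:
        """(cin, cout, stride, residual, prune_group) per conv block."""
        rows = []
        cin = 3
        for s, (w, nb) in enumerate(zip(self.stage_widths, self.blocks_per_stage)):
            for b in range(nb):
                stride = 2 if b == 0 else 1
                residual = self.with_residual and b > 0
                group = f"stage{s}" if self.with_residual else f"stage{s}.block{b}"
                rows.append((cin, w, stride, residual, group))
                cin = w
        return rows

    def to_descriptor(self) -> ArchDescriptor:
        layers: list[LayerSpec] = []
        side = self.input_side
        for i, (cin, cout, stride, residual, group) in enumerate(self.block_table()):
            side = side // stride
            nm = f"block{i}"
            layers.append(LayerSpec(kind="conv", cin=cin, cout=cout, K=3, stride=stride,
                                    H=side, W=side, prune_group=group, name=f"{nm}.conv"))
            layers.append(LayerSpec(kind="bn", cin=cout, cout=cout, H=side, W=side,
                                    prune_group=group, name=f"{nm}.bn"))
            layers.append(LayerSpec(kind="act", cin=cout, cout=cout, H=side, W=side,
                                    name=f"{nm}.relu"))
        c = self.stage_widths[-1]
        layers.append(LayerSpec(kind="pool_global", cin=c, cout=c, K=side, name="avgpool"))
        layers.append(LayerSpec(kind="fc", cin=c, cout=self.num_classes, has_bias=True,
                                name="fc"))
        return ArchDescriptor(layers=tuple(layers),
                              input_size=(self.input_side, self.input_side, 3),
                              num_classes=self.num_classes,
                              name="smallcnn")


class BlockTableSpec:
    """Block-level backbone description: one (cin, cout, stride, residual,
    prune_group) row per conv block.  The general form of
    :class:`ClassifierSpec` — non-uniformly pruned networks, whose widths
    vary within a stage, are only expressible at this level."""

    def __init__(self, rows, num_classes: int, input_side: int,
                 with_residual: bool = False):
        self._rows = [(int(a), int(b), int(s), bool(r), str(g))
                      for a, b, s, r, g in rows]
        self.num_classes = int(num_classes)
        self.input_side = int(input_side)
        self.with_residual = bool(with_residual)
        self.stage_widths = tuple(r[1] for r in self._rows)

    def block_table(self):
        return list(self._rows)

    def to_descriptor(self) -> ArchDescriptor:
        layers = []
        side = self.input_side
        for i, (cin, cout, stride, _res, group) in enumerate(self._rows):
            side //= stride
            layers.append(LayerSpec(kind="conv", cin=cin, cout=cout, K=3,
                                    stride=stride, H=side, W=side,
                                    prune_group=group, name=f"block{i}.conv"))
            layers.append(LayerSpec(kind="bn", cin=cout, cout=cout, H=side, W=side,
                                    prune_group=group, name=f"block{i}.bn"))
            layers.append(LayerSpec(kind="act", cin=cout, cout=cout, H=side, W=side,
                                    name=f"block{i}.relu"))
        c = self._rows[-1][1]
        layers.append(LayerSpec(kind="pool_global", cin=c, cout=c, K=side,
                                name="avgpool"))
        layers.append(LayerSpec(kind="fc", cin=c, cout=self.num_classes,
                                has_bias=True, name="fc"))
        return ArchDescriptor(layers=tuple(layers),
                              input_size=(self.input_side, self.input_side, 3),
                              num_classes=self.num_classes, name="smallcnn")

    def __eq__(self, other) -> bool:
        try:
            return (self.block_table() == other.block_table()
                    and self.num_classes == other.num_classes
                    and self.input_side == other.input_side)
        except AttributeError:
            return NotImplemented

    def __repr__(self) -> str:
        return (f"BlockTableSpec(rows={self._rows!r}, "
                f"num_classes={self.num_classes}, input_side={self.input_side})")


@dataclass
class TrainConfig:
    """Optimization settings; defaults mirror the published full-scale runs
    (SGD, momentum 0.9, initial lr 1e-4, cosine decay, batch 64, early stop
    with patience 50).  Desk-scale experiments override lr/batch/epochs."""

    optimizer: str = "sgd"
    momentum: float = 0.9
    initial_lr: float = 1e-4
    batch_size: int = 64
    early_stop_patience: int = 50
    max_epochs: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.initial_lr <= 0 or self.momentum < 0 or self.batch_size < 1:
            raise ValueError("rates must be positive")
        if self.early_stop_patience < 1 or self.max_epochs < 1:
            raise ValueError("patience and max_epochs must be >= 1")
        if self.optimizer != "sgd":
            raise ValueError("only sgd is supported")


class _Block:
    """conv -> BN -> ReLU, optionally with an identity residual skip."""

    def __init__(self, cin: int, cout: int, stride: int, residual: bool,
                 group: str, rng: np.random.Generator):
        if residual and (cin != cout or stride != 1):
            raise ValueError("identity residual requires cin == cout and stride 1")
        self.conv = nn.Conv2d(cin, cout, K=3, stride=stride, rng=rng)
        self.bn = nn.BatchNorm2d(cout)
        self.relu = nn.ReLU()
        self.residual = residual
        self.group = group

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        y = self.bn.forward(self.conv.forward(x, train), train)
        if self.residual:
            y = y + x
        return self.relu.forward(y, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.relu.backward(dy)
        dx = self.conv.backward(self.bn.backward(dy))
        if self.residual:
            dx = dx + dy
        return dx


class Classifier:
    """Trainable small CNN bound to a :class:`ClassifierSpec`."""

    def __init__(self, spec: ClassifierSpec, rng: np.random.Generator):
        self.spec = spec
        self.blocks = [_Block(cin, cout, stride, residual, group, rng)
                       for cin, cout, stride, residual, group in spec.block_table()]
        self.gap = nn.GlobalAvgPool()
        self.fc = nn.Linear(spec.stage_widths[-1], spec.num_classes, rng=rng)
        self.last_features: np.ndarray | None = None

    # -- plumbing ----------------------------------------------------------
    def layers(self):
        for b in self.blocks:
            yield b.conv
            yield b.bn
        yield self.fc

    def parameters(self) -> list[np.ndarray]:
        out = []
        for lay in self.layers():
            out.extend(lay.params().values())
        return out

    def gradients(self) -> list[np.ndarray]:
        out = []
        for lay in self.layers():
            out.extend(lay.grads().values())
        return out

    def num_params(self) -> int:
        return sum(int(p.size) for p in self.parameters())

    def descriptor(self) -> ArchDescriptor:
        return self.spec.to_descriptor()

    # -- forward/backward --------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for b in self.blocks:
            x = b.forward(x, train)
        self.last_features = x
        return self.fc.forward(self.gap.forward(x, train), train)

    def backward(self, dlogits: np.ndarray, to_features: bool = False) -> np.ndarray:
        """Propagate a logit gradient; with ``to_features`` stop at (and
        return) the gradient of the last block's activation map."""
        dx = self.gap.backward(self.fc.backward(dlogits))
        if to_features:
            return dx
        for b in reversed(self.blocks):
            dx = b.backward(dx)
        return dx


def build_classifier(spec: ClassifierSpec, rng: np.random.Generator | int) -> Classifier:
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    return Classifier(spec, rng)


def records_to_arrays(records: list[AnnotatedImage]) -> tuple[np.ndarray, np.ndarray]:
    """Stack a manifest into (X, y); pixels are scaled to [-1, 1] floats."""
    X = np.stack([r.pixels for r in records]).astype(np.float32)
    X = (X / 255.0 - 0.5) / 0.5
    X = X.transpose(0, 3, 1, 2)
    y = np.array([r.label for r in records], dtype=np.int64)
    return X, y


def _sgd_step(model: Classifier, velocity: list[np.ndarray], lr: float,
              momentum: float) -> None:
    for p, g, v in zip(model.parameters(), model.gradients(), velocity):
        v *= momentum
        v += g
        p -= lr * v


def cosine_lr(initial_lr: float, epoch: int, max_epochs: int) -> float:
    return initial_lr * 0.5 * (1.0 + np.cos(np.pi * epoch / max_epochs))


def train_classifier(
    model: Classifier,
    train_records: list[AnnotatedImage],
    valid_records: list[AnnotatedImage],
    cfg: TrainConfig,
    loss_grad=None,
) -> dict:
    """SGD + cosine decay + early stopping on validation accuracy.

    ``loss_grad(logits, labels) -> (loss, dlogits, extra)`` may replace the
    default cross-entropy (the distillation stage passes a composite); the
    best-validation weights are restored on exit.  Returns the history dict.
    """
    if not train_records or not valid_records:
        raise ValueError("manifests must be non-empty")
    X, y = records_to_arrays(train_records)
    Xv, yv = records_to_arrays(valid_records)
    rng = np.random.default_rng(cfg.seed)
    velocity = [np.zeros_like(p) for p in model.parameters()]
    history: dict = {"epoch": [], "train_loss": [], "train_acc": [], "val_acc": [],
                     "lr": [], "extra": []}
    best_acc, best_state, since_best = -1.0, None, 0

    def snapshot():
        return [p.copy() for p in model.parameters()] + [
            (b.bn.running_mean.copy(), b.bn.running_var.copy()) for b in model.blocks]

    def restore(state):
        ps = model.parameters()
        for p, s in zip(ps, state[:len(ps)]):
            p[...] = s
        for b, (m, v) in zip(model.blocks, state[len(ps):]):
            b.bn.running_mean, b.bn.running_var = m.copy(), v.copy()

    for epoch in range(cfg.max_epochs):
        lr = cosine_lr(cfg.initial_lr, epoch, cfg.max_epochs)
        order = rng.permutation(len(X))
        losses, correct, extras = [], 0, []
        for start in range(0, len(X), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            logits = model.forward(X[idx], train=True)
            if loss_grad is None:
                loss, dlogits = nn.cross_entropy(logits, y[idx])
                extra = {}
            else:
                loss, dlogits, extra = loss_grad(logits, y[idx], idx)
            model.backward(dlogits)
            _sgd_step(model, velocity, lr, cfg.momentum)
            losses.append(loss)
            correct += int((logits.argmax(axis=1) == y[idx]).sum())
            extras.append(extra)
        val_pred = predict(model, Xv)[0]
        val_acc = float((val_pred == yv).mean())
        history["epoch"].append(epoch)
        history["train_loss"].append(float(np.mean(losses)))
        history["train_acc"].append(correct / len(X))
        history["val_acc"].append(val_acc)
        history["lr"].append(lr)
        history["extra"].append(extras[-1] if extras else {})
        if val_acc > best_acc:
            best_acc, best_state, since_best = val_acc, snapshot(), 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                break
    if best_state is not None:
        restore(best_state)
    history["best_val_acc"] = best_acc
    return history


def predict(model: Classifier, images: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(labels, probabilities, logits); argmax ties break to the lowest index."""
    if images.ndim == 3:
        images = images[None]
    side = model.spec.input_side
    if images.shape[2] != side or images.shape[3] != side:
        raise ValueError(f"expected {side}x{side} inputs, got {images.shape[2:]}")
    logits = model.forward(images, train=False)
    probs = nn.softmax(logits)
    return logits.argmax(axis=1), probs, logits


def activations_and_gradients(
    model: Classifier, image: np.ndarray, class_index: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Last conv stage's activations A and d(logit_c)/dA for one image."""
    if not 0 <= class_index < model.spec.num_classes:
        raise ValueError(f"class_index {class_index} out of range")
    x = image[None] if image.ndim == 3 else image
    model.forward(x, train=True)
    A = model.last_features[0].copy()
    onehot = np.zeros((1, model.spec.num_classes), dtype=np.float32)
    onehot[0, class_index] = 1.0
    dA = model.backward(onehot, to_features=True)[0]
    return A, dA


def save_model(model: Classifier, path) -> None:
    """Checkpoint weights plus the block table (covers pruned students)."""
    arrays = {}
    for i, b in enumerate(model.blocks):
        arrays[f"b{i}.W"] = b.conv.W
        arrays[f"b{i}.gamma"] = b.bn.gamma
        arrays[f"b{i}.beta"] = b.bn.beta
        arrays[f"b{i}.rmean"] = b.bn.running_mean
        arrays[f"b{i}.rvar"] = b.bn.running_var
    arrays["fc.W"] = model.fc.W
    arrays["fc.b"] = model.fc.b
    spec = model.spec
    rows = spec.block_table()
    arrays["block_meta"] = np.array(
        [[cin, cout, stride, int(res)] for cin, cout, stride, res, _g in rows],
        dtype=np.int64)
    arrays["block_groups"] = np.array([g for *_, g in rows])
    arrays["head"] = np.array([spec.num_classes, spec.input_side,
                               int(spec.with_residual)], dtype=np.int64)
    np.savez(path, **arrays)


def load_model(path) -> Classifier:
    data = np.load(path)
    meta = data["block_meta"]
    groups = [str(g) for g in data["block_groups"]]
    num_classes, input_side, with_residual = (int(v) for v in data["head"])
    rows = [(int(m[0]), int(m[1]), int(m[2]), bool(m[3]), g)
            for m, g in zip(meta, groups)]
    spec = BlockTableSpec(rows, num_classes, input_side, bool(with_residual))
    model = Classifier(spec, np.random.default_rng(0))
    for i, b in enumerate(model.blocks):
        b.conv.W = data[f"b{i}.W"]
        b.bn.gamma = data[f"b{i}.gamma"]
        b.bn.beta = data[f"b{i}.beta"]
        b.bn.running_mean = data[f"b{i}.rmean"]
        b.bn.running_var = data[f"b{i}.rvar"]
    model.fc.W = data["fc.W"]
    model.fc.b = data["fc.b"]
    return model
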