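"""Architecture descriptors and exact cost accounting.

A network is described as an ordered table of layer specs carrying channel
counts, kernel size and output spatial size.  Parameter and multiply-
accumulate (MAC) counts are computed layer-by-layer with integer arithmetic:

* conv:   ``params = cout * K^2 * cin (+ cout if biased)``,
          ``macs = H * W * cout * (K^2 * cin + 1)``
* fc:     ``params = cin * cout + cout``, ``macs = cin * cout + cout``
* bn:     ``params = 2 * cout`` (scale, shift), one op per output element
* act:    one op per output element
* pool:   ``K^2`` ops per output element (spatial), one op per input
          element (global)

The conv MAC rule is the per-layer ``(cin * K^2 + 1) * cout`` accounting per
output position; the ``+1`` accumulator slot is charged for every conv, biased
or not.  A doubled ``flops = 2 * macs`` field is exposed for the reading of
the same accounting in floating-point operations.

The descriptor's channel-group ids (``prune_group``) tie together layers
whose widths must shrink jointly under structured channel pruning, e.g. the
convolutions feeding a residual sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

__all__ = [
    "LayerSpec",
    "ArchDescriptor",
    "CostReport",
    "resnet50_descriptor",
    "count_params",
    "count_macs",
    "apply_genome",
    "mac_ratio",
    "pruned_width",
]

_KINDS = {"conv", "fc", "bn", "act", "pool_global", "pool_spatial"}


@dataclass(frozen=True)
class LayerSpec:
    """One row of the architecture table.

    ``src`` is the index of the layer whose output feeds this one; ``None``
    means the immediately preceding row (or the network input for row 0).
    ``prune_group`` links layers whose output-channel counts must stay equal
    under channel pruning; ``None`` marks an unprunable layer (e.g. the
    classification head).
    """

    kind: str
    cin: int
    cout: int
    K: int = 1
    stride: int = 1
    H: int = 1
    W: int = 1
    has_bias: bool = False
    prune_group: str | None = None
    name: str = ""
    src: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")
        for f in ("cin", "cout", "K", "stride", "H", "W"):
            v = getattr(self, f)
            if not isinstance(v, int) or v < 1:
                raise ValueError(f"{f} must be a positive integer, got {v!r}")


@dataclass(frozen=True)
class ArchDescriptor:
    layers: tuple[LayerSpec, ...]
    input_size: tuple[int, int, int]  # (height, width, channels)
    num_classes: int
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))
        self.validate()

    def validate(self) -> None:
        if not self.layers:
            raise ValueError("descriptor has no layers")
        last = self.layers[-1]
        if last.kind != "fc" or last.cout != self.num_classes:
            raise ValueError("last layer must be an fc head of size num_classes")
        for i, lay in enumerate(self.layers):
            feed_cout = self._feeder_cout(i)
            if lay.cin != feed_cout:
                raise ValueError(
                    f"layer {i} ({lay.name or lay.kind}): cin={lay.cin} does not "
                    f"match feeding width {feed_cout}"
                )
            if lay.kind in ("bn", "act", "pool_global", "pool_spatial") and lay.cout != lay.cin:
                raise ValueError(f"layer {i}: {lay.kind} must preserve channel count")

    def _feeder_cout(self, i: int) -> int:
        src = self.layers[i].src
        if src is None:
            return self.input_size[2] if i == 0 else self.layers[i - 1].cout
        if not 0 <= src < i:
            raise ValueError(f"layer {i}: src index {src} out of range")
        return self.layers[src].cout

    @property
    def prune_groups(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for lay in self.layers:
            if lay.prune_group is not None:
                seen.setdefault(lay.prune_group, None)
        return tuple(seen)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "input_size": list(self.input_size),
            "num_classes": self.num_classes,
            "layers": [
                {
                    "kind": l.kind, "cin": l.cin, "cout": l.cout, "K": l.K,
                    "stride": l.stride, "H": l.H, "W": l.W,
                    "has_bias": l.has_bias, "prune_group": l.prune_group,
                    "name": l.name, "src": l.src,
                }
                for l in self.layers
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ArchDescriptor":
        return cls(
            layers=tuple(LayerSpec(**row) for row in d["layers"]),
            input_size=tuple(d["input_size"]),
            num_classes=int(d["num_classes"]),
            name=d.get("name", ""),
        )


@dataclass(frozen=True)
class CostReport:
    params_total: int
    macs_total: int
    per_layer: tuple[tuple[str, int, int], ...]  # (layer name, params, macs)

    @property
    def flops_total(self) -> int:
        """Doubled count: one multiply + one add per MAC."""
        return 2 * self.macs_total

    def __post_init__(self) -> None:
        if self.params_total != sum(p for _, p, _ in self.per_layer):
            raise ValueError("params_total does not equal per-layer sum")
        if self.macs_total != sum(m for _, _, m in self.per_layer):
            raise ValueError("macs_total does not equal per-layer sum")


def _layer_params(lay: LayerSpec) -> int:
    if lay.kind == "conv":
        return lay.cout * lay.K * lay.K * lay.cin + (lay.cout if lay.has_bias else 0)
    if lay.kind == "fc":
        return lay.cin * lay.cout + (lay.cout if lay.has_bias else 0)
    if lay.kind == "bn":
        return 2 * lay.cout
    return 0


def _layer_macs(lay: LayerSpec) -> int:
    if lay.kind == "conv":
        return lay.H * lay.W * lay.cout * (lay.K * lay.K * lay.cin + 1)
    if lay.kind == "fc":
        return lay.cin * lay.cout + (lay.cout if lay.has_bias else 0)
    if lay.kind in ("bn", "act"):
        return lay.H * lay.W * lay.cout
    if lay.kind == "pool_spatial":
        return lay.H * lay.W * lay.cout * lay.K * lay.K
    if lay.kind == "pool_global":
        # one op per pooled input element: input spatial size = H*W of feeder,
        # recorded on the pool row as K (kernel side covering the full map)
        return lay.K * lay.K * lay.cout
    raise AssertionError(lay.kind)


def count_params(arch: ArchDescriptor) -> CostReport:
    """Exact trainable-parameter count, layer by layer."""
    rows = [(l.name or f"{l.kind}{i}", _layer_params(l), 0) for i, l in enumerate(arch.layers)]
    return CostReport(
        params_total=sum(p for _, p, _ in rows),
        macs_total=0,
        per_layer=tuple(rows),
    )


def count_macs(arch: ArchDescriptor) -> CostReport:
    """Exact multiply-accumulate count under the documented convention."""
    rows = [
        (l.name or f"{l.kind}{i}", _layer_params(l), _layer_macs(l))
        for i, l in enumerate(arch.layers)
    ]
    return CostReport(
        params_total=sum(p for _, p, _ in rows),
        macs_total=sum(m for _, _, m in rows),
        per_layer=tuple(rows),
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def pruned_width(cout: int, ratio: float) -> int:
    """Channel count kept when a width ``cout`` is pruned at ``ratio``."""
    return max(1, _round_half_up(ratio * cout))


def apply_genome(arch: ArchDescriptor, genome: Mapping[str, float]) -> ArchDescriptor:
    """Rewrite the descriptor with per-group channel keep-ratios applied.

    Every layer in prune-group ``g`` has its output width replaced by
    ``max(1, round(ratio_g * cout))``; downstream input widths follow through
    the connectivity, and the fc head keeps its class count.
    """
    missing = set(arch.prune_groups) - set(genome)
    if missing:
        raise ValueError(f"genome missing prune groups: {sorted(missing)}")
    for g, r in genome.items():
        if not (0.0 < r <= 1.0):
            raise ValueError(f"keep ratio for group {g!r} must be in (0, 1], got {r}")

    new_cout: list[int] = []
    new_layers: list[LayerSpec] = []
    for i, lay in enumerate(arch.layers):
        src = lay.src
        if src is None:
            cin = arch.input_size[2] if i == 0 else new_cout[i - 1]
        else:
            cin = new_cout[src]
        if lay.kind in ("conv", "fc") and lay.prune_group is not None:
            cout = pruned_width(lay.cout, genome[lay.prune_group])
        elif lay.kind in ("bn", "act", "pool_global", "pool_spatial"):
            cout = cin
        else:
            cout = lay.cout  # unprunable conv/fc (e.g. the class head)
        new_layers.append(replace(lay, cin=cin, cout=cout))
        new_cout.append(cout)
    return ArchDescriptor(
        layers=tuple(new_layers),
        input_size=arch.input_size,
        num_classes=arch.num_classes,
        name=arch.name + "+pruned" if arch.name else "pruned",
    )


def mac_ratio(arch: ArchDescriptor, genome: Mapping[str, float]) -> float:
    """MAC count of the pruned descriptor relative to the unpruned one."""
    return count_macs(apply_genome(arch, genome)).macs_total / count_macs(arch).macs_total


_RESNET50_STAGES = ((256, 3, 1), (512, 4, 2), (1024, 6, 2), (2048, 3, 2))


def resnet50_descriptor(num_classes: int, input_side: int) -> ArchDescriptor:
    """Layer table of the standard ResNet50 bottleneck classifier.

    Stem conv 7x7/64 (stride 2), 3x3/2 max pool, four stages of [3, 4, 6, 3]
    bottleneck blocks with output widths 256/512/1024/2048, BN after every
    conv, global average pool and a ``2048 -> num_classes`` fc head.  The two
    1x1/3x3 convs inside each bottleneck carry their own prune groups; the
    block-output convs and downsample convs of a stage share the stage's
    residual group so pruned tensors stay shape-compatible across the
    residual sums.
    """
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    if input_side % 32 != 0:
        raise ValueError(f"input_side must be divisible by 32, got {input_side}")

    L: list[LayerSpec] = []

    def add(**kw) -> int:
        L.append(LayerSpec(**kw))
        return len(L) - 1

    s = input_side // 2
    add(kind="conv", cin=3, cout=64, K=7, stride=2, H=s, W=s, prune_group="stem", name="conv1")
    add(kind="bn", cin=64, cout=64, H=s, W=s, prune_group="stem", name="bn1")
    add(kind="act", cin=64, cout=64, H=s, W=s, name="relu1")
    s //= 2
    add(kind="pool_spatial", cin=64, cout=64, K=3, stride=2, H=s, W=s, name="maxpool")

    cin = 64
    block_in = len(L) - 1  # index of the layer feeding the current block
    for si, (C, n_blocks, first_stride) in enumerate(_RESNET50_STAGES, start=1):
        mid = C // 4
        res_group = f"stage{si}.res"
        for b in range(1, n_blocks + 1):
            stride = first_stride if b == 1 else 1
            out = s // stride
            pre = f"stage{si}.block{b}"
            g1, g2 = f"{pre}.conv1", f"{pre}.conv2"
            add(kind="conv", cin=cin, cout=mid, K=1, H=s, W=s,
                prune_group=g1, name=f"{pre}.conv1", src=block_in)
            add(kind="bn", cin=mid, cout=mid, H=s, W=s, prune_group=g1, name=f"{pre}.bn1")
            add(kind="act", cin=mid, cout=mid, H=s, W=s, name=f"{pre}.relu1")
            add(kind="conv", cin=mid, cout=mid, K=3, stride=stride, H=out, W=out,
                prune_group=g2, name=f"{pre}.conv2")
            add(kind="bn", cin=mid, cout=mid, H=out, W=out, prune_group=g2, name=f"{pre}.bn2")
            add(kind="act", cin=mid, cout=mid, H=out, W=out, name=f"{pre}.relu2")
            add(kind="conv", cin=mid, cout=C, K=1, H=out, W=out,
                prune_group=res_group, name=f"{pre}.conv3")
            i3 = add(kind="bn", cin=C, cout=C, H=out, W=out, prune_group=res_group,
                     name=f"{pre}.bn3")
            if b == 1:
                add(kind="conv", cin=cin, cout=C, K=1, stride=stride, H=out, W=out,
                    prune_group=res_group, name=f"{pre}.downsample", src=block_in)
                add(kind="bn", cin=C, cout=C, H=out, W=out, prune_group=res_group,
                    name=f"{pre}.downsample_bn")
            block_in = add(kind="act", cin=C, cout=C, H=out, W=out,
                           name=f"{pre}.relu3", src=i3)
            cin = C
            s = out
    add(kind="pool_global", cin=cin, cout=cin, K=s, H=1, W=1, name="avgpool")
    add(kind="fc", cin=cin, cout=num_classes, has_bias=True, name="fc")
    return ArchDescriptor(
        layers=tuple(L),
        input_size=(input_side, input_side, 3),
        num_classes=num_classes,
        name="resnet50",
    )
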