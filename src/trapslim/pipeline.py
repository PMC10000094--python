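"""End-to-end experiment orchestration at desk scale.

Reproduces the shape of the full-scale studies on synthetic confounded
data: the augmentation comparison (baseline / repeat sampling / cutout /
RBS / IS / mixed, scored by decorrelated-test accuracy and FRoH) and the
compression comparison (genetic vs random band-constrained search, each
followed by optional distillation fine-tuning).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .archspec import count_macs, count_params
from .augment import RBSParams, apply_cutout, build_augmented_set
from .distill import KDConfig, finetune_with_kd
from .metrics import acc_cls, dataset_froh
from .model import (ClassifierSpec, TrainConfig, build_classifier, predict,
                    records_to_arrays, train_classifier)
from .prune import SearchConfig, ga_search, materialize_student, random_search, recalibrate_bn
from .synthdata import SceneConfig, generate_dataset

__all__ = [
    "ExperimentConfig",
    "desk_train_config",
    "published_train_config",
    "run_augmentation_study",
    "shortcut_study",
    "run_compression_study",
    "shortcut_benchmark_config",
    "compression_benchmark_config",
]

AUG_METHODS = ("baseline", "repeat_sampling", "cutout", "rbs", "is", "mixed")


def desk_train_config(**overrides) -> TrainConfig:
    """Optimization settings sized for the small CNN on synthetic scenes."""
    base = dict(initial_lr=0.05, batch_size=16, max_epochs=45,
                early_stop_patience=25, seed=0)
    base.update(overrides)
    return TrainConfig(**base)


def published_train_config(**overrides) -> TrainConfig:
    """The published full-scale settings (for users with the hardware)."""
    base = dict(initial_lr=1e-4, batch_size=64, max_epochs=500,
                early_stop_patience=50, seed=0)
    base.update(overrides)
    return TrainConfig(**base)


def shortcut_benchmark_config(seed: int) -> "ExperimentConfig":
    """Canonical conditions for the shortcut-learning study: 4 species at 4
    fully-confounded sites, 96x96 scenes, low-contrast foregrounds, the
    desk training schedule, and a half-and-half IS/RBS mix."""
    return ExperimentConfig(seed=seed)


def compression_benchmark_config(seed: int) -> "ExperimentConfig":
    """Canonical conditions for the compression study: an unconfounded
    6-species scene (compression is orthogonal to the background shortcut,
    so the teacher should generalize), a 6-block teacher whose per-block
    prune groups span a genome space far larger than the search budget,
    and the 12-parent / 36-offspring search preset."""
    from .prune import desk_search_config

    return ExperimentConfig(
        scene=SceneConfig(n_sites=6, n_species=6, image_side=48,
                          confound_strength=0.0, instances_per_class=(28, 24),
                          seed=seed),
        model=ClassifierSpec(stage_widths=(12, 24, 48), blocks_per_stage=(2, 2, 2),
                             num_classes=6, input_side=48),
        train=desk_train_config(max_epochs=60),
        search=desk_search_config(max_generations=8),
        seed=seed)


@dataclass
class ExperimentConfig:
    scene: SceneConfig = field(default_factory=SceneConfig)
    model: ClassifierSpec = field(default_factory=ClassifierSpec)
    train: TrainConfig = field(default_factory=desk_train_config)
    search: SearchConfig = field(default_factory=SearchConfig)
    kd: KDConfig | None = None
    is_fraction: float = 0.5
    rbs_fraction: float = 0.5
    out_dir: str | None = None
    seed: int = 0


def _spawn(seed: int, k: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(k,)))


def _train_and_score(cfg: ExperimentConfig, train_records, test_records,
                     seed_offset: int, froh_on: list | None = None):
    spec = dataclasses.replace(cfg.model, num_classes=cfg.scene.n_species,
                               input_side=cfg.scene.image_side)
    model = build_classifier(spec, _spawn(cfg.seed, 100 + seed_offset))
    tcfg = dataclasses.replace(cfg.train, seed=cfg.seed + seed_offset)
    history = train_classifier(model, train_records, test_records, tcfg)
    Xt, yt = records_to_arrays(test_records)
    test_acc = acc_cls(predict(model, Xt)[0], yt)
    froh_val = float("nan")
    if froh_on is not None:
        froh_val, _ = dataset_froh(model, froh_on)
    return model, history, test_acc, froh_val


def _aug_variant(method: str, train, cutouts, backgrounds, rng,
                 is_fraction: float, rbs_fraction: float):
    f = is_fraction + rbs_fraction
    n_extra = int(round(f * len(train)))
    if method == "baseline":
        return list(train)
    if method == "repeat_sampling":
        picks = rng.integers(0, len(train), size=n_extra)
        return list(train) + [train[i] for i in picks]
    if method == "cutout":
        picks = rng.integers(0, len(train), size=n_extra)
        return list(train) + [apply_cutout(train[i], rng) for i in picks]
    if method == "rbs":
        return build_augmented_set(train, cutouts, backgrounds, rng,
                                   is_fraction=0.0, rbs_fraction=f)
    if method == "is":
        return build_augmented_set(train, cutouts, backgrounds, rng,
                                   is_fraction=f, rbs_fraction=0.0)
    if method == "mixed":
        return build_augmented_set(train, cutouts, backgrounds, rng,
                                   is_fraction=is_fraction, rbs_fraction=rbs_fraction)
    raise ValueError(f"unknown augmentation method {method!r}")


def run_augmentation_study(cfg: ExperimentConfig,
                           methods: tuple[str, ...] = AUG_METHODS,
                           froh: bool = True) -> pd.DataFrame:
    """Train one model per augmentation variant on the same confounded
    scene; report decorrelated-test accuracy and (optionally) mean FRoH."""
    scene = dataclasses.replace(cfg.scene, seed=cfg.seed)
    train, test, cutouts, backgrounds = generate_dataset(scene)
    rows = []
    for k, method in enumerate(methods):
        rng = _spawn(cfg.seed, 200 + k)
        variant = _aug_variant(method, train, cutouts, backgrounds, rng,
                               cfg.is_fraction, cfg.rbs_fraction)
        _model, history, test_acc, froh_val = _train_and_score(
            cfg, variant, test, seed_offset=k, froh_on=test if froh else None)
        rows.append({"method": method, "n_train": len(variant),
                     "acc_cls": test_acc, "froh": froh_val,
                     "train_acc": history["train_acc"][-1]})
    table = pd.DataFrame(rows)
    _maybe_write(cfg, table, "augmentation_study.csv")
    return table


def shortcut_study(cfg: ExperimentConfig) -> dict:
    """The two-arm version of the augmentation study (baseline vs mixed),
    returning the quantities the shortcut-learning claim is about."""
    scene = dataclasses.replace(cfg.scene, seed=cfg.seed)
    train, test, cutouts, backgrounds = generate_dataset(scene)
    out = {}
    for k, method in enumerate(("baseline", "mixed")):
        rng = _spawn(cfg.seed, 200 + k)
        variant = _aug_variant(method, train, cutouts, backgrounds, rng,
                               cfg.is_fraction, cfg.rbs_fraction)
        model, history, test_acc, froh_val = _train_and_score(
            cfg, variant, test, seed_offset=k, froh_on=test)
        out[f"{method}_train_acc"] = history["train_acc"][-1]
        out[f"{method}_test_acc"] = test_acc
        out[f"{method}_froh"] = froh_val
    return out


def run_compression_study(
    cfg: ExperimentConfig,
    teacher=None,
    finetune: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genetic vs equal-budget random band-constrained search.

    Returns the comparison table (method, accuracy, params, macs, and the
    fine-tuned accuracy when distillation is enabled) and the per-generation
    fitness history of the genetic search.
    """
    scene = dataclasses.replace(cfg.scene, seed=cfg.seed)
    train, test, _cutouts, _backgrounds = generate_dataset(scene)
    if teacher is None:
        teacher, _, _, _ = _train_and_score(cfg, train, test, seed_offset=0)
    arch = teacher.descriptor()
    Xt, yt = records_to_arrays(test)
    teacher_acc = acc_cls(predict(teacher, Xt)[0], yt)

    scfg = dataclasses.replace(cfg.search, seed=cfg.seed, p0=teacher.num_params())
    best_ga, history = ga_search(teacher, arch, train, test, scfg)
    budget = scfg.population_size * len(history)
    best_rand, _ = random_search(teacher, arch, train, test, scfg, budget=budget)

    rows = [{"method": "teacher", "accuracy": teacher_acc,
             "params": teacher.num_params(),
             "macs": count_macs(arch).macs_total, "accuracy_finetuned": float("nan")}]
    for name, best in (("ga_abn", best_ga), ("random_sampling", best_rand)):
        student = materialize_student(teacher, best.genome)
        recalibrate_bn(student, train, scfg.recal_batches,
                       _spawn(cfg.seed, 300), batch_size=scfg.recal_batch_size)
        ft_acc = float("nan")
        if finetune and cfg.kd is not None:
            finetune_with_kd(student, teacher, train, test, cfg.kd)
            ft_acc = acc_cls(predict(student, Xt)[0], yt)
        rows.append({"method": name, "accuracy": best.n, "params": best.p,
                     "macs": best.macs, "accuracy_finetuned": ft_acc})
    table = pd.DataFrame(rows)
    _maybe_write(cfg, table, "compression_study.csv")
    _maybe_write(cfg, history, "ga_history.csv")
    return table, history


def _maybe_write(cfg: ExperimentConfig, table: pd.DataFrame, name: str) -> None:
    if cfg.out_dir is None:
        return
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / name
    table.to_csv(path, index=False)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    with (out / "artifacts.jsonl").open("a") as fh:
        fh.write(json.dumps({"file": name, "sha256": digest,
                             "seed": cfg.seed, "time": time.time()}) + "\n")
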