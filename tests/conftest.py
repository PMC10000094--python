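"""Shared fixtures.

The three stochastic studies (shortcut mitigation, compression search,
distillation fine-tuning) are expensive, so they run once per session over
the fixed seed set {1, 2, 3} and multiple tests read the cached results.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from trapslim.distill import KDConfig, finetune_with_kd
from trapslim.metrics import acc_cls
from trapslim.model import predict, records_to_arrays
from trapslim.pipeline import (compression_benchmark_config,
                               desk_train_config, shortcut_benchmark_config,
                               shortcut_study, _spawn, _train_and_score)
from trapslim.prune import ga_search, materialize_student, random_search, recalibrate_bn
from trapslim.synthdata import generate_dataset

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")

SEEDS = (1, 2, 3)


@pytest.fixture(scope="session")
def shortcut_runs():
    """Baseline-vs-mixed augmentation outcomes on the confounded scene."""
    return [shortcut_study(shortcut_benchmark_config(s)) for s in SEEDS]


@pytest.fixture(scope="session")
def compression_runs():
    """Per-seed teacher + genetic and random search results."""
    out = []
    for seed in SEEDS:
        cfg = compression_benchmark_config(seed)
        scene = dataclasses.replace(cfg.scene, seed=seed)
        train, test, _cuts, _bgs = generate_dataset(scene)
        teacher, _hist, teacher_acc, _ = _train_and_score(cfg, train, test, 0)
        scfg = dataclasses.replace(cfg.search, seed=seed, p0=teacher.num_params())
        best_ga, history = ga_search(teacher, teacher.descriptor(), train, test, scfg)
        budget = scfg.population_size * len(history)
        best_rand, _ = random_search(teacher, teacher.descriptor(), train, test,
                                     scfg, budget=budget)
        out.append({"seed": seed, "cfg": cfg, "scfg": scfg, "train": train,
                    "test": test, "teacher": teacher, "teacher_acc": teacher_acc,
                    "ga": best_ga, "ga_history": history, "random": best_rand})
    return out


@pytest.fixture(scope="session")
def kd_runs(compression_runs):
    """Validation accuracy of the best pruned student before fine-tuning and
    after each distillation variant, per seed."""
    out = []
    for run in compression_runs:
        seed, cfg, scfg = run["seed"], run["cfg"], run["scfg"]
        train, test, teacher = run["train"], run["test"], run["teacher"]
        Xt, yt = records_to_arrays(test)
        accs = {}
        for method in ("none", "mse", "soft_kl", "hard_kl"):
            student = materialize_student(teacher, run["ga"].genome)
            recalibrate_bn(student, train, scfg.recal_batches, _spawn(seed, 51),
                           batch_size=scfg.recal_batch_size)
            if method != "none":
                kd = KDConfig(method=method,
                              train=desk_train_config(max_epochs=20, seed=seed))
                finetune_with_kd(student, teacher, train, test, kd)
            accs[method] = acc_cls(predict(student, Xt)[0], yt)
        out.append({"seed": seed, **accs})
    return out
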