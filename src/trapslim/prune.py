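"""Structured channel pruning by genetic search with adaptive BN.

A candidate sub-network is a *genome*: one channel keep-ratio per prune
group, drawn from the grid {0.1, 0.2, ..., 1.0}, constrained so that the
sub-network's MAC count falls inside a compression band (e.g. 50 +/- 5% of
the parent).  Evaluating a genome is cheap: slice the teacher's weights
(keeping the channels with the largest filter L1 norms), refresh every BN
layer's inference statistics on a few calibration batches (mean and
unbiased, N-1, variance — "adaptive BN"), and measure validation accuracy.
No gradient step is taken during the search.

Fitness follows the published formula ``f_j = n_j * p_j / p_0`` (validation
accuracy times the parameter ratio) under ``fitness_form='literal_product'``;
as printed it rewards larger sub-networks, so the compression-oriented
reading ``n_j / (p_j / p_0)`` is available as ``'accuracy_per_size'``.  The
search keeps the best ``parents_kept`` individuals, breeds
``population_size`` offspring by uniform crossover plus per-gene mutation,
and stops when the population's total fitness stalls.
"""

from __future__ import annotations

import copy
import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import archspec
from .archspec import ArchDescriptor, apply_genome, count_macs, count_params, pruned_width
from .model import Classifier, predict, records_to_arrays
from .synthdata import AnnotatedImage

__all__ = [
    "RATIO_GRID",
    "Individual",
    "SearchConfig",
    "sample_genome",
    "materialize_student",
    "recalibrate_bn",
    "evaluate_fitness",
    "evolve_generation",
    "ga_search",
    "random_search",
]

log = logging.getLogger(__name__)

RATIO_GRID: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(1, 11))

PruneGenome = dict[str, float]


@dataclass
class Individual:
    genome: PruneGenome
    n: float = float("nan")  # validation accuracy
    p: int = 0  # parameter count
    macs: int = 0
    f: float = float("nan")  # fitness


@dataclass
class SearchConfig:
    """Search settings; the published preset keeps 20 parents and breeds 100
    offspring per generation, desk-scale runs use 12/36."""

    compression_target: float = 0.5
    band_halfwidth: float = 0.05
    population_size: int = 100
    parents_kept: int = 20
    mutation_rate: float = 0.1
    recal_batches: int = 30
    recal_batch_size: int = 16
    fitness_form: str = "literal_product"
    convergence_tol: float = 1e-3
    convergence_patience: int = 3
    max_generations: int = 30
    p0: int = 0
    seed: int = 0
    sample_retries: int = 2000

    def __post_init__(self) -> None:
        lo = self.compression_target - self.band_halfwidth
        if not (0.0 < lo and self.compression_target <= 1.0):
            raise ValueError("compression band must lie inside (0, 1]")
        if self.parents_kept >= self.population_size:
            raise ValueError("parents_kept must be smaller than population_size")
        if self.fitness_form not in ("literal_product", "accuracy_per_size"):
            raise ValueError(f"unknown fitness_form {self.fitness_form!r}")


def desk_search_config(**overrides) -> SearchConfig:
    base = dict(population_size=36, parents_kept=12, recal_batches=4,
                max_generations=10)
    base.update(overrides)
    return SearchConfig(**base)


def _in_band(ratio: float, cfg: SearchConfig) -> bool:
    return (cfg.compression_target - cfg.band_halfwidth - 1e-12
            <= ratio <= cfg.compression_target + cfg.band_halfwidth + 1e-12)


def sample_genome(
    arch: ArchDescriptor,
    cfg: SearchConfig,
    rng: np.random.Generator,
    grid: tuple[float, ...] = RATIO_GRID,
) -> PruneGenome:
    """Uniform grid sampling, rejected until the MAC ratio enters the band."""
    groups = arch.prune_groups
    base_macs = count_macs(arch).macs_total
    closest, closest_dist = None, float("inf")
    for _ in range(cfg.sample_retries):
        g = {k: float(grid[int(rng.integers(len(grid)))]) for k in groups}
        ratio = count_macs(apply_genome(arch, g)).macs_total / base_macs
        if _in_band(ratio, cfg):
            return g
        d = abs(ratio - cfg.compression_target)
        if d < closest_dist:
            closest, closest_dist = ratio, d
    raise RuntimeError(
        f"no genome inside the band {cfg.compression_target}+/-{cfg.band_halfwidth} "
        f"after {cfg.sample_retries} tries; closest MAC ratio was {closest:.3f}")


def channel_scores(model: Classifier) -> dict[str, np.ndarray]:
    """Per prune-group filter importance: L1 norm of each output filter,
    summed over the group's convolutions."""
    scores: dict[str, np.ndarray] = {}
    for b in model.blocks:
        s = np.abs(b.conv.W).sum(axis=(1, 2, 3))
        scores[b.group] = scores.get(b.group, 0) + s
    return scores


def materialize_student(model: Classifier, genome: PruneGenome) -> Classifier:
    """Slice the teacher into the genome's sub-network.

    For each prune group the ``round(ratio * c)`` channels with the largest
    filter L1 norms survive (index order preserved); dependent tensors —
    the next conv's input channels, BN parameters and statistics, the fc
    input — are sliced consistently.  Weights are copied, not shared.
    """
    groups = {b.group for b in model.blocks}
    missing = groups - set(genome)
    if missing:
        raise ValueError(f"genome missing prune groups: {sorted(missing)}")
    scores = channel_scores(model)
    keep: dict[str, np.ndarray] = {}
    for g, s in scores.items():
        k = pruned_width(len(s), genome[g])
        top = np.argsort(-s, kind="stable")[:k]
        keep[g] = np.sort(top)

    student = copy.deepcopy(model)
    prev = np.arange(3)
    for b in student.blocks:
        idx = keep[b.group]
        if b.residual and len(prev) != len(idx):
            raise ValueError("residual block's group must match its input group")
        b.conv.W = np.ascontiguousarray(b.conv.W[idx][:, prev])
        b.conv.cin, b.conv.cout = len(prev), len(idx)
        b.conv.dW = np.zeros_like(b.conv.W)
        bn = b.bn
        bn.gamma, bn.beta = bn.gamma[idx].copy(), bn.beta[idx].copy()
        bn.running_mean = bn.running_mean[idx].copy()
        bn.running_var = bn.running_var[idx].copy()
        bn.dgamma, bn.dbeta = np.zeros_like(bn.gamma), np.zeros_like(bn.beta)
        bn.c = len(idx)
        prev = idx
    student.fc.W = np.ascontiguousarray(student.fc.W[:, prev])
    student.fc.dW = np.zeros_like(student.fc.W)

    # rebind the spec so descriptors/parameter counts stay truthful
    student.spec = _pruned_spec(model.spec, genome)
    return student


def _pruned_spec(spec, genome: PruneGenome):
    """Block-level spec of the pruned network (widths may vary per block)."""
    from .model import BlockTableSpec

    rows = []
    cin = 3
    for (_old_cin, old_cout, stride, residual, group) in spec.block_table():
        cout = pruned_width(old_cout, genome[group])
        rows.append((cin, cout, stride, residual, group))
        cin = cout
    return BlockTableSpec(rows, spec.num_classes, spec.input_side,
                          spec.with_residual)


def recalibrate_bn(
    model: Classifier,
    calibration: list[AnnotatedImage] | np.ndarray,
    recal_batches: int,
    rng: np.random.Generator,
    batch_size: int = 16,
    var_floor: float = 1e-5,
) -> Classifier:
    """Replace every BN layer's inference statistics with fresh batch moments.

    Runs ``recal_batches`` mini-batches of calibration data through the
    frozen network; per batch each BN records the channel mean and unbiased
    (N-1) variance of its pre-normalization input, and the stored inference
    statistics become the average over batches.  All non-BN weights are
    untouched.  Mutates and returns ``model``.
    """
    if recal_batches < 1:
        raise ValueError("recal_batches must be >= 1")
    X = calibration if isinstance(calibration, np.ndarray) else records_to_arrays(calibration)[0]
    if len(X) == 0:
        raise ValueError("calibration data is empty")
    sums: list[np.ndarray] = [np.zeros(b.bn.c) for b in model.blocks]
    sqs: list[np.ndarray] = [np.zeros(b.bn.c) for b in model.blocks]
    for _ in range(recal_batches):
        idx = rng.choice(len(X), size=min(batch_size, len(X)), replace=False)
        x = X[idx]
        for j, b in enumerate(model.blocks):
            x_in = x
            x = b.conv.forward(x, train=False)
            mean = x.mean(axis=(0, 2, 3))
            n = x.shape[0] * x.shape[2] * x.shape[3]
            var = x.var(axis=(0, 2, 3)) * n / max(n - 1, 1)
            var = np.maximum(var, var_floor)
            sums[j] += mean
            sqs[j] += var
            inv = 1.0 / np.sqrt(var + b.bn.eps)
            x = (b.bn.gamma[:, None, None] * (x - mean[:, None, None]) * inv[:, None, None]
                 + b.bn.beta[:, None, None])
            if b.residual:
                x = x + x_in
            x = np.maximum(x, 0)
    for j, b in enumerate(model.blocks):
        b.bn.running_mean = (sums[j] / recal_batches).astype(np.float32)
        b.bn.running_var = np.maximum(sqs[j] / recal_batches, var_floor).astype(np.float32)
    return model


def batch_stats(x: np.ndarray) -> tuple[float, float]:
    """Adaptive-BN moments of a 1-D activation sample: mean and unbiased
    variance (N-1 denominator)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("need at least two samples for the unbiased estimator")
    mu = float(x.mean())
    var = float(((x - mu) ** 2).sum() / (n - 1))
    return mu, var


def fitness(n: float, p: int, p0: int, form: str = "literal_product") -> float:
    if p0 <= 0:
        raise ValueError("p0 must be positive")
    ratio = p / p0
    if form == "literal_product":
        return n * ratio
    if form == "accuracy_per_size":
        return n / ratio
    raise ValueError(f"unknown fitness_form {form!r}")


def evaluate_fitness(
    student: Classifier,
    genome: PruneGenome,
    valid_records: list[AnnotatedImage] | tuple[np.ndarray, np.ndarray],
    cfg: SearchConfig,
) -> Individual:
    """Accuracy on the validation manifest + analytic costs -> fitness."""
    if isinstance(valid_records, tuple):
        Xv, yv = valid_records
    else:
        Xv, yv = records_to_arrays(valid_records)
    pred = predict(student, Xv)[0]
    n = float((pred == yv).mean())
    desc = student.descriptor()
    p = count_params(desc).params_total
    macs = count_macs(desc).macs_total
    return Individual(genome=dict(genome), n=n, p=p, macs=macs,
                      f=fitness(n, p, cfg.p0, cfg.fitness_form))


def evolve_generation(
    parents: list[Individual],
    arch: ArchDescriptor,
    cfg: SearchConfig,
    rng: np.random.Generator,
    grid: tuple[float, ...] = RATIO_GRID,
) -> list[PruneGenome]:
    """Uniform crossover of two distinct parents + per-gene mutation,
    re-sampled until each offspring satisfies the MAC band."""
    if len(parents) < 2:
        raise ValueError("need at least two parents")
    groups = arch.prune_groups
    base_macs = count_macs(arch).macs_total
    offspring: list[PruneGenome] = []
    for _ in range(cfg.population_size):
        child = None
        for _try in range(cfg.sample_retries):
            i, j = rng.choice(len(parents), size=2, replace=False)
            a, b = parents[i].genome, parents[j].genome
            g = {k: (a[k] if rng.uniform() < 0.5 else b[k]) for k in groups}
            for k in groups:
                if rng.uniform() < cfg.mutation_rate:
                    g[k] = float(grid[int(rng.integers(len(grid)))])
            ratio = count_macs(apply_genome(arch, g)).macs_total / base_macs
            if _in_band(ratio, cfg):
                child = g
                break
        if child is None:
            raise RuntimeError("could not breed a band-valid offspring within budget")
        offspring.append(child)
    return offspring


def _evaluate_genomes(
    teacher: Classifier,
    genomes: list[PruneGenome],
    calib: np.ndarray,
    valid: tuple[np.ndarray, np.ndarray],
    cfg: SearchConfig,
    rng: np.random.Generator,
) -> list[Individual]:
    out = []
    for g in genomes:
        student = materialize_student(teacher, g)
        recalibrate_bn(student, calib, cfg.recal_batches, rng,
                       batch_size=cfg.recal_batch_size)
        out.append(evaluate_fitness(student, g, valid, cfg))
    return out


def ga_search(
    teacher: Classifier,
    arch: ArchDescriptor,
    train_records: list[AnnotatedImage],
    valid_records: list[AnnotatedImage],
    cfg: SearchConfig,
) -> tuple[Individual, pd.DataFrame]:
    """Evolutionary search over band-constrained genomes.

    Every generation the surviving parents are carried into the evaluated
    pool (elitism, so the best fitness never decreases), ``population_size``
    offspring are bred and evaluated after BN recalibration, and the top
    ``parents_kept`` survive.  The loop stops once the relative change of
    the pool's total fitness stays below ``convergence_tol`` for
    ``convergence_patience`` consecutive generations.
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.p0 <= 0:
        cfg = dataclasses.replace(cfg, p0=teacher.num_params())
    calib = records_to_arrays(train_records)[0]
    valid = records_to_arrays(valid_records)

    genomes = [sample_genome(arch, cfg, rng) for _ in range(cfg.population_size)]
    pool = _evaluate_genomes(teacher, genomes, calib, valid, cfg, rng)
    history_rows = []
    stall, prev_total = 0, None
    for gen in range(cfg.max_generations):
        pool.sort(key=lambda ind: ind.f, reverse=True)
        parents = pool[:cfg.parents_kept]
        total = float(sum(ind.f for ind in pool))
        history_rows.append({
            "generation": gen, "best_f": parents[0].f,
            "mean_f": float(np.mean([i.f for i in pool])), "total_f": total,
            "best_acc": parents[0].n, "best_params": parents[0].p,
            "best_macs": parents[0].macs,
        })
        if prev_total is not None:
            rel = abs(total - prev_total) / max(abs(prev_total), 1e-12)
            stall = stall + 1 if rel < cfg.convergence_tol else 0
            if stall >= cfg.convergence_patience:
                break
        prev_total = total
        if gen == cfg.max_generations - 1:
            break
        offspring = evolve_generation(parents, arch, cfg, rng)
        pool = parents + _evaluate_genomes(teacher, offspring, calib, valid, cfg, rng)
    pool.sort(key=lambda ind: ind.f, reverse=True)
    return pool[0], pd.DataFrame(history_rows)


def random_search(
    teacher: Classifier,
    arch: ArchDescriptor,
    train_records: list[AnnotatedImage],
    valid_records: list[AnnotatedImage],
    cfg: SearchConfig,
    budget: int,
) -> tuple[Individual, pd.DataFrame]:
    """Equal-budget baseline: independent band-constrained samples, each
    evaluated with the same adaptive-BN protocol as the genetic search."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.p0 <= 0:
        cfg = dataclasses.replace(cfg, p0=teacher.num_params())
    calib = records_to_arrays(train_records)[0]
    valid = records_to_arrays(valid_records)
    best, rows = None, []
    for t in range(budget):
        g = sample_genome(arch, cfg, rng)
        ind = _evaluate_genomes(teacher, [g], calib, valid, cfg, rng)[0]
        if best is None or ind.f > best.f:
            best = ind
        rows.append({"draw": t, "f": ind.f, "best_f": best.f, "acc": ind.n})
    return best, pd.DataFrame(rows)
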