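"""Genome sampling, adaptive BN, fitness, evolution, student materialization."""

import dataclasses

import numpy as np
import pytest

from trapslim.archspec import apply_genome, count_macs, count_params
from trapslim.model import ClassifierSpec, build_classifier, records_to_arrays
from trapslim.prune import (RATIO_GRID, SearchConfig, batch_stats,
                            channel_scores, evaluate_fitness, evolve_generation,
                            fitness, ga_search, materialize_student,
                            recalibrate_bn, sample_genome)
from trapslim.synthdata import AnnotatedImage

SPEC = ClassifierSpec(stage_widths=(8, 16), blocks_per_stage=(1, 1),
                      num_classes=3, input_side=32)
ONE_GROUP_SPEC = ClassifierSpec(stage_widths=(10,), blocks_per_stage=(1,),
                                num_classes=3, input_side=16)


def toy_records(n: int, classes: int = 3, side: int = 32, seed: int = 0):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        lab = i % classes
        base = np.zeros((side, side, 3))
        base[..., lab % 3] = 60 + 50 * lab
        px = np.clip(base + rng.normal(0, 10, base.shape), 0, 255).astype(np.uint8)
        recs.append(AnnotatedImage(pixels=px, label=lab, bbox=(0, 0, side, side)))
    return recs


def search_cfg(**kw) -> SearchConfig:
    base = dict(population_size=8, parents_kept=3, recal_batches=2,
                max_generations=4, p0=1, seed=0)
    base.update(kw)
    return SearchConfig(**base)


class TestAdaptiveBNStats:
    def test_three_point_sample(self):
        mu, var = batch_stats([1.0, 2.0, 3.0])
        assert mu == 2.0 and var == 1.0  # ((-1)^2 + 0 + 1^2) / (3 - 1)

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            batch_stats([1.0])

    def test_constant_input_gives_activation_mean_and_floored_variance(self):
        model = build_classifier(SPEC, 0)
        for b in model.blocks:  # padding-free: constant in -> constant out
            b.conv.pad = 0
        X = np.full((6, 3, 32, 32), 0.25, dtype=np.float32)
        conv_out = model.blocks[0].conv.forward(X, train=False)
        recalibrate_bn(model, X, recal_batches=1, rng=np.random.default_rng(0),
                       batch_size=6)
        bn = model.blocks[0].bn
        assert np.allclose(bn.running_mean, conv_out.mean(axis=(0, 2, 3)), atol=1e-5)
        assert np.allclose(bn.running_var, 1e-5)

    def test_single_full_batch_equals_whole_pass_oracle(self):
        model = build_classifier(SPEC, 1)
        X = np.random.default_rng(3).normal(size=(10, 3, 32, 32)).astype(np.float32)
        conv_out = model.blocks[0].conv.forward(X, train=False)
        n = conv_out.shape[0] * conv_out.shape[2] * conv_out.shape[3]
        direct_mean = conv_out.mean(axis=(0, 2, 3))
        direct_var = conv_out.var(axis=(0, 2, 3)) * n / (n - 1)
        recalibrate_bn(model, X, recal_batches=1, rng=np.random.default_rng(0),
                       batch_size=10)
        bn = model.blocks[0].bn
        assert np.allclose(bn.running_mean, direct_mean, atol=1e-5)
        assert np.allclose(bn.running_var, direct_var, rtol=1e-4)

    def test_non_bn_weights_bitwise_unchanged(self):
        model = build_classifier(SPEC, 2)
        before = [model.blocks[0].conv.W.copy(), model.fc.W.copy(),
                  model.blocks[0].bn.gamma.copy()]
        X = np.random.default_rng(4).normal(size=(8, 3, 32, 32)).astype(np.float32)
        recalibrate_bn(model, X, recal_batches=3, rng=np.random.default_rng(1))
        assert np.array_equal(model.blocks[0].conv.W, before[0])
        assert np.array_equal(model.fc.W, before[1])
        assert np.array_equal(model.blocks[0].bn.gamma, before[2])

    def test_zero_batches_rejected(self):
        model = build_classifier(SPEC, 0)
        with pytest.raises(ValueError):
            recalibrate_bn(model, np.zeros((4, 3, 32, 32), np.float32), 0,
                           np.random.default_rng(0))


class TestFitness:
    def test_ratio_one_is_accuracy_under_both_forms(self):
        assert fitness(0.9, 100, 100, "literal_product") == pytest.approx(0.9)
        assert fitness(0.9, 100, 100, "accuracy_per_size") == pytest.approx(0.9)

    def test_half_size_under_both_readings(self):
        assert fitness(0.8, 50, 100, "literal_product") == pytest.approx(0.40)
        assert fitness(0.8, 50, 100, "accuracy_per_size") == pytest.approx(1.60)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            fitness(0.8, 50, 0)


class TestSampleGenome:
    def test_identity_band_accepts_all_ones(self):
        arch = SPEC.to_descriptor()
        cfg = search_cfg(compression_target=1.0, band_halfwidth=0.05)
        g = sample_genome(arch, cfg, np.random.default_rng(0))
        ratio = count_macs(apply_genome(arch, g)).macs_total / count_macs(arch).macs_total
        assert 0.95 <= ratio <= 1.0

    def test_samples_respect_band(self):
        arch = SPEC.to_descriptor()
        cfg = search_cfg()
        rng = np.random.default_rng(1)
        base = count_macs(arch).macs_total
        for _ in range(200):
            g = sample_genome(arch, cfg, rng)
            ratio = count_macs(apply_genome(arch, g)).macs_total / base
            assert 0.45 - 1e-9 <= ratio <= 0.55 + 1e-9

    def test_one_group_net_only_returns_enumerated_feasible_ratios(self):
        arch = ONE_GROUP_SPEC.to_descriptor()
        cfg = search_cfg(compression_target=0.5, band_halfwidth=0.2)
        base = count_macs(arch).macs_total
        feasible = {
            r for r in RATIO_GRID
            if 0.3 <= count_macs(apply_genome(arch, {"stage0.block0": r})).macs_total / base <= 0.7
        }
        assert feasible  # the oracle set is non-trivial
        rng = np.random.default_rng(2)
        for _ in range(100):
            g = sample_genome(arch, cfg, rng)
            assert g["stage0.block0"] in feasible

    def test_infeasible_band_diagnosed(self):
        arch = ONE_GROUP_SPEC.to_descriptor()
        cfg = search_cfg(compression_target=0.02, band_halfwidth=0.001,
                         sample_retries=50)
        with pytest.raises(RuntimeError, match="closest"):
            sample_genome(arch, cfg, np.random.default_rng(0))


class TestEvolveGeneration:
    def _parents(self, arch, cfg, n=3):
        rng = np.random.default_rng(7)
        from trapslim.prune import Individual
        return [Individual(genome=sample_genome(arch, cfg, rng), f=0.5)
                for _ in range(n)]

    def test_identical_parents_closed_under_crossover(self):
        arch = SPEC.to_descriptor()
        cfg = search_cfg(mutation_rate=0.0)
        p = self._parents(arch, cfg, 1)[0]
        from trapslim.prune import Individual
        parents = [p, Individual(genome=dict(p.genome), f=0.5)]
        for child in evolve_generation(parents, arch, cfg, np.random.default_rng(0)):
            assert child == p.genome

    def test_no_mutation_means_locus_containment(self):
        arch = SPEC.to_descriptor()
        cfg = search_cfg(mutation_rate=0.0)
        parents = self._parents(arch, cfg)
        children = evolve_generation(parents, arch, cfg, np.random.default_rng(1))
        for child in children:
            for k, v in child.items():
                assert any(par.genome[k] == v for par in parents)

    def test_offspring_satisfy_band(self):
        arch = SPEC.to_descriptor()
        cfg = search_cfg(mutation_rate=0.3)
        parents = self._parents(arch, cfg)
        base = count_macs(arch).macs_total
        for child in evolve_generation(parents, arch, cfg, np.random.default_rng(2)):
            ratio = count_macs(apply_genome(arch, child)).macs_total / base
            assert 0.45 - 1e-9 <= ratio <= 0.55 + 1e-9

    def test_single_parent_rejected(self):
        arch = SPEC.to_descriptor()
        cfg = search_cfg()
        with pytest.raises(ValueError):
            evolve_generation(self._parents(arch, cfg, 1), arch, cfg,
                              np.random.default_rng(0))


class TestMaterializeStudent:
    def test_all_ones_identity_logits(self):
        model = build_classifier(SPEC, 3)
        genome = {g: 1.0 for g in SPEC.to_descriptor().prune_groups}
        student = materialize_student(model, genome)
        X = np.random.default_rng(5).normal(size=(4, 3, 32, 32)).astype(np.float32)
        assert np.array_equal(student.forward(X, train=False),
                              model.forward(X, train=False))

    def test_kept_channels_are_top_l1(self):
        model = build_classifier(SPEC, 4)
        genome = {"stage0.block0": 0.5, "stage1.block0": 0.5}
        student = materialize_student(model, genome)
        scores = channel_scores(model)
        expect0 = np.sort(np.argsort(-scores["stage0.block0"], kind="stable")[:4])
        assert np.array_equal(
            student.blocks[0].conv.W,
            model.blocks[0].conv.W[expect0])
        expect1 = np.sort(np.argsort(-scores["stage1.block0"], kind="stable")[:8])
        assert np.array_equal(
            student.blocks[1].conv.W,
            model.blocks[1].conv.W[expect1][:, expect0])
        assert np.array_equal(student.fc.W, model.fc.W[:, expect1])

    def test_student_params_match_descriptor_arithmetic(self):
        model = build_classifier(SPEC, 5)
        genome = {"stage0.block0": 0.6, "stage1.block0": 0.3}
        student = materialize_student(model, genome)
        expected = count_params(apply_genome(SPEC.to_descriptor(), genome)).params_total
        assert student.num_params() == expected
        assert student.descriptor().num_classes == 3

    def test_residual_group_slicing(self):
        spec = ClassifierSpec((8, 8), (2, 2), num_classes=2, input_side=32,
                              with_residual=True)
        model = build_classifier(spec, 6)
        student = materialize_student(model, {"stage0": 0.5, "stage1": 0.5})
        X = np.random.default_rng(6).normal(size=(2, 3, 32, 32)).astype(np.float32)
        out = student.forward(X, train=False)
        assert out.shape == (2, 2)
        assert student.num_params() < model.num_params()


class TestSearch:
    def test_evaluate_fitness_uses_accuracy_and_counts(self):
        model = build_classifier(SPEC, 7)
        recs = toy_records(12)
        cfg = search_cfg(p0=model.num_params())
        genome = {g: 1.0 for g in SPEC.to_descriptor().prune_groups}
        ind = evaluate_fitness(model, genome, recs, cfg)
        assert 0.0 <= ind.n <= 1.0
        assert ind.p == model.num_params()
        assert ind.f == pytest.approx(ind.n * ind.p / cfg.p0)

    def test_one_group_search_matches_exhaustive_oracle(self):
        """On a single-group net with deterministic evaluation, the search
        must return the feasible grid ratio that brute force scores best."""
        arch = ONE_GROUP_SPEC.to_descriptor()
        train = toy_records(16, side=16, seed=1)
        valid = toy_records(9, side=16, seed=2)
        teacher = build_classifier(ONE_GROUP_SPEC, 8)
        cfg = search_cfg(compression_target=0.5, band_halfwidth=0.2,
                         population_size=6, parents_kept=2, max_generations=3,
                         recal_batches=1, recal_batch_size=16,
                         p0=teacher.num_params())
        base = count_macs(arch).macs_total
        X = records_to_arrays(train)[0]
        best_oracle, best_f = None, -1.0
        for r in RATIO_GRID:
            g = {"stage0.block0": r}
            ratio = count_macs(apply_genome(arch, g)).macs_total / base
            if not 0.3 <= ratio <= 0.7:
                continue
            student = materialize_student(teacher, g)
            recalibrate_bn(student, X, 1, np.random.default_rng(0), batch_size=16)
            ind = evaluate_fitness(student, g, valid, cfg)
            if ind.f > best_f:
                best_oracle, best_f = r, ind.f
        best, _hist = ga_search(teacher, arch, train, valid, cfg)
        assert best.genome["stage0.block0"] == best_oracle
        assert best.f == pytest.approx(best_f)

    def test_history_and_termination_contract(self):
        arch = SPEC.to_descriptor()
        teacher = build_classifier(SPEC, 9)
        cfg = search_cfg(max_generations=3, p0=teacher.num_params())
        best, hist = ga_search(teacher, arch, toy_records(10), toy_records(6, seed=5), cfg)
        assert len(hist) <= cfg.max_generations
        assert (hist["best_f"].diff().dropna() >= -1e-12).all()
        assert {"generation", "best_f", "mean_f", "total_f"} <= set(hist.columns)
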