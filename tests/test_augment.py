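"""Random pasting and regional background suppression."""

import numpy as np
import pytest

from trapslim.augment import (PasteParams, RBSParams, apply_cutout, apply_rbs,
                              build_augmented_set, random_paste, sample_rbs_mask)
from trapslim.synthdata import (InstanceCutout, SceneConfig, compose_scene,
                                generate_background, generate_dataset,
                                generate_instance)

CFG = SceneConfig(n_sites=3, n_species=3, image_side=48,
                  instances_per_class=(6, 4), seed=7,
                  backgrounds_per_site=2, cutouts_per_species=2)


def rect_cutout(w: int, h: int, value: int = 77) -> InstanceCutout:
    return InstanceCutout(patch=np.full((h, w, 3), value, np.uint8),
                          mask=np.ones((h, w), bool), label=0)


class TestRandomPaste:
    def test_identity_transform_matches_compose(self):
        rng = np.random.default_rng(0)
        bg = generate_background(0, rng, CFG)
        cut = generate_instance(0, rng, CFG)
        params = PasteParams(rotation_range=(0, 0), scale_range=(1, 1))
        pasted = random_paste(cut, bg, np.random.default_rng(1), params,
                              position=(0, 0))
        direct = compose_scene(bg, cut, (0, 0))
        assert np.array_equal(pasted.pixels, direct.pixels)
        assert pasted.bbox == direct.bbox
        assert pasted.provenance == "synthesized"

    def test_quarter_turn_swaps_bbox_sides(self):
        rng = np.random.default_rng(0)
        bg = generate_background(0, rng, CFG)
        cut = rect_cutout(10, 6)
        params = PasteParams(rotation_range=(90, 90), scale_range=(1, 1))
        out = random_paste(cut, bg, np.random.default_rng(2), params)
        x0, y0, x1, y1 = out.bbox
        assert abs((x1 - x0) - 6) <= 1 and abs((y1 - y0) - 10) <= 1

    @pytest.mark.parametrize("angle", [0, 90, 180, 270])
    def test_right_angle_rotation_preserves_pixel_multiset(self, angle):
        rng = np.random.default_rng(0)
        bg = generate_background(1, rng, CFG)
        cut = generate_instance(1, rng, CFG)
        params = PasteParams(rotation_range=(angle, angle), scale_range=(1, 1))
        out = random_paste(cut, bg, np.random.default_rng(3), params)
        before = np.sort(cut.patch[cut.mask].ravel())
        after = np.sort(out.pixels[out.mask].ravel())
        assert np.array_equal(before, after)

    def test_placements_cover_all_quadrants(self):
        rng = np.random.default_rng(11)
        bg = generate_background(0, rng, CFG)
        cut = rect_cutout(6, 6)
        seen = set()
        for _ in range(200):
            out = random_paste(cut, bg, rng,
                               PasteParams(scale_range=(0.8, 1.2)))
            x0, y0, x1, y1 = out.bbox
            cx, cy = (x0 + x1) / 2, (y0 + y1) / 2
            seen.add((cx < 24, cy < 24))
        assert len(seen) == 4

    def test_oversized_cutout_rejected(self):
        rng = np.random.default_rng(0)
        bg = generate_background(0, rng, CFG)
        cut = rect_cutout(60, 60)
        with pytest.raises(ValueError, match="fit"):
            random_paste(cut, bg, rng, PasteParams(rotation_range=(0, 0),
                                                   scale_range=(1, 1)))

    def test_label_preserved(self):
        rng = np.random.default_rng(4)
        bg = generate_background(2, rng, CFG)
        cut = generate_instance(2, rng, CFG)
        assert random_paste(cut, bg, rng).label == 2


class TestSampleRBSMask:
    def test_full_frame_bbox_yields_none(self):
        m = sample_rbs_mask((48, 48), (0, 0, 48, 48), np.random.default_rng(0))
        assert m is None

    def test_masks_always_disjoint_from_bbox(self):
        rng = np.random.default_rng(5)
        bbox = (0, 0, 24, 48)  # left half
        for _ in range(1000):
            m = sample_rbs_mask((48, 48), bbox, rng, area_range=(0.02, 0.08))
            if m is None:
                continue
            x0, y0, x1, y1 = m.rect
            assert x1 <= 24 or x0 >= 24 or y1 <= 0 or y0 >= 48

    def test_degenerate_ranges_give_expected_side(self):
        rng = np.random.default_rng(6)
        f = 0.04
        m = sample_rbs_mask((100, 100), (0, 0, 10, 10), rng,
                            area_range=(f, f), aspect_range=(1, 1))
        x0, y0, x1, y1 = m.rect
        side = round(100 * np.sqrt(f))
        assert (x1 - x0) == side and (y1 - y0) == side


class TestApplyRBS:
    def test_bbox_interior_bytewise_unchanged(self):
        train, _, _, _ = generate_dataset(CFG)
        rng = np.random.default_rng(7)
        for rec in train:
            out = apply_rbs(rec, rng)
            x0, y0, x1, y1 = rec.bbox
            assert np.array_equal(out.pixels[y0:y1, x0:x1],
                                  rec.pixels[y0:y1, x0:x1])
            assert out.bbox == rec.bbox and out.label == rec.label

    def test_suppressed_region_is_fill_value(self):
        train, _, _, _ = generate_dataset(CFG)
        rec = train[0]
        rng = np.random.default_rng(8)
        out = apply_rbs(rec, rng, RBSParams(fill_value=3))
        changed = np.any(out.pixels != rec.pixels, axis=2)
        assert changed.any()
        assert np.all(out.pixels[changed] == 3)
        assert out.provenance == "suppressed"

    def test_zero_masks_is_identity(self):
        train, _, _, _ = generate_dataset(CFG)
        out = apply_rbs(train[0], np.random.default_rng(9), RBSParams(n_masks=0))
        assert np.array_equal(out.pixels, train[0].pixels)

    def test_cutout_may_hit_foreground(self):
        # the contrast to RBS: a big cutout rectangle can cover the bbox
        train, _, _, _ = generate_dataset(CFG)
        rec = train[0]
        rng = np.random.default_rng(0)
        hit = False
        for _ in range(50):
            out = apply_cutout(rec, rng, RBSParams(area_range=(0.5, 0.6)))
            x0, y0, x1, y1 = rec.bbox
            if not np.array_equal(out.pixels[y0:y1, x0:x1], rec.pixels[y0:y1, x0:x1]):
                hit = True
                break
        assert hit


class TestBuildAugmentedSet:
    def test_zero_mix_is_identity(self):
        train, _, cutouts, backgrounds = generate_dataset(CFG)
        out = build_augmented_set(train, cutouts, backgrounds,
                                  np.random.default_rng(0), 0.0, 0.0)
        assert out == train

    def test_half_half_bookkeeping(self):
        train, _, cutouts, backgrounds = generate_dataset(CFG)
        n = len(train)
        out = build_augmented_set(train, cutouts, backgrounds,
                                  np.random.default_rng(1), 0.5, 0.5)
        assert len(out) == 2 * n
        prov = [r.provenance for r in out[n:]]
        assert prov.count("synthesized") == n // 2
        assert prov.count("suppressed") == n - n // 2

    def test_additions_are_valid_and_label_preserving(self):
        train, _, cutouts, backgrounds = generate_dataset(CFG)
        out = build_augmented_set(train, cutouts, backgrounds,
                                  np.random.default_rng(2), 1.0, 1.0)
        for rec in out:
            rec.validate()
        orig_counts = {c: sum(r.label == c for r in train) for c in range(3)}
        new_counts = {c: sum(r.label == c for r in out) for c in range(3)}
        # proportional additions keep the (here uniform) balance uniform
        assert len(set(new_counts.values())) == 1
        assert all(new_counts[c] >= 2 * orig_counts[c] for c in orig_counts)

    def test_empty_background_pool_rejected(self):
        train, _, cutouts, _ = generate_dataset(CFG)
        with pytest.raises(ValueError, match="background"):
            build_augmented_set(train, cutouts, [], np.random.default_rng(0),
                                0.5, 0.0)
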