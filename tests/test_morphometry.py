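import math

import numpy as np
import pytest

from epimux import scenes
from epimux.morphometry import (
    MorphologyRules,
    diameter_um,
    label_aggregates,
    morphology_distribution,
)

EXPECTED_CLASS = {
    "lewy_body": "lewy_body",
    "lewy_neurite": "lewy_neurite",
    "punctate_lysosomal": "punctate",
    "glial": "lewy_neurite",
}


def disc_mask(shape, center, radius):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def flood_fill_count(mask: np.ndarray) -> int:
    """Brute-force 8-connected component count (stack-based flood fill)."""
    mask = mask.copy()
    count = 0
    rows, cols = mask.shape
    for r0 in range(rows):
        for c0 in range(cols):
            if not mask[r0, c0]:
                continue
            count += 1
            stack = [(r0, c0)]
            mask[r0, c0] = False
            while stack:
                r, c = stack.pop()
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < rows and 0 <= cc < cols and mask[rr, cc]:
                            mask[rr, cc] = False
                            stack.append((rr, cc))
    return count


class TestLabelAggregates:
    def test_two_disjoint_discs(self):
        mask = disc_mask((100, 100), (25, 25), 10) | disc_mask((100, 100), (75, 75), 10)
        objs = label_aggregates(mask, pixel_size_um=0.5)
        assert len(objs) == 2

    def test_touching_discs_merge(self):
        mask = disc_mask((100, 100), (50, 40), 10) | disc_mask((100, 100), (50, 59), 10)
        objs = label_aggregates(mask, pixel_size_um=0.5)
        assert len(objs) == 1

    def test_count_matches_flood_fill_oracle(self, rng):
        for _ in range(20):
            mask = rng.random((40, 40)) < 0.25
            objs = label_aggregates(mask, pixel_size_um=1.0, min_object_px=1)
            assert len(objs) == flood_fill_count(mask)

    def test_small_objects_dropped(self):
        mask = np.zeros((50, 50), bool)
        mask[5, 5] = True  # 1 px
        mask[20:30, 20:30] = True  # 100 px
        objs = label_aggregates(mask, pixel_size_um=1.0, min_object_px=5)
        assert len(objs) == 1
        assert objs[0].area_px == 100

    def test_empty_mask(self):
        assert label_aggregates(np.zeros((10, 10), bool), pixel_size_um=1.0) == []

    def test_areas_partition_union(self, rng):
        mask = rng.random((60, 60)) < 0.3
        objs = label_aggregates(mask, pixel_size_um=1.0, min_object_px=1)
        assert sum(o.area_px for o in objs) == int(mask.sum())


class TestClassification:
    def test_disc_is_lewy_body(self):
        mask = disc_mask((100, 100), (50, 50), 20)
        (obj,) = label_aggregates(mask, pixel_size_um=0.5)
        assert obj.morph_class == "lewy_body"
        assert obj.circularity > 0.9
        assert obj.aspect_ratio < 1.1

    def test_bar_is_lewy_neurite(self):
        mask = np.zeros((80, 80), bool)
        mask[40:43, 10:70] = True  # 3 x 60 bar
        (obj,) = label_aggregates(mask, pixel_size_um=0.5)
        assert obj.morph_class == "lewy_neurite"
        assert obj.aspect_ratio > 10

    def test_tiny_disc_is_punctate(self):
        mask = disc_mask((40, 40), (20, 20), 1.5)
        (obj,) = label_aggregates(mask, pixel_size_um=0.5, min_object_px=3)
        assert obj.equivalent_diameter_um < 2.0
        assert obj.morph_class == "punctate"

    def test_invariants_on_random_scene(self, noisefree_scene):
        _, image, gt = noisefree_scene
        union = np.zeros(image.shape, bool)
        for e in image.epitopes:
            union |= gt.channel_mask(e)
        for obj in label_aggregates(union, image.pixel_size_um):
            assert 0 < obj.circularity <= 1.1
            assert obj.aspect_ratio >= 1.0

    def test_simulator_kinds_recovered(self):
        ok = total = 0
        for seed in range(5):
            spec = scenes.random_scene(seed=seed, noise_sigma=0.0)
            image, gt = scenes.render_scene(spec)
            union = np.zeros(image.shape, bool)
            for e in image.epitopes:
                union |= gt.channel_mask(e)
            for obj in label_aggregates(union, image.pixel_size_um):
                overlaps = [int((fp & obj.footprint).sum()) for fp in gt.footprints]
                kind = gt.kinds[int(np.argmax(overlaps))]
                total += 1
                ok += obj.morph_class == EXPECTED_CLASS[kind]
        assert total > 30
        assert ok / total >= 0.95

    def test_club_shaped_neurite_classified(self):
        spec = scenes.SceneSpec(
            shape=(128, 128), pixel_size_um=0.5,
            aggregates=[
                scenes.AggregateSpec(
                    kind="lewy_neurite", centroid=(64, 40), size_um=18.0,
                    thickness_um=1.4, club_end=True,
                    epitope_profile={"Nterm": scenes.EpitopePattern("uniform", 150.0)},
                )
            ],
            seed=7,
        )
        image, gt = scenes.render_scene(spec)
        (obj,) = label_aggregates(gt.channel_mask("Nterm"), 0.5)
        assert obj.morph_class == "lewy_neurite"


class TestDistribution:
    def test_arithmetic(self):
        mask = np.zeros((200, 200), bool)
        mask[10:20, 10:20] = True  # 100 px compact square -> lewy_body
        mask[100:103, 50:150] = True  # 300 px bar -> lewy_neurite
        objs = label_aggregates(mask, pixel_size_um=1.0)
        dist = morphology_distribution(objs)
        assert dist.area_share_pct["lewy_neurite"] == pytest.approx(75.0)
        assert dist.area_share_pct["lewy_body"] == pytest.approx(25.0)

    def test_single_class_is_100(self):
        mask = disc_mask((60, 60), (30, 30), 15)
        dist = morphology_distribution(label_aggregates(mask, 0.5))
        assert dist.area_share_pct["lewy_body"] == pytest.approx(100.0)

    def test_shares_sum_to_100(self, noisefree_scene):
        _, image, gt = noisefree_scene
        union = np.zeros(image.shape, bool)
        for e in image.epitopes:
            union |= gt.channel_mask(e)
        dist = morphology_distribution(label_aggregates(union, image.pixel_size_um))
        assert sum(dist.area_share_pct.values()) == pytest.approx(100.0, abs=1e-9)

    def test_empty_flagged(self):
        dist = morphology_distribution([])
        assert not dist.defined
        assert math.isnan(dist.area_share_pct["lewy_body"])


class TestDiameters:
    def test_disc_equivalent_diameter(self):
        mask = disc_mask((60, 60), (30, 30), 10)
        (obj,) = label_aggregates(mask, pixel_size_um=0.5)
        # area ~ pi * 10^2 px -> equivalent diameter ~ 20 px = 10 um
        assert diameter_um(obj)["equivalent_diameter_um"] == pytest.approx(10.0, rel=0.05)

    def test_line_feret_vs_equivalent(self):
        mask = np.zeros((10, 120), bool)
        mask[5, 10:110] = True  # 1 x 100 line
        (obj,) = label_aggregates(mask, pixel_size_um=1.0)
        d = diameter_um(obj)
        assert d["feret_diameter_um"] == pytest.approx(100.0, rel=0.01)
        assert d["equivalent_diameter_um"] == pytest.approx(2 * math.sqrt(100 / math.pi), rel=1e-6)

    def test_simulator_lb_diameter_round_trip(self):
        spec = scenes.SceneSpec(
            shape=(256, 256), pixel_size_um=0.5,
            aggregates=[
                scenes.AggregateSpec(
                    kind="lewy_body", centroid=(128, 128), size_um=50.0,
                    epitope_profile={"Nterm": scenes.EpitopePattern("uniform", 150.0)},
                )
            ],
        )
        _, gt = scenes.render_scene(spec)
        (obj,) = label_aggregates(gt.channel_mask("Nterm"), 0.5)
        assert abs(obj.equivalent_diameter_um - 50.0) / 50.0 < 0.05

    def test_scale_equivariance(self):
        mask = disc_mask((80, 80), (40, 40), 15)
        (a,) = label_aggregates(mask, pixel_size_um=0.5)
        (b,) = label_aggregates(mask, pixel_size_um=1.0)
        assert b.equivalent_diameter_um == pytest.approx(2 * a.equivalent_diameter_um)
        assert b.area_um2 == pytest.approx(4 * a.area_um2)
        assert b.circularity == a.circularity
        assert b.aspect_ratio == a.aspect_ratio


def test_rules_from_config(config):
    rules = MorphologyRules.from_config(config)
    assert rules.lb_min_circularity == config.lb_min_circularity
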