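import numpy as np
import pytest

from epimux import scenes
from epimux.scenes import (
    AggregateSpec,
    EpitopePattern,
    PKModel,
    SceneSpec,
    expected_report,
    render_scene,
    simulate_pk_series,
)


def single_lb_spec(pattern_by_epitope, noise_sigma=0.0, seed=0, peak=100.0):
    profile = {e: EpitopePattern(p, peak) if p != "absent" else EpitopePattern()
               for e, p in pattern_by_epitope.items()}
    return SceneSpec(
        shape=(128, 128),
        pixel_size_um=0.5,
        aggregates=[
            AggregateSpec(kind="lewy_body", centroid=(64, 64), size_um=20.0,
                          epitope_profile=profile)
        ],
        noise_sigma=noise_sigma,
        seed=seed,
    )


class TestSpecValidation:
    def test_all_absent_rejected(self):
        with pytest.raises(ValueError, match="non-absent"):
            AggregateSpec(kind="lewy_body", centroid=(0, 0), size_um=10,
                          epitope_profile={"N": EpitopePattern()})

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            AggregateSpec(kind="lewy_body", centroid=(0, 0), size_um=0,
                          epitope_profile={"N": EpitopePattern("uniform", 1.0)})

    def test_zero_peak_rejected(self):
        with pytest.raises(ValueError, match="peak"):
            EpitopePattern("uniform", 0.0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(shape=(8, 8), pixel_size_um=0.5, aggregates=[], noise_sigma=-1)

    def test_footprint_outside_image_rejected(self):
        spec = single_lb_spec({"Nterm": "uniform"})
        spec.aggregates[0].centroid = (-500, -500)
        with pytest.raises(ValueError, match="outside"):
            render_scene(spec)

    def test_yaml_round_trip(self, tmp_path):
        spec = single_lb_spec({"Nterm": "uniform", "pS129": "peripheral_ring"})
        import yaml

        payload = {
            "shape": list(spec.shape),
            "pixel_size_um": spec.pixel_size_um,
            "seed": 3,
            "aggregates": [
                {
                    "kind": "lewy_body",
                    "centroid": [64, 64],
                    "size_um": 20.0,
                    "epitope_profile": {
                        "Nterm": {"pattern": "uniform", "peak": 100.0},
                        "pS129": {"pattern": "peripheral_ring", "peak": 80.0},
                    },
                }
            ],
        }
        path = tmp_path / "scene.yaml"
        path.write_text(yaml.safe_dump(payload))
        loaded = SceneSpec.from_file(path)
        img, _ = render_scene(loaded)
        assert img.shape == (128, 128)


class TestRenderScene:
    def test_uniform_all_epitopes_identical(self):
        spec = single_lb_spec({"Nterm": "uniform", "pS129": "uniform", "Cterm": "uniform"})
        image, gt = render_scene(spec)
        footprint = gt.footprints[0]
        for e in ("pS129", "Cterm"):
            np.testing.assert_array_equal(image.channels["Nterm"], image.channels[e])
        assert (image.channels["Nterm"][footprint] == 100.0).all()
        assert (image.channels["Nterm"][~footprint] == 0.0).all()

    def test_absent_pattern_gives_background_only(self):
        spec = SceneSpec(
            shape=(96, 96),
            pixel_size_um=0.5,
            aggregates=[
                AggregateSpec(
                    kind="lewy_neurite", centroid=(48, 48), size_um=15.0,
                    thickness_um=1.5,
                    epitope_profile={"Nterm": EpitopePattern("uniform", 120.0)},
                )
            ],
            monomer_background={"Cterm": 5.0},
        )
        image, _ = render_scene(spec)
        assert (image.channels["Nterm"] > 0).any()
        assert (image.channels["pS129"] == 0).all()
        assert (image.channels["Cterm"] == 5.0).all()

    def test_fixed_seed_bit_identical(self):
        spec = scenes.random_scene(seed=9, shape=(128, 128))
        img1, _ = render_scene(spec)
        img2, _ = render_scene(scenes.random_scene(seed=9, shape=(128, 128)))
        for e in img1.epitopes:
            np.testing.assert_array_equal(img1.channels[e], img2.channels[e])

    def test_ring_pattern_in_outer_annulus(self):
        spec = single_lb_spec({"pS129": "peripheral_ring"})
        image, gt = render_scene(spec)
        mask = gt.aggregate_masks[0]["pS129"]
        rr, cc = np.nonzero(mask)
        radius = spec.aggregates[0].size_um / (2 * spec.pixel_size_um)
        dist = np.hypot(rr - 64, cc - 64)
        in_annulus = dist >= (1 - spec.ring_fraction) * radius - 1.0
        assert in_annulus.mean() >= 0.90

    def test_ground_truth_masks_inside_image(self, reference_scene):
        _, image, gt = reference_scene
        for masks in gt.aggregate_masks:
            for m in masks.values():
                assert m.shape == image.shape


class TestExpectedReport:
    def test_n_only_aggregate(self):
        spec = single_lb_spec({"Nterm": "uniform"})
        _, gt = render_scene(spec)
        rep = expected_report(gt)
        assert rep.unique_pct["Nterm"] == 100.0
        assert rep.overlap_area_px == 0

    def test_identical_labelling_full_overlap(self):
        spec = single_lb_spec({"Nterm": "uniform", "pS129": "uniform", "Cterm": "uniform"})
        _, gt = render_scene(spec)
        rep = expected_report(gt)
        assert rep.overlap_pct == 100.0
        assert all(v == 0 for v in rep.unique_area_px.values())

    def test_toy_interval_masks(self):
        # masks A=1-10, B=6-15, C=11-20 on a 1x21 strip
        def interval(lo, hi):
            m = np.zeros((1, 21), dtype=bool)
            m[0, lo : hi + 1] = True
            return m

        gt = scenes.GroundTruth(
            aggregate_masks=[{"A": interval(1, 10), "B": interval(6, 15), "C": interval(11, 20)}],
            kinds=["lewy_neurite"],
            footprints=[interval(1, 20)],
            region_mask=np.ones((1, 21), dtype=bool),
            pixel_size_um=1.0,
        )
        rep = expected_report(gt)
        assert rep.total_area_px == 20
        assert rep.unique_area_px == {"A": 5, "B": 0, "C": 5}
        assert rep.overlap_area_px == 10

    def test_empty_ground_truth_flagged(self):
        gt = scenes.GroundTruth(
            aggregate_masks=[], kinds=[], footprints=[],
            region_mask=np.ones((4, 4), bool), pixel_size_um=1.0,
        )
        rep = expected_report(gt)
        assert rep.total_area_px == 0
        assert not rep.percentages_defined

    def test_additivity_exact(self, reference_scene):
        _, _, gt = reference_scene
        rep = expected_report(gt)
        assert rep.total_area_px == sum(rep.unique_area_px.values()) + rep.overlap_area_px


class TestPKSeries:
    def model(self, **retention):
        return PKModel(timepoints_min=[0, 15, 30, 60],
                       retention=retention or {"Nterm": {15: 1.0, 30: 0.5, 60: 0.25}})

    def test_timepoints_must_start_at_zero(self):
        with pytest.raises(ValueError, match="start at 0"):
            PKModel(timepoints_min=[15, 30], retention={})

    def test_retention_at_zero_must_be_one(self):
        with pytest.raises(ValueError, match="t=0"):
            PKModel(timepoints_min=[0, 30], retention={"Nterm": {0: 0.5}})

    def test_halving_affects_only_that_channel(self):
        spec = single_lb_spec({"Nterm": "uniform", "pS129": "uniform"})
        model = PKModel(timepoints_min=[0, 30], retention={"Nterm": {30: 0.5}})
        images, gts = simulate_pk_series(spec, model)
        fp = gts[0].footprints[0]
        np.testing.assert_allclose(images[1].channels["Nterm"][fp], 50.0)
        np.testing.assert_allclose(images[1].channels["pS129"][fp], 100.0)

    def test_unmasking_exceeds_pretreatment(self):
        spec = single_lb_spec({"Nterm": "uniform"})
        model = PKModel(timepoints_min=[0, 15], retention={"Nterm": {15: 1.2}})
        images, _ = simulate_pk_series(spec, model)
        assert images[1].channels["Nterm"].max() == pytest.approx(120.0)

    def test_t0_equals_render_scene_bit_exact(self):
        spec = single_lb_spec({"Nterm": "uniform"}, noise_sigma=2.0, seed=21)
        images, _ = simulate_pk_series(spec, self.model())
        base, _ = render_scene(spec)
        np.testing.assert_array_equal(images[0].channels["Nterm"], base.channels["Nterm"])

    def test_all_ones_model_reproducible_per_timepoint(self):
        spec = single_lb_spec({"Nterm": "uniform"}, noise_sigma=2.0, seed=5)
        model = PKModel(timepoints_min=[0, 30], retention={})
        imgs_a, _ = simulate_pk_series(spec, model)
        imgs_b, _ = simulate_pk_series(spec, model)
        for a, b in zip(imgs_a, imgs_b):
            np.testing.assert_array_equal(a.channels["Nterm"], b.channels["Nterm"])
        # different timepoints use independent noise streams
        assert not np.array_equal(imgs_a[0].channels["Nterm"], imgs_a[1].channels["Nterm"])

    def test_monotone_ground_truth_intensity(self):
        spec = single_lb_spec({"Nterm": "uniform"})
        model = PKModel(timepoints_min=[0, 15, 30, 60],
                        retention={"Nterm": {15: 0.9, 30: 0.5, 60: 0.2}})
        _, gts = simulate_pk_series(spec, model)
        series = [gt.integrated_intensity[0]["Nterm"] for gt in gts]
        assert series == sorted(series, reverse=True)

    def test_unaffected_kind_untouched(self):
        spec = single_lb_spec({"Nterm": "uniform"})
        model = PKModel(timepoints_min=[0, 30], retention={"Nterm": {30: 0.5}},
                        affected_kinds=("glial",))
        images, _ = simulate_pk_series(spec, model)
        np.testing.assert_array_equal(images[0].channels["Nterm"], images[1].channels["Nterm"])


class TestExportGroundTruth:
    def test_exports_label_tiffs_and_manifest(self, tmp_path):
        spec = scenes.random_scene(seed=2, shape=(128, 128), n_lewy_bodies=1,
                                   n_lewy_neurites=1, n_punctate=1, n_glial=0)
        _, gt = render_scene(spec)
        scenes.export_ground_truth(gt, tmp_path)
        import pandas as pd
        import tifffile

        manifest = pd.read_csv(tmp_path / "gt_manifest.csv")
        assert len(manifest) == 3
        label = tifffile.imread(tmp_path / "gt_Nterm.tif")
        assert label.max() >= 1
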