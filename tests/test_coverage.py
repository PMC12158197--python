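"""Segmentation, fractional cover and the accuracy/error statistics."""

import io

import numpy as np
import pandas as pd
import pytest

from vegcover import (
    AccuracySummary,
    ClassificationMask,
    ConfigurationError,
    ConfusionMatrix2x2,
    ErrorReport,
    InputError,
    LabeledPixelSet,
    MaskSource,
    Polarity,
    SceneConfig,
    ThresholdResult,
    VIRaster,
    binarize,
    build_class_histograms_from_values,
    compute_index,
    confusion_stats,
    coverage,
    error_table,
    extraction_errors,
    find_intersection_threshold,
    generate_scene,
    labels_from_mask,
    resolution_analysis,
    segment_by_threshold,
    threshold_sensitivity,
)


def _vi(values, name="EXG", polarity=Polarity.VEG_HIGH, valid=None):
    values = np.atleast_2d(np.asarray(values, dtype=np.float64))
    if valid is None:
        valid = np.ones_like(values, dtype=bool)
    return VIRaster(index_name=name, values=values, valid_mask=valid,
                    polarity=polarity)


def _thr(name, t, polarity=Polarity.VEG_HIGH):
    return ThresholdResult(index_name=name, intersection_interval=(t, t),
                           threshold=t, polarity=polarity, misclassified_count=0)


class TestSegmentAndCoverage:
    def test_veg_high_boundary_is_closed_on_the_vegetation_side(self):
        mask = segment_by_threshold(_vi([10, 58, 59, 200]), _thr("EXG", 58.0))
        np.testing.assert_array_equal(mask.labels[0], [0, 1, 1, 1])

    def test_veg_low_rule_for_the_red_green_ratio(self):
        mask = segment_by_threshold(
            _vi([0.4, 0.63, 0.9], "RGRI", Polarity.VEG_LOW),
            _thr("RGRI", 0.63, Polarity.VEG_LOW),
        )
        np.testing.assert_array_equal(mask.labels[0], [1, 1, 0])

    def test_all_invalid_vi_gives_all_nodata_mask(self):
        vi = _vi([1.0, 2.0], valid=np.zeros((1, 2), dtype=bool))
        mask = segment_by_threshold(vi, _thr("EXG", 1.5))
        assert (mask.labels == 255).all()

    def test_index_mismatch_rejected(self):
        with pytest.raises(ConfigurationError):
            segment_by_threshold(_vi([1.0]), _thr("VDVI", 0.5))

    def test_coverage_fraction_of_valid_pixels(self):
        labels = np.array([[1, 1, 1, 1, 1], [1, 0, 0, 0, 0], [255, 255, 255, 255, 255]],
                          dtype=np.uint8)
        res = coverage(ClassificationMask(labels, MaskSource.THRESHOLD))
        assert res.coverage_pct == 60.0
        assert res.n_veg == 6 and res.n_valid == 10

    def test_all_vegetation_and_no_valid_pixels(self):
        all_veg = ClassificationMask(np.ones((3, 3), np.uint8), MaskSource.THRESHOLD)
        assert coverage(all_veg).coverage_pct == 100.0
        empty = ClassificationMask(np.full((2, 2), 255, np.uint8), MaskSource.THRESHOLD)
        with pytest.raises(InputError):
            coverage(empty)

    def test_noiseless_pipeline_recovers_generator_target_exactly(self):
        """Zero-noise scene built at 62.94% cover: thresholding the VDVI
        raster returns the realized coverage with no error at all."""
        cfg = SceneConfig(rows=100, cols=100, target_coverage_pct=62.94,
                          rgb_sd=(0, 0, 0), shadow_fraction=0.0,
                          mixed_pixel_band_px=0, seed=3)
        scene = generate_scene(cfg)
        assert scene.realized_coverage_pct == pytest.approx(62.94, abs=0.005)
        vi = compute_index(scene.image, "VDVI")
        lab = labels_from_mask(scene.truth_mask, n_per_class=300,
                               rng=np.random.default_rng(3))
        hist = build_class_histograms_from_values(
            "VDVI",
            vi.values[lab.rows[lab.is_vegetation()], lab.cols[lab.is_vegetation()]],
            vi.values[lab.rows[~lab.is_vegetation()], lab.cols[~lab.is_vegetation()]],
            0.01,
        )
        thr = find_intersection_threshold(hist)
        cov = coverage(segment_by_threshold(vi, thr))
        assert cov.coverage_pct == pytest.approx(scene.realized_coverage_pct, abs=1e-12)

    def test_coverage_monotone_in_threshold(self):
        rng = np.random.default_rng(9)
        vi_vals = rng.normal(0, 1, (50, 50))
        sweep = np.linspace(-2, 2, 21)
        for polarity in (Polarity.VEG_HIGH, Polarity.VEG_LOW):
            vi = VIRaster("EXG", vi_vals, np.ones_like(vi_vals, bool), polarity)
            covs = [coverage(binarize(vi, t, polarity)).coverage_pct for t in sweep]
            diffs = np.diff(covs)
            if polarity is Polarity.VEG_HIGH:
                assert (diffs <= 0).all()
            else:
                assert (diffs >= 0).all()

    def test_mask_partition_conserved(self):
        rng = np.random.default_rng(1)
        labels = rng.choice([0, 1, 255], size=(40, 40), p=[0.4, 0.5, 0.1])
        mask = ClassificationMask(labels.astype(np.uint8), MaskSource.THRESHOLD)
        assert mask.vegetation.sum() + mask.soil.sum() == mask.valid.sum()


class TestConfusionStats:
    def test_printed_reference_confusion_matrix(self):
        """The published wheat/soil validation matrix reproduces its printed
        user's and producer's accuracies and a Kappa just under 0.99."""
        cm = ConfusionMatrix2x2(29611, 140, 157, 22405)
        s = confusion_stats(cm)
        assert s.users_accuracy_veg == pytest.approx(0.9953, abs=5e-5)
        assert s.users_accuracy_soil == pytest.approx(0.9930, abs=5e-5)
        assert s.producers_accuracy_veg == pytest.approx(0.9947, abs=5e-5)
        assert s.producers_accuracy_soil == pytest.approx(0.9938, abs=5e-5)
        assert s.overall_accuracy == pytest.approx(0.9943, abs=5e-5)
        assert s.kappa == pytest.approx(0.9884, abs=5e-5)

    def test_perfect_and_chance_agreement(self):
        perfect = confusion_stats(ConfusionMatrix2x2(50, 0, 0, 50))
        assert perfect.overall_accuracy == 1.0 and perfect.kappa == 1.0
        chance = confusion_stats(ConfusionMatrix2x2(25, 25, 25, 25))
        assert chance.kappa == 0.0

    def test_degenerate_marginals_rejected(self):
        with pytest.raises(InputError):
            confusion_stats(ConfusionMatrix2x2(10, 0, 0, 0))

    def test_kappa_matches_sklearn_on_random_matrices(self):
        """Independent oracle: sklearn's cohen_kappa_score on expanded labels."""
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(17)
        for _ in range(100):
            n = rng.integers(1, 50, size=4)
            if (n[0] + n[1] == 0) or (n[2] + n[3] == 0):
                continue
            cm = ConfusionMatrix2x2(*map(int, n))
            pred = np.repeat([1, 1, 0, 0], n)
            ref = np.repeat([1, 0, 1, 0], n)
            expected = cohen_kappa_score(pred, ref)
            if np.isnan(expected):
                continue
            assert confusion_stats(cm).kappa == pytest.approx(expected, abs=1e-12)


class TestExtractionErrors:
    @pytest.mark.parametrize(
        "thr_cov, ref_cov, signed, absolute",
        [
            (74.90, 76.57, -2.18, 1.67),
            (61.28, 60.02, 2.10, 1.26),
            (77.11, 75.13, 2.64, 1.98),
            (57.52, 60.02, -4.17, 2.50),
            (62.18, 62.94, -1.21, 0.76),
        ],
    )
    def test_signed_relative_and_absolute_point_errors(self, thr_cov, ref_cov,
                                                       signed, absolute):
        rep = extraction_errors([("x", thr_cov, ref_cov)])
        row = rep.table.iloc[0]
        assert row["extraction_error_pct"] == pytest.approx(signed, abs=5e-3)
        assert row["absolute_error_points"] == pytest.approx(absolute, abs=5e-3)

    def test_equal_coverages_give_zero_errors(self):
        rep = extraction_errors([("x", 42.0, 42.0)])
        assert rep.table.iloc[0]["extraction_error_pct"] == 0.0
        assert rep.table.iloc[0]["absolute_error_points"] == 0.0

    def test_zero_reference_coverage_rejected(self):
        with pytest.raises(InputError):
            extraction_errors([("x", 10.0, 0.0)])

    def test_sample_sd_of_absolute_errors_across_types(self):
        """Four vegetation types under one index: SD of the |errors| is the
        published per-index spread, 0.60."""
        rep = extraction_errors(
            [("crop", 85.14, 85.78), ("tree", 73.96, 73.77),
             ("shrub", 61.28, 60.02), ("mixed", 73.62, 75.13)],
            index_name="EXG",
        )
        assert rep.abs_error_sd == pytest.approx(0.60, abs=5e-3)

    def test_error_report_round_trips_through_csv(self):
        rep = extraction_errors(
            [("crop", 85.14, 85.78), ("shrub", 61.28, 60.02)], index_name="EXG")
        buf = io.StringIO(rep.to_csv())
        back = ErrorReport.from_csv(buf)
        buf2 = io.StringIO(back.to_csv())
        assert buf.getvalue() == buf2.getvalue()

    def test_error_table_stacks_indices(self):
        table = error_table({
            "EXG": [("crop", 85.14, 85.78)],
            "RGRI": [("crop", 86.92, 85.78)],
        })
        assert set(table["index_name"]) == {"EXG", "RGRI"}


class TestResolutionAnalysis:
    @staticmethod
    def _blocky_scene(seed=13):
        """Patches made of whole 8x8 blocks, so block-averaging by 2/4/8
        keeps every downsampled pixel pure."""
        from vegcover import RGBRaster, MaskSource

        rng = np.random.default_rng(seed)
        coarse = rng.random((12, 12)) < 0.55  # 12x12 blocks of 8px
        veg = np.kron(coarse, np.ones((8, 8), dtype=bool))
        img = np.where(veg[..., None],
                       np.array([60, 160, 60]), np.array([150, 120, 90]))
        raster = RGBRaster(red=img[..., 0].astype(np.uint8),
                           green=img[..., 1].astype(np.uint8),
                           blue=img[..., 2].astype(np.uint8),
                           valid_mask=None, gsd_cm=0.83)
        truth = ClassificationMask(veg.astype(np.uint8), MaskSource.TRUTH)
        return raster, truth

    def test_noiseless_block_scene_has_zero_errors_at_all_resolutions(self):
        from vegcover import SyntheticScene, resample_scene

        raster, truth = self._blocky_scene()
        scene = SyntheticScene(image=raster, truth_mask=truth,
                               realized_coverage_pct=100 * truth.vegetation.mean())
        scenes = [(0.83, scene.image)]
        for f in (2, 4, 8):
            rs = resample_scene(scene, f)
            scenes.append((0.83 * f, rs.image))
        labels = labels_from_mask(truth, n_per_class=200,
                                  rng=np.random.default_rng(4))
        rep = resolution_analysis(scenes, "VDVI", labels)
        np.testing.assert_allclose(rep.table["extraction_error_pct"], 0.0, atol=1e-9)
        np.testing.assert_allclose(rep.table["absolute_error_points"], 0.0, atol=1e-9)

    def test_checkerboard_coverage_preserved_by_block_averaging(self):
        from vegcover import SyntheticScene, resample_scene

        veg = np.indices((32, 32)).sum(axis=0) % 2 == 0
        truth = ClassificationMask(veg.astype(np.uint8), MaskSource.TRUTH)
        img = np.where(veg[..., None], np.array([60, 160, 60]),
                       np.array([150, 120, 90]))
        from vegcover import RGBRaster

        raster = RGBRaster(red=img[..., 0].astype(np.uint8),
                           green=img[..., 1].astype(np.uint8),
                           blue=img[..., 2].astype(np.uint8),
                           valid_mask=None, gsd_cm=1.0)
        scene = SyntheticScene(image=raster, truth_mask=truth,
                               realized_coverage_pct=50.0)
        rs = resample_scene(scene, 2)
        # 2x2 blocks are half vegetation; ties go to vegetation
        assert rs.realized_coverage_pct == 100.0

    def test_printed_finest_resolution_row_reproduced_from_coverage_pairs(self):
        """Feeding the published finest-GSD coverage pairs through the error
        arithmetic reproduces that row's statistics."""
        rep = extraction_errors(
            [("crop", 85.78, 85.63), ("tree", 74.90, 76.57),
             ("shrub", 62.18, 62.94)], index_name="VDVI")
        got = rep.table.set_index("vegetation_type")
        assert got.loc["tree", "extraction_error_pct"] == pytest.approx(-2.18, abs=5e-3)
        assert got.loc["tree", "absolute_error_points"] == pytest.approx(1.67, abs=5e-3)
        assert got.loc["shrub", "extraction_error_pct"] == pytest.approx(-1.21, abs=5e-3)
        # printed SD is 0.77 from unrounded intermediates; recomputation from
        # the printed coverages gives 0.765
        assert rep.abs_error_sd == pytest.approx(0.77, abs=0.01)

    def test_inconsistent_extents_rejected(self):
        raster, truth = self._blocky_scene()
        labels = labels_from_mask(truth, n_per_class=50,
                                  rng=np.random.default_rng(0))
        with pytest.raises(InputError):
            resolution_analysis([(0.83, raster), (1.66, raster)], "VDVI", labels)


class TestThresholdSensitivity:
    @staticmethod
    def _setup(scene_seed=31):
        scene = generate_scene(SceneConfig(rows=128, cols=128, seed=scene_seed))
        vi = compute_index(scene.image, "VDVI")
        lab = labels_from_mask(scene.truth_mask, n_per_class=400,
                               rng=np.random.default_rng(scene_seed))
        hist = build_class_histograms_from_values(
            "VDVI",
            vi.values[lab.rows[lab.is_vegetation()], lab.cols[lab.is_vegetation()]],
            vi.values[lab.rows[~lab.is_vegetation()], lab.cols[~lab.is_vegetation()]],
            0.01,
        )
        thr = find_intersection_threshold(hist)
        return vi, thr, lab

    def test_well_separated_scene_is_robust_to_five_percent(self):
        vi, thr, lab = self._setup()
        rep = threshold_sensitivity(vi, thr, lab, perturbation_pct=5.0)
        assert rep.max_accuracy_change_pct < 2.0

    def test_zero_perturbation_changes_nothing(self):
        vi, thr, lab = self._setup()
        rep = threshold_sensitivity(vi, thr, lab, perturbation_pct=0.0)
        assert rep.max_accuracy_change_pct == 0.0

    def test_gap_wider_than_perturbation_changes_nothing(self):
        """No labelled pixel sits within the perturbed band, so accuracy is
        bitwise unchanged."""
        vals = np.array([[0.0, 0.05, 0.95, 1.0]])
        vi = VIRaster("VDVI", vals, np.ones_like(vals, bool), Polarity.VEG_HIGH)
        lab = LabeledPixelSet(
            [0, 0, 0, 0], [0, 1, 2, 3],
            np.array(["soil", "soil", "vegetation", "vegetation"], dtype=object))
        thr = ThresholdResult("VDVI", (0.5, 0.5), 0.5, Polarity.VEG_HIGH, 0)
        rep = threshold_sensitivity(vi, thr, lab, perturbation_pct=5.0)
        assert rep.accuracy_low == rep.accuracy_nominal == rep.accuracy_high == 1.0
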