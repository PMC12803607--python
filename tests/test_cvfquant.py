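"""Quantification pipeline: ROI, linear Bayes classifier, morphology, CVF."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import multivariate_normal

import fibrosurv as fs
from fibrosurv.synthslide import BACKGROUND, CLASS_NAMES, FIBROSIS, MUSCLE


def _white(h, w):
    return np.full((h, w, 3), 245, dtype=np.uint8)


class TestDetectROI:
    def test_uniform_white_image_empty_roi(self):
        assert fs.detect_roi(_white(50, 50)).sum() == 0

    def test_planted_square_exact_pixel_count(self):
        img = _white(60, 60)
        img[20:30, 25:35] = (180, 60, 70)
        roi = fs.detect_roi(img)
        assert roi.sum() == 100
        assert roi[20:30, 25:35].all()

    def test_covers_truth_tissue(self, small_slide):
        roi = fs.detect_roi(small_slide.pixels)
        tissue = small_slide.truth_mask != BACKGROUND
        assert (roi & tissue).sum() / tissue.sum() >= 0.99

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            fs.detect_roi(_white(5, 5), background_distance_threshold=0)

    def test_empty_image(self):
        roi = fs.detect_roi(np.zeros((0, 0, 3), dtype=np.uint8))
        assert roi.size == 0


class TestTrainClassifier:
    def test_exact_means_two_point_classes(self):
        colors = np.vstack([np.zeros((12, 3)), np.full((12, 3), 255.0)])
        # tiny jitter on one sample per class keeps the pooled covariance defined
        colors[0] += 1
        colors[12] -= 1
        labels = np.array([BACKGROUND] * 12 + [MUSCLE] * 12)
        clf = fs.train_classifier(fs.PixelTrainingSet(colors, labels))
        np.testing.assert_allclose(clf.class_means[BACKGROUND], colors[:12].mean(axis=0))
        np.testing.assert_allclose(clf.class_means[MUSCLE], colors[12:].mean(axis=0))

    def test_equal_priors_three_classes(self, small_slide):
        ts = fs.sample_training_pixels(small_slide, 50, seed=0)
        clf = fs.train_classifier(ts, prior_mode="equal")
        np.testing.assert_allclose(clf.priors, np.full(3, 1 / 3))

    def test_empirical_priors(self, small_slide):
        ts = fs.sample_training_pixels(small_slide, 50, seed=0)
        clf = fs.train_classifier(ts, prior_mode="empirical")
        np.testing.assert_allclose(clf.priors, np.full(3, 1 / 3))  # balanced draw

    def test_pooled_covariance_matches_independent_formula(self):
        rng = np.random.default_rng(5)
        xa = rng.normal(0, 3, (40, 3))
        xb = rng.normal(30, 5, (25, 3))
        colors = np.vstack([xa, xb])
        labels = np.array([BACKGROUND] * 40 + [MUSCLE] * 25)
        clf = fs.train_classifier(fs.PixelTrainingSet(colors, labels))
        pooled = ((len(xa) - 1) * np.cov(xa.T) + (len(xb) - 1) * np.cov(xb.T)) / (65 - 2)
        np.testing.assert_allclose(clf.shared_covariance, pooled, rtol=1e-10)

    def test_training_set_invariants(self):
        with pytest.raises(ValueError, match="two classes"):
            fs.PixelTrainingSet(np.zeros((20, 3)), np.zeros(20, dtype=int))
        with pytest.raises(ValueError, match="fewer than 10"):
            fs.PixelTrainingSet(
                np.zeros((15, 3)), np.array([0] * 10 + [1] * 5)
            )


class TestClassifyPixels:
    def _iso_clf(self):
        means = np.array([[0.0, 0.0, 0.0], [2.0, 2.0, 2.0], [4.0, 4.0, 4.0]])
        return fs.LinearBayesClassifier(
            class_means=means, shared_covariance=np.eye(3), priors=np.full(3, 1 / 3)
        )

    def test_midpoint_tie_goes_to_earlier_class(self):
        clf = self._iso_clf()
        # (1,1,1) ties background/muscle; (3,3,3) ties muscle/fibrosis
        pred = clf.predict(np.array([[1.0, 1.0, 1.0], [3.0, 3.0, 3.0]]))
        assert pred.tolist() == [BACKGROUND, MUSCLE]

    def test_slide_accuracy_inside_roi(self, small_slide, trained_classifier):
        roi = fs.detect_roi(small_slide.pixels)
        labels = fs.classify_pixels(small_slide.pixels, roi, trained_classifier)
        truth = small_slide.truth_mask
        inside = roi & (truth != BACKGROUND)
        acc = (labels[inside] == truth[inside]).mean()
        assert acc >= 0.99

    def test_resubstitution_accuracy(self, small_slide, trained_classifier):
        ts = fs.sample_training_pixels(small_slide, 1000, seed=1)
        pred = trained_classifier.predict(ts.colors)
        assert (pred == ts.labels).mean() >= 0.99

    def test_non_roi_is_background(self, small_slide, trained_classifier):
        roi = np.zeros(small_slide.truth_mask.shape, dtype=bool)
        labels = fs.classify_pixels(small_slide.pixels, roi, trained_classifier)
        assert (labels == BACKGROUND).all()

    def test_shape_mismatch(self, small_slide, trained_classifier):
        with pytest.raises(ValueError):
            fs.classify_pixels(
                small_slide.pixels, np.ones((3, 3), dtype=bool), trained_classifier
            )

    def test_agrees_with_gaussian_log_posterior_oracle(self, trained_classifier):
        """Linear-discriminant argmax must equal the full Gaussian
        log-posterior argmax (shared covariance), including the tie rule."""
        rng = np.random.default_rng(2024)
        colors = rng.integers(0, 256, size=(1000, 3)).astype(float)
        clf = trained_classifier
        log_post = np.column_stack(
            [
                multivariate_normal.logpdf(colors, mean=clf.class_means[k], cov=clf.shared_covariance)
                + np.log(clf.priors[k])
                for k in range(3)
            ]
        )
        assert np.array_equal(clf.predict(colors), np.argmax(log_post, axis=1))


class TestPostprocess:
    def test_single_pixel_removed_by_opening(self):
        labels = np.zeros((20, 20), dtype=np.uint8)
        labels[10, 10] = MUSCLE
        out = fs.postprocess(labels, min_fragment_area_px=0, opening_radius_px=1)
        assert (out == BACKGROUND).all()

    def test_min_area_boundary(self):
        # 3x3 block (9 px), no opening: threshold 10 removes it, 9 keeps it
        labels = np.zeros((20, 20), dtype=np.uint8)
        labels[5:8, 5:8] = FIBROSIS
        removed = fs.postprocess(labels, min_fragment_area_px=10, opening_radius_px=0)
        kept = fs.postprocess(labels, min_fragment_area_px=9, opening_radius_px=0)
        assert (removed == BACKGROUND).all()
        assert np.count_nonzero(kept == FIBROSIS) == 9

    def test_idempotence_on_generated_slide(self, small_slide, trained_classifier):
        roi = fs.detect_roi(small_slide.pixels)
        labels = fs.classify_pixels(small_slide.pixels, roi, trained_classifier)
        once = fs.postprocess(labels, min_fragment_area_px=625, opening_radius_px=1)
        twice = fs.postprocess(once, min_fragment_area_px=625, opening_radius_px=1)
        assert np.array_equal(once, twice)

    def test_removes_planted_artifacts(self, small_slide, trained_classifier):
        noisy = fs.add_artifacts(small_slide, n_dust=4, n_micro_fragments=3, seed=2)
        seg = fs.quantify_slide(noisy, trained_classifier)
        # everything labelled tissue must belong to the one true fragment
        tissue = seg.label_mask != BACKGROUND
        truth_tissue = small_slide.truth_mask != BACKGROUND
        assert (tissue & ~truth_tissue).sum() / tissue.sum() < 0.01


class TestAreasAndCVF:
    def test_pixel_to_mm2_conversion(self):
        labels = np.zeros((100, 100), dtype=np.uint8)
        labels.ravel()[:1000] = FIBROSIS
        seg = fs.compute_areas(labels, resolution_um_per_px=10.0)
        assert seg.areas_mm2["fibrosis"] == pytest.approx(0.1)

    def test_counts_partition_image(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 3, size=(37, 53)).astype(np.uint8)
        seg = fs.compute_areas(labels, 4.0)
        assert sum(seg.pixel_counts.values()) == 37 * 53

    @pytest.mark.parametrize(
        "fib,mus,expected", [(0.0, 10.0, 0.0), (10.0, 0.0, 100.0), (32.0, 68.0, 32.0)]
    )
    def test_cvf_formula(self, fib, mus, expected):
        assert fs.compute_cvf(fib, mus) == pytest.approx(expected)

    def test_cvf_no_tissue_error(self):
        with pytest.raises(ValueError, match="no tissue"):
            fs.compute_cvf(0.0, 0.0)

    @given(
        fib=st.floats(0.001, 50.0),
        mus=st.floats(0.001, 50.0),
    )
    def test_cvf_bounds_property(self, fib, mus):
        cvf = fs.compute_cvf(fib, mus)
        assert 0.0 < cvf < 100.0


class TestQualityFilterAndAggregation:
    def _seg(self, fib, mus, fid="f"):
        labels = np.zeros((2, 2), dtype=np.uint8)
        seg = fs.compute_areas(labels, 4.0, fragment_id=fid)
        seg.areas_mm2 = {"background": 0.0, "muscle": mus, "fibrosis": fib}
        return seg

    def test_below_threshold_excluded_with_reason(self):
        retained, excluded = fs.quality_filter([self._seg(0.5, 1.4, "a")], min_tissue_mm2=2.0)
        assert retained == []
        assert excluded[0][0] == "a" and "2.0 mm2" in excluded[0][1]

    def test_all_pass(self):
        retained, excluded = fs.quality_filter(
            [self._seg(1.0, 2.0), self._seg(2.0, 2.0)], min_tissue_mm2=2.0
        )
        assert len(retained) == 2 and excluded == []

    def test_zero_retained_patient_flagged(self):
        p = fs.aggregate_patient("p1", [])
        assert not p.usable and np.isnan(p.cvf_percent)

    def test_pooling_is_area_weighted_not_mean_of_fractions(self):
        p = fs.aggregate_patient(
            "p1", [self._seg(1.0, 3.0), self._seg(6.0, 2.0)], min_total_tissue_mm2=2.0
        )
        assert p.cvf_percent == pytest.approx(100.0 * 7.0 / 12.0)
        assert p.cvf_percent != pytest.approx(50.0)  # mean of 25 and 75

    def test_single_fragment_identity(self):
        p = fs.aggregate_patient("p1", [self._seg(1.0, 3.0)], min_total_tissue_mm2=2.0)
        assert p.cvf_percent == pytest.approx(25.0)

    def test_order_invariance(self):
        frags = [self._seg(1.0, 3.0), self._seg(3.0, 1.0), self._seg(0.5, 0.5)]
        a = fs.aggregate_patient("p", frags)
        b = fs.aggregate_patient("p", frags[::-1])
        assert a.cvf_percent == b.cvf_percent


class TestEndToEnd:
    def test_background_margin_invariance(self, small_slide, trained_classifier):
        seg = fs.quantify_slide(small_slide, trained_classifier)
        cvf = fs.compute_cvf(seg.areas_mm2["fibrosis"], seg.areas_mm2["muscle"])
        pad = 40
        h, w, _ = small_slide.pixels.shape
        # extend with palette-like background noise
        rng = np.random.default_rng(0)
        big = np.clip(
            rng.normal(245, 12, (h + 2 * pad, w + 2 * pad, 3)), 0, 255
        ).astype(np.uint8)
        big[pad:-pad, pad:-pad] = small_slide.pixels
        mask = np.zeros(big.shape[:2], dtype=np.uint8)
        mask[pad:-pad, pad:-pad] = small_slide.truth_mask
        padded = fs.SyntheticSlide(
            pixels=big,
            truth_mask=mask,
            resolution_um_per_px=small_slide.resolution_um_per_px,
            fragment_id="padded",
            true_cvf_percent=small_slide.true_cvf_percent,
        )
        seg2 = fs.quantify_slide(padded, trained_classifier)
        cvf2 = fs.compute_cvf(seg2.areas_mm2["fibrosis"], seg2.areas_mm2["muscle"])
        assert abs(cvf2 - cvf) < 0.1

    def test_monotonicity_in_planted_fraction(self, trained_classifier):
        measured = []
        for target in (10.0, 30.0, 60.0):
            slide = fs.generate_fragment(0.25, target, seed=77)
            seg = fs.quantify_slide(slide, trained_classifier)
            measured.append(
                fs.compute_cvf(seg.areas_mm2["fibrosis"], seg.areas_mm2["muscle"])
            )
        assert measured == sorted(measured)
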