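"""Pixel features, classifier training, and islet-object creation."""

import numpy as np
import pandas as pd
import pytest

from isletpath.cells import CellDetectionResult
from isletpath.islets import (create_islet_objects, extract_pixel_features,
                              train_pixel_classifier)
from isletpath.slide_io import Slide


def flat_slide(arr, mpp=1.0, marker="INS"):
    return Slide(pixels=arr[None].astype(np.float32), mpp=mpp,
                 channel_map={marker: 0})


class TestPixelFeatures:
    def test_feature_arity_one_channel_one_scale(self):
        s = flat_slide(np.zeros((20, 20)))
        f = extract_pixel_features(s, scales_um=(1.0,))
        assert f.shape == (20, 20, 2)            # raw + one scale

    def test_constant_image_all_features_constant(self):
        s = flat_slide(np.full((30, 30), 4.25))
        f = extract_pixel_features(s, scales_um=(1.0, 2.0, 4.0))
        np.testing.assert_allclose(f, 4.25, rtol=1e-6)

    def test_delta_image_peak_matches_direct_convolution(self):
        img = np.zeros((41, 41))
        img[20, 20] = 1.0
        sigma = 2.0
        f = extract_pixel_features(flat_slide(img), scales_um=(sigma,))
        # oracle: separable sampled-Gaussian kernel, independent of ndimage
        r = int(4 * sigma)                        # default truncation
        g = np.exp(-np.arange(-r, r + 1) ** 2 / (2 * sigma ** 2))
        g /= g.sum()
        expected_peak = g[r] ** 2
        assert f[20, 20, 1] == pytest.approx(expected_peak, rel=1e-6)

    def test_roi_outside_image_errors(self):
        s = flat_slide(np.zeros((20, 20)))
        with pytest.raises(ValueError, match="roi"):
            extract_pixel_features(s, roi=(slice(30, 40), slice(0, 5)))

    def test_empty_scales_error(self):
        with pytest.raises(ValueError):
            extract_pixel_features(flat_slide(np.zeros((5, 5))), scales_um=())


class TestTrainClassifier:
    @staticmethod
    def separable():
        feats = np.zeros((20, 20, 2), dtype=np.float32)
        labels = np.zeros((20, 20), dtype=np.uint8)
        feats[:10] = 10.0
        labels[:10] = 1
        labels[10:] = 2
        return feats, labels

    def test_separable_training_accuracy_is_one(self):
        feats, labels = self.separable()
        clf = train_pixel_classifier(feats, labels, seed=0)
        assert clf.training_accuracy == 1.0

    def test_same_seed_identical_predictions(self, rng):
        feats = rng.uniform(0, 1, size=(30, 30, 3)).astype(np.float32)
        labels = (rng.random((30, 30)) > 0.5).astype(np.uint8) + 1
        a = train_pixel_classifier(feats, labels, seed=9)
        b = train_pixel_classifier(feats, labels, seed=9)
        X = feats.reshape(-1, 3)
        np.testing.assert_array_equal(a.model.predict(X), b.model.predict(X))

    def test_single_class_labels_error(self):
        feats = np.zeros((10, 10, 2), dtype=np.float32)
        labels = np.full((10, 10), 1, dtype=np.uint8)
        with pytest.raises(ValueError, match="both islet and ignore"):
            train_pixel_classifier(feats, labels)

    def test_held_out_pixel_accuracy_on_synthetic_slide(self, small_run):
        slide, gt, result, _ = small_run
        from isletpath.islets import DEFAULT_SCALES_UM
        from isletpath.synthetic import (truth_pixel_labels,
                                         _rasterize_union)
        channels = [m for m in slide.markers
                    if m in ("Hoechst", "INS", "PI", "GCG", "CHGA")]
        feats = extract_pixel_features(slide, scales_um=DEFAULT_SCALES_UM,
                                       channels=channels)
        labels = truth_pixel_labels(gt)
        clf = train_pixel_classifier(feats, labels, seed=4,
                                     channels=channels)
        pred = clf.predict_mask(slide, within=gt.tissue_mask)
        truth_mask = _rasterize_union([i.polygon for i in gt.islets],
                                      gt.tissue_mask.shape, slide.mpp)
        held_out = gt.tissue_mask & (labels == 0)
        acc = (pred[held_out] == truth_mask[held_out]).mean()
        assert acc >= 0.95


def fake_detection(centroids_um, shape=(100, 100), mpp=1.0):
    cells = pd.DataFrame({
        "cell_id": np.arange(1, len(centroids_um) + 1),
        "centroid_x_um": [c[0] for c in centroids_um],
        "centroid_y_um": [c[1] for c in centroids_um],
    })
    z = np.zeros(shape, dtype=np.int32)
    return CellDetectionResult(nucleus_labels=z, cell_labels=z.copy(),
                               cells=cells, mpp=mpp)


class TestCreateIsletObjects:
    @pytest.mark.parametrize("n_cells,expect", [(9, 0), (10, 1)])
    def test_min_cell_threshold_boundary(self, n_cells, expect):
        mask = np.zeros((100, 100), dtype=bool)
        mask[20:60, 20:60] = True
        pts = [(30.0 + 2 * i, 30.0) for i in range(n_cells)]
        det = fake_detection(pts)
        islets, endo, cells = create_islet_objects(mask, det, min_cells=10)
        assert len(islets) == expect
        if expect:
            assert endo.sum() == mask.sum()
            assert (cells["islet_id"] == 0).all()
        else:
            assert not endo.any()
            assert (cells["islet_id"] == -1).all()

    def test_holes_filled_before_counting(self):
        mask = np.zeros((60, 60), dtype=bool)
        mask[10:50, 10:50] = True
        mask[25:35, 25:35] = False                 # hole
        pts = [(12.0 + 3 * i, 12.0) for i in range(10)]
        islets, endo, _ = create_islet_objects(mask, fake_detection((pts)),
                                               min_cells=10)
        assert len(islets) == 1
        assert endo[30, 30]                        # hole is endocrine now

    def test_synthetic_islet_count_and_iou(self, small_run):
        _, gt, result, _ = small_run
        assert abs(len(result.islets) - len(gt.islets)) <= 1
        ious = []
        for det in result.islets:
            ious.append(max(det.polygon.intersection(t.polygon).area
                            / det.polygon.union(t.polygon).area
                            for t in gt.islets))
        assert np.mean(ious) >= 0.7

    def test_every_islet_has_min_cells_and_scattered_cells_excluded(
            self, small_run):
        _, gt, result, _ = small_run
        for islet in result.islets:
            assert islet.n_cells >= 10
        # no detected islet is built around a scattered single endocrine cell
        import shapely.geometry as sgeom
        scattered = gt.cells[gt.cells["kind"].str.startswith("scattered")]
        pts = [sgeom.Point(x, y) for x, y in zip(scattered["x_um"],
                                                 scattered["y_um"])]
        for islet in result.islets:
            inside = sum(islet.polygon.covers(p) for p in pts)
            assert inside <= 1   # an islet never forms on scattered singles

    def test_union_of_islets_equals_endocrine_mask(self, small_run):
        _, _, result, _ = small_run
        # pixel-exact identity used by compartment accounting
        n_endo_px = int(result.endocrine_mask.sum())
        assert n_endo_px > 0
        assert result.summary.endocrine_area_mm2 == pytest.approx(
            n_endo_px * result.tissue.mpp ** 2 / 1e6, abs=1e-12)
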