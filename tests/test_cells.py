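"""Cell detection, intensity measurement and neighborhood smoothing."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage as ndi
from scipy.optimize import linear_sum_assignment

from isletpath.cells import (CellDetectionConfig, add_smoothed_features,
                             detect_cells, measure_cells)
from isletpath.slide_io import Slide
from isletpath.tissue import TissueMask


def nuclei_slide(points, shape=(200, 200), amp=120.0, sigma=1.75, mpp=1.0):
    """Slide with Gaussian nuclei at the given (x, y) µm positions."""
    img = np.zeros(shape, dtype=np.float32)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for x, y in points:
        img += amp * np.exp(-(((xx + 0.5) * mpp - x) ** 2
                              + ((yy + 0.5) * mpp - y) ** 2)
                            / (2 * sigma ** 2))
    return Slide(pixels=img[None], mpp=mpp, channel_map={"Hoechst": 0})


def full_tissue(shape=(200, 200), mpp=1.0):
    return TissueMask(mask=np.ones(shape, dtype=bool), mpp=mpp,
                      n_components=1)


class TestDetectCells:
    def test_blank_nuclear_channel_gives_no_cells(self):
        slide = nuclei_slide([])
        res = detect_cells(slide, full_tissue(), CellDetectionConfig())
        assert res.n_cells == 0

    def test_missing_nuclear_channel_errors(self):
        slide = Slide(pixels=np.zeros((1, 20, 20)), mpp=1.0,
                      channel_map={"INS": 0})
        with pytest.raises(ValueError, match="nuclear channel"):
            detect_cells(slide, full_tissue((20, 20)), CellDetectionConfig())

    def test_two_separated_nuclei_centroids_within_one_pixel(self):
        pts = [(80.0, 100.0), (80.0 + 3 * 3.5, 100.0)]   # 3 radii apart
        slide = nuclei_slide(pts)
        res = detect_cells(slide, full_tissue(), CellDetectionConfig())
        assert res.n_cells == 2
        got = np.sort(res.cells["centroid_x_um"].to_numpy())
        want = np.sort([p[0] for p in pts])
        np.testing.assert_allclose(got, want, atol=1.0)
        np.testing.assert_allclose(res.cells["centroid_y_um"], 100.0,
                                   atol=1.0)

    def test_watershed_equals_connected_components_when_not_touching(self):
        rng = np.random.default_rng(42)
        cfg = CellDetectionConfig()
        for _ in range(20):
            n = rng.integers(3, 12)
            pts = []
            while len(pts) < n:
                cand = rng.uniform(15, 185, size=2)
                if all(np.hypot(*(cand - p)) > 16 for p in pts):
                    pts.append(cand)
            slide = nuclei_slide([tuple(p) for p in pts])
            res = detect_cells(slide, full_tissue(), cfg)
            binary = slide.channel("Hoechst") > cfg.nucleus_threshold
            _, n_cc = ndi.label(binary)
            assert res.n_cells == n_cc == n

    def test_nucleus_threshold_monotonicity(self, small_slide):
        """Raising the nucleus threshold shrinks the segmented foreground
        exactly; detection counts follow, up to the ~1% jitter that watershed
        re-splitting and the area filter introduce at boundary thresholds."""
        slide, _ = small_slide
        from isletpath.tissue import ThresholderConfig, detect_tissue
        tissue = detect_tissue(slide, ThresholderConfig())
        fg = [(slide.channel("Hoechst") > t).sum()
              for t in (20.0, 30.0, 50.0, 80.0)]
        assert all(a >= b for a, b in zip(fg, fg[1:]))
        counts = [detect_cells(slide, tissue,
                               CellDetectionConfig(nucleus_threshold=t)).n_cells
                  for t in (20.0, 30.0, 50.0, 80.0)]
        assert all(b <= a * 1.02 for a, b in zip(counts, counts[1:]))
        assert counts[-1] < counts[0]

    def test_ground_truth_recovery_count_and_recall(self, small_run):
        slide, gt, result, _ = small_run
        n_true = len(gt.cells)
        n_det = len(result.cells)
        assert abs(n_det - n_true) / n_true <= 0.05
        # Hungarian matching with a 5 µm gate
        det = result.cells[["centroid_x_um", "centroid_y_um"]].to_numpy()
        tru = gt.cells[["x_um", "y_um"]].to_numpy()
        d = np.hypot(det[:, None, 0] - tru[None, :, 0],
                     det[:, None, 1] - tru[None, :, 1])
        ri, ci = linear_sum_assignment(np.minimum(d, 1e6))
        recall = (d[ri, ci] <= 5.0).sum() / n_true
        assert recall >= 0.95


class TestMeasureCells:
    def test_uniform_channel_means_equal_value(self):
        slide = nuclei_slide([(50, 50), (120, 130)])
        px = np.concatenate([slide.pixels,
                             np.full((1, 200, 200), 7.5, dtype=np.float32)])
        slide2 = Slide(pixels=px, mpp=1.0,
                       channel_map={"Hoechst": 0, "INS": 1})
        res = detect_cells(slide2, full_tissue(), CellDetectionConfig())
        cells = measure_cells(res, slide2)
        for comp in ("Nucleus", "Cytoplasm", "Cell"):
            np.testing.assert_allclose(cells[f"INS: {comp} mean"], 7.5,
                                       rtol=1e-6)

    def test_zero_expansion_sets_cytoplasm_fallback(self):
        slide = nuclei_slide([(100, 100)])
        cfg = CellDetectionConfig(cell_expansion_um=0.0)
        res = detect_cells(slide, full_tissue(), cfg)
        cells = measure_cells(res, slide)
        assert cells["cytoplasm_fallback"].all()
        np.testing.assert_allclose(cells["Hoechst: Cytoplasm mean"],
                                   cells["Hoechst: Nucleus mean"])

    def test_positive_cell_mean_above_noise_floor(self, small_run):
        slide, gt, result, _ = small_run
        spec = gt.spec
        beta = gt.cells[gt.cells["kind"] == "beta"]
        det = result.cells
        tree_xy = det[["centroid_x_um", "centroid_y_um"]].to_numpy()
        from scipy.spatial import cKDTree
        d, idx = cKDTree(tree_xy).query(beta[["x_um", "y_um"]].to_numpy())
        matched = det.iloc[idx[d <= 5.0]]
        floor = spec.background + 3 * spec.noise_sd
        assert (matched["INS: Cell mean"] > floor).mean() >= 0.99


class TestSmoothedFeatures:
    @staticmethod
    def table(xy, values):
        df = pd.DataFrame({"cell_id": np.arange(len(xy)),
                           "centroid_x_um": xy[:, 0],
                           "centroid_y_um": xy[:, 1],
                           "INS: Cell mean": values})
        return df

    def test_isolated_cell_keeps_own_value(self):
        df = self.table(np.array([[0.0, 0.0], [500.0, 500.0]]),
                        np.array([3.0, 9.0]))
        out = add_smoothed_features(df, radius_um=25)
        np.testing.assert_allclose(out["Smoothed 25 um: INS: Cell mean"],
                                   [3.0, 9.0])

    def test_coincident_pair_averages(self):
        df = self.table(np.array([[10.0, 10.0], [10.0, 10.0]]),
                        np.array([2.0, 8.0]))
        out = add_smoothed_features(df, radius_um=25)
        np.testing.assert_allclose(out["Smoothed 25 um: INS: Cell mean"],
                                   [5.0, 5.0])

    def test_matches_brute_force_to_1e9(self, rng):
        xy = rng.uniform(0, 120, size=(50, 2))
        vals = rng.uniform(0, 100, size=50)
        df = self.table(xy, vals)
        out = add_smoothed_features(df.copy(), radius_um=25)
        sigma = 12.5
        expected = np.empty(50)
        for i in range(50):                       # O(n²) oracle
            num = den = 0.0
            for j in range(50):
                d = np.hypot(*(xy[i] - xy[j]))
                if d <= 25:
                    w = np.exp(-d ** 2 / (2 * sigma ** 2))
                    num += w * vals[j]
                    den += w
            expected[i] = num / den
        np.testing.assert_allclose(out["Smoothed 25 um: INS: Cell mean"],
                                   expected, rtol=0, atol=1e-9)

    def test_shift_invariance(self, rng):
        xy = rng.uniform(0, 100, size=(30, 2))
        vals = rng.uniform(0, 10, size=30)
        a = add_smoothed_features(self.table(xy, vals), radius_um=25)
        b = add_smoothed_features(self.table(xy + [1234.5, -777.25], vals),
                                  radius_um=25)
        np.testing.assert_allclose(a["Smoothed 25 um: INS: Cell mean"],
                                   b["Smoothed 25 um: INS: Cell mean"],
                                   rtol=0, atol=1e-9)
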