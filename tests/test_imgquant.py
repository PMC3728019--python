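import numpy as np
import pandas as pd
import pytest

from thfish import imgquant, synth
from thfish.imgquant import ImageStack, LabelMask

from conftest import counts_vs_truth, make_planted_scene


def _blank_stack(value=0.0, shape=(5, 64, 64)):
    return ImageStack(np.full(shape, value), pixel_size_um=0.13)


def _planted_spot_stack(positions, amplitude=200.0, sigma=1.5, noise_sd=0.0, shape=(9, 96, 96), seed=0):
    rng = np.random.default_rng(seed)
    stack = np.zeros(shape)
    zz, yy, xx = np.indices(shape)
    for (z, y, x) in positions:
        stack += amplitude * np.exp(
            -((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2) - (zz - z) ** 2 / (2 * 0.75**2)
        )
    if noise_sd:
        stack += rng.normal(0, noise_sd, shape)
        stack = np.clip(stack, 0, None)
    return ImageStack(stack, pixel_size_um=0.13)


class TestSegmentation:
    def test_blank_image_zero_labels(self):
        mask = imgquant.segment_cells(_blank_stack(7.0))
        assert mask.n_cells == 0

    def test_separated_disks_recovered_with_high_iou(self):
        # 5 well-separated disks: 5 labels, each IoU >= 0.8 against truth
        centers = np.array([[40, 40], [130, 40], [220, 40], [85, 130], [175, 130]], float)
        counts = pd.DataFrame({"cell_id": range(1, 6), "tbx21": [0] * 5})
        scene = synth.SceneParams(n_cells=5, seed=0, fov_px=260)
        _, bf, truth = synth.make_scene(scene, counts, centers_px=centers)
        mask = imgquant.segment_cells(bf, min_area_px=500)
        assert mask.n_cells == 5
        for i in range(1, 6):
            tr = truth.label_mask == i
            labs, cnt = np.unique(mask.labels[tr], return_counts=True)
            best = labs[np.argmax(cnt)]
            assert best > 0
            pred = mask.labels == best
            iou = (tr & pred).sum() / (tr | pred).sum()
            assert iou >= 0.8

    def test_touching_disks_split(self):
        # two tangent cells: the watershed splits them at the neck
        r = 7.0 / 0.13 / 2
        centers = np.array([[60, 60], [60 + 2 * r, 60]])
        counts = pd.DataFrame({"cell_id": [1, 2], "tbx21": [0, 0]})
        scene = synth.SceneParams(n_cells=2, seed=1, fov_px=180)
        _, bf, truth = synth.make_scene(scene, counts, centers_px=centers)
        mask = imgquant.segment_cells(bf, min_area_px=500)
        assert mask.n_cells == 2

    def test_labels_partition_foreground(self, planted_scene):
        # each labelled pixel carries exactly one label by construction;
        # verify the mask is a clean partition with contiguous ids
        _, bf, _, _ = planted_scene
        mask = imgquant.segment_cells(bf, min_area_px=500)
        ids = np.unique(mask.labels)
        assert ids[0] == 0
        np.testing.assert_array_equal(ids[1:], np.arange(1, mask.n_cells + 1))


class TestSpotDetection:
    def test_blank_stack_no_spots(self):
        assert imgquant.detect_spots(_blank_stack(), threshold=5.0) == []

    def test_threshold_must_be_positive(self):
        with pytest.raises(ValueError):
            imgquant.detect_spots(_blank_stack(), threshold=0.0)

    def test_planted_spots_recovered_within_one_pixel(self):
        rng = np.random.default_rng(3)
        pos = [(rng.integers(2, 7), 10 + 8 * i, 10 + 7 * ((i * 13) % 10)) for i in range(10)]
        stack = _planted_spot_stack(pos, noise_sd=20.0)
        spots = imgquant.detect_spots(stack, sigma_px=1.5)
        assert len(spots) == 10
        found = {(s.y, s.x) for s in spots}
        for (_, y, x) in pos:
            assert any(abs(fy - y) <= 1 and abs(fx - x) <= 1 for fy, fx in found)

    def test_threshold_above_peak_suppresses_spot(self):
        stack = _planted_spot_stack([(4, 40, 40)])
        from thfish.imgquant import _log_response

        peak = _log_response(stack.pixels, 1.5).max()
        assert imgquant.detect_spots(stack, sigma_px=1.5, threshold=peak * 1.01) == []

    def test_spot_spanning_slices_counted_once(self):
        # a bright spot bleeding into neighbouring z-slices is one 3-D region
        stack = _planted_spot_stack([(4, 40, 40)], amplitude=500.0)
        spots = imgquant.detect_spots(stack, sigma_px=1.5, threshold=5.0)
        assert len(spots) == 1


class TestThresholdSelection:
    def test_plateau_matches_any_plateau_count(self):
        rng = np.random.default_rng(5)
        pos = [(int(rng.integers(2, 7)), int(rng.integers(8, 88)), int(rng.integers(8, 88))) for _ in range(8)]
        stack = _planted_spot_stack(pos, noise_sd=15.0, seed=5)
        thr = imgquant.select_threshold(stack, sigma_px=1.5)
        n_auto = len(imgquant.detect_spots(stack, sigma_px=1.5, threshold=thr))
        # nearby thresholds in the plateau give the same count
        assert len(imgquant.detect_spots(stack, sigma_px=1.5, threshold=thr * 1.2)) == n_auto
        assert len(imgquant.detect_spots(stack, sigma_px=1.5, threshold=thr / 1.2)) == n_auto

    def test_scale_equivariance(self):
        pos = [(4, 20, 20), (3, 50, 60), (5, 70, 30)]
        stack = _planted_spot_stack(pos, noise_sd=10.0, seed=2)
        thr1 = imgquant.select_threshold(stack, sigma_px=1.5)
        doubled = ImageStack(stack.pixels * 2, pixel_size_um=0.13)
        thr2 = imgquant.select_threshold(doubled, sigma_px=1.5)
        assert thr2 == pytest.approx(2 * thr1, rel=1e-6)
        n1 = len(imgquant.detect_spots(stack, sigma_px=1.5, threshold=thr1))
        n2 = len(imgquant.detect_spots(doubled, sigma_px=1.5, threshold=thr2))
        assert n1 == n2 == 3

    def test_blank_stack_warns_and_counts_zero(self):
        stack = _blank_stack(3.0)
        with pytest.warns(UserWarning):
            thr = imgquant.select_threshold(stack)
        assert len(imgquant.detect_spots(stack, threshold=thr)) == 0


class TestAssignment:
    def test_all_spots_in_one_cell(self):
        labels = np.zeros((50, 50), dtype=int)
        labels[10:30, 10:30] = 1
        labels[35:45, 35:45] = 2
        spots = [imgquant.Spot("g", 0, 15 + i, 15, 1.0) for i in range(5)]
        counts, n_bg = imgquant.assign_spots(spots, LabelMask(labels))
        assert counts.loc[1, "g"] == 5
        assert counts.loc[2, "g"] == 0
        assert n_bg == 0

    def test_background_spot_discarded_and_reported(self):
        labels = np.zeros((20, 20), dtype=int)
        labels[5:10, 5:10] = 1
        spots = [imgquant.Spot("g", 0, 6, 6, 1.0), imgquant.Spot("g", 0, 1, 1, 1.0)]
        counts, n_bg = imgquant.assign_spots(spots, LabelMask(labels))
        assert counts.loc[1, "g"] == 1
        assert n_bg == 1


class TestFluorescence:
    def _two_cell_mask(self):
        labels = np.zeros((40, 60), dtype=int)
        labels[10:20, 5:15] = 1
        labels[10:20, 35:45] = 2
        return LabelMask(labels)

    def test_uniform_image_all_zero(self):
        mask = self._two_cell_mask()
        stack = _blank_stack(50.0, shape=(3, 40, 60))
        totals = imgquant.quantify_fluorescence(stack, mask)
        assert all(v == 0.0 for v in totals.values())

    def test_bright_cell_algebra(self):
        # one cell at v + delta, the other at v, equal areas A: bright total
        # is A*delta, dim total 0
        mask = self._two_cell_mask()
        img = np.full((3, 40, 60), 10.0)
        img[1][mask.labels == 1] = 14.0
        totals = imgquant.quantify_fluorescence(ImageStack(img, 0.13), mask)
        assert totals[1] == pytest.approx(100 * 4.0)
        assert totals[2] == 0.0

    def test_totals_nonnegative_and_offset_invariant(self):
        rng = np.random.default_rng(0)
        mask = self._two_cell_mask()
        img = rng.uniform(0, 100, (3, 40, 60))
        t1 = imgquant.quantify_fluorescence(ImageStack(img, 0.13), mask)
        t2 = imgquant.quantify_fluorescence(ImageStack(img + 37.0, 0.13), mask)
        assert all(v >= 0 for v in t1.values())
        for k in t1:
            assert t1[k] == pytest.approx(t2[k], abs=1e-6)

    def test_no_cells_empty_result(self):
        assert imgquant.quantify_fluorescence(_blank_stack(), LabelMask(np.zeros((64, 64), int))) == {}


class TestExtrapolation:
    def test_exact_linear_inversion(self):
        s = 321.0
        counts = np.array([0.0, 10, 20, 50, 80, 120, 1000])
        fluor = s * counts
        new, slope = imgquant.extrapolate_counts(counts, fluor, resolvable_max=200)
        assert slope == pytest.approx(s)
        assert new[-1] == pytest.approx(1000.0)
        np.testing.assert_allclose(new[:-1], counts[:-1])

    def test_no_dense_cells_unchanged(self):
        counts = np.array([5.0, 10, 20, 40, 60])
        fluor = 10.0 * counts
        new, _ = imgquant.extrapolate_counts(counts, fluor, resolvable_max=200)
        np.testing.assert_allclose(new, counts)

    def test_errors(self):
        with pytest.raises(ValueError):
            imgquant.extrapolate_counts(np.array([1.0, 2]), np.array([1.0, 2]), resolvable_max=200)
        counts = np.array([10.0, 20, 30, 40, 50])
        with pytest.raises(ValueError):
            imgquant.extrapolate_counts(counts, -1.0 * counts, resolvable_max=200)

    def test_dense_cell_recovered_from_fluorescence(self):
        # planted 500-spot cell (unresolvable) plus OFF cells anchoring the
        # background and resolvable calibration cells
        tb = [0, 0, 0, 0, 0, 10, 15, 20, 25, 30, 35, 40, 45, 500]
        counts = pd.DataFrame({"cell_id": np.arange(1, 15), "ifng": tb})
        scene = synth.SceneParams(n_cells=14, seed=0)
        fish, _, truth = synth.make_scene(scene, counts)
        mask = LabelMask(truth.label_mask)
        spots = imgquant.detect_spots(fish["ifng"])
        det_df, _ = imgquant.assign_spots(spots, mask)
        det = det_df["ifng"].reindex(range(1, 15)).fillna(0).to_numpy(float)
        fl = imgquant.quantify_fluorescence(fish["ifng"], mask, z_mode="sum")
        fl = np.array([fl[i] for i in range(1, 15)])
        new, _ = imgquant.extrapolate_counts(det, fl, resolvable_max=200)
        assert abs(new[-1] - 500) / 500 < 0.10


class TestEndToEnd:
    def test_planted_counts_recovered(self, planted_scene):
        # full imaging chain on a planted scene: segmentation + auto-threshold
        # detection + assignment recovers the exact count for >= 95% of cells
        fish, bf, truth, counts = planted_scene
        mask = imgquant.segment_cells(bf, min_area_px=500)
        exact = total = 0
        for gene in ("tbx21", "gata3"):
            spots = imgquant.detect_spots(fish[gene])
            det, _ = imgquant.assign_spots(spots, mask)
            for true, found in counts_vs_truth(mask, truth, det, gene):
                total += 1
                exact += int(true == found)
        assert exact / total >= 0.95
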