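"""Nucleus detection, per-cell classification and endpoint arithmetic."""

import math

import numpy as np
import pytest

from microtma import (
    CellRecord,
    DetectionParams,
    MultiplexImage,
    SectionParams,
    classify_cells,
    detect_nuclei,
    generate_section,
    quantify_spheroid,
)
from microtma.cellquant import quantify_labels

from conftest import match_to_truth


def make_image(nuclear=None, red=None, green=None, shape=(64, 64), pixel_size=1.0):
    zeros = np.zeros(shape, dtype=float)
    return MultiplexImage(
        channels={
            "nuclear": zeros if nuclear is None else nuclear,
            "red": zeros.copy() if red is None else red,
            "green": zeros.copy() if green is None else green,
        },
        pixel_size_um=pixel_size,
    )


def gaussian_blob(shape, cx, cy, sigma, amplitude):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))


class TestDetectNuclei:
    def test_blank_image_no_centers(self):
        assert len(detect_nuclei(np.zeros((100, 100)), pixel_size_um=1.0)) == 0

    def test_single_nucleus_located_to_one_pixel(self):
        img = gaussian_blob((100, 100), cx=50, cy=50, sigma=2.5, amplitude=100)
        centers = detect_nuclei(img, DetectionParams(), pixel_size_um=1.0)
        assert len(centers) == 1
        assert math.hypot(centers[0][0] - 50, centers[0][1] - 50) <= 1.0

    def test_non_2d_input_rejected(self):
        with pytest.raises(ValueError, match="2D"):
            detect_nuclei(np.zeros((3, 4, 5)), pixel_size_um=1.0)

    def test_pairwise_separation_enforced(self, default_section):
        params, image, _ = default_section
        dp = DetectionParams()
        centers = detect_nuclei(image.nuclear, dp, image.pixel_size_um)
        from scipy.spatial.distance import pdist

        min_d = dp.min_center_distance_um / image.pixel_size_um
        assert pdist(centers).min() >= min_d

    def test_row_major_output_order(self, fast_section):
        _, image, _ = fast_section
        centers = detect_nuclei(image.nuclear, DetectionParams(), image.pixel_size_um)
        ys = centers[:, 1]
        assert (np.diff(ys) >= 0).all()

    def test_detection_matches_ground_truth(self, default_section):
        """Count within +-5% and detections 1-1 matched within a cell radius."""
        params, image, truth = default_section
        dp = DetectionParams()
        centers = detect_nuclei(image.nuclear, dp, image.pixel_size_um)
        n_true = truth.n_cells
        assert abs(len(centers) - n_true) <= 0.05 * n_true
        r_px = dp.cell_radius_um / image.pixel_size_um
        det_i, gt_i = match_to_truth(centers, truth, r_px)
        assert len(det_i) >= 0.95 * n_true
        assert len(np.unique(gt_i)) == len(gt_i)  # no double assignments

    def test_sigma_ordering_validated(self):
        with pytest.raises(ValueError, match="sigma"):
            DetectionParams(dog_sigma_small_um=5.0, dog_sigma_large_um=4.0)


class TestClassifyCells:
    def test_fixed_threshold_above_is_tumor(self):
        red = np.full((64, 64), 10.0)
        img = make_image(red=red)
        recs = classify_cells(img, [(32, 32)], DetectionParams(red_threshold_mode="fixed:5"))
        assert recs[0].compartment == "tumor"

    def test_tie_at_threshold_is_negative(self):
        red = np.full((64, 64), 10.0)
        img = make_image(red=red)
        recs = classify_cells(img, [(32, 32)], DetectionParams(red_threshold_mode="fixed:10"))
        assert recs[0].compartment == "normal"

    def test_empty_centers_empty_records(self):
        img = make_image()
        assert classify_cells(img, [], DetectionParams()) == []

    def test_every_center_yields_one_record(self, default_section):
        _, image, _ = default_section
        dp = DetectionParams()
        centers = detect_nuclei(image.nuclear, dp, image.pixel_size_um)
        recs = classify_cells(image, centers, dp)
        assert len(recs) == len(centers)

    def test_edge_cell_uses_in_bounds_pixels(self):
        red = np.full((40, 40), 7.0)
        img = make_image(red=red, shape=(40, 40))
        recs = classify_cells(img, [(0, 0)], DetectionParams(red_threshold_mode="fixed:5"))
        assert recs[0].mean_red == pytest.approx(7.0)
        assert recs[0].compartment == "tumor"

    def test_raising_red_threshold_never_increases_tumor_count(self, fast_section):
        _, image, _ = fast_section
        dp = DetectionParams()
        centers = detect_nuclei(image.nuclear, dp, image.pixel_size_um)
        counts = []
        for thr in (0.0, 5.0, 20.0, 80.0, 1e9):
            recs = classify_cells(
                image, centers, DetectionParams(red_threshold_mode=f"fixed:{thr}")
            )
            counts.append(sum(r.compartment == "tumor" for r in recs))
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == len(centers) and counts[-1] == 0

    def test_classification_accuracy_on_synthetic_truth(self, default_section):
        """Otsu auto-thresholds recover >=95% of true compartment/marker labels."""
        params, image, truth = default_section
        dp = DetectionParams()
        centers = detect_nuclei(image.nuclear, dp, image.pixel_size_um)
        recs = classify_cells(image, centers, dp)
        r_px = dp.cell_radius_um / image.pixel_size_um
        det_i, gt_i = match_to_truth(centers, truth, r_px)
        comp_true = truth.cells["compartment"].to_numpy()[gt_i]
        mark_true = truth.cells["marker"].to_numpy()[gt_i]
        comp_pred = np.array([recs[i].compartment for i in det_i])
        mark_pred = np.array([recs[i].marker for i in det_i])
        assert (comp_pred == comp_true).mean() >= 0.95
        assert (mark_pred == mark_true).mean() >= 0.95

    def test_brute_force_disc_mean_oracle(self):
        """classify_cells equals a per-pixel-disc reimplementation exactly."""
        rng = np.random.default_rng(5)
        shape = (120, 140)
        chans = {n: rng.uniform(0, 50, shape) for n in ("nuclear", "red", "green")}
        img = MultiplexImage(channels=chans, pixel_size_um=1.0)
        centers = [(15.0, 15.0), (60.0, 40.0), (120.0, 100.0), (0.0, 119.0)]
        dp = DetectionParams(
            cell_radius_um=10.0,
            red_threshold_mode="fixed:25",
            green_threshold_mode="fixed:25",
        )
        recs = classify_cells(img, centers, dp)

        r_px = 10
        for rec, (cx, cy) in zip(recs, centers):
            sums = {"nuclear": 0.0, "red": 0.0, "green": 0.0}
            count = 0
            for row in range(shape[0]):
                for col in range(shape[1]):
                    if (row - round(cy)) ** 2 + (col - round(cx)) ** 2 <= r_px**2:
                        count += 1
                        for n in sums:
                            sums[n] += chans[n][row, col]
            assert rec.mean_nuclear == pytest.approx(sums["nuclear"] / count, abs=1e-12)
            assert rec.mean_red == pytest.approx(sums["red"] / count, abs=1e-12)
            assert rec.mean_green == pytest.approx(sums["green"] / count, abs=1e-12)
            assert rec.compartment == ("tumor" if sums["red"] / count > 25 else "normal")
            assert rec.marker == ("positive" if sums["green"] / count > 25 else "negative")


class TestQuantify:
    def test_endpoint_arithmetic(self):
        recs = [
            CellRecord((0, 0), 0, 0, 0, "tumor", "positive"),
            CellRecord((1, 0), 0, 0, 0, "tumor", "positive"),
            CellRecord((2, 0), 0, 0, 0, "tumor", "negative"),
            CellRecord((3, 0), 0, 0, 0, "normal", "negative"),
        ]
        q = quantify_spheroid(recs)
        assert (q.n_total, q.n_tumor, q.n_normal) == (4, 3, 1)
        assert q.pct_tumor == pytest.approx(75.0)
        assert q.pct_marker_tumor == pytest.approx(66.6667, abs=1e-3)
        assert q.pct_marker_normal == pytest.approx(0.0)

    def test_all_tumor_leaves_normal_pct_missing(self):
        recs = [CellRecord((i, 0), 0, 0, 0, "tumor", "negative") for i in range(5)]
        q = quantify_spheroid(recs)
        assert q.pct_tumor == 100.0
        assert q.pct_marker_normal is None

    def test_empty_records_all_missing(self):
        q = quantify_spheroid([])
        assert q.n_total == 0
        assert q.pct_tumor is None
        assert q.pct_marker_tumor is None
        assert q.pct_marker_normal is None

    def test_counts_partition_total(self, fast_section):
        params, image, _ = fast_section
        dp = DetectionParams()
        centers = detect_nuclei(image.nuclear, dp, image.pixel_size_um)
        q = quantify_spheroid(classify_cells(image, centers, dp))
        assert q.n_tumor + q.n_normal == q.n_total == len(centers)
        assert q.n_marker_tumor <= q.n_tumor and q.n_marker_normal <= q.n_normal

    def test_injected_fractions_recovered(self):
        """Generated tumor 40% / marker-tumor 60% recovered within 5 points."""
        p = SectionParams(
            n_cells=400, seed=17, tumor_fraction=0.4,
            marker_frac_tumor=0.6, marker_frac_normal=0.05, pixel_size_um=1.0,
        )
        image, _ = generate_section(p)
        dp = DetectionParams()
        centers = detect_nuclei(image.nuclear, dp, image.pixel_size_um)
        q = quantify_spheroid(classify_cells(image, centers, dp))
        assert q.pct_tumor == pytest.approx(40.0, abs=5.0)
        assert q.pct_marker_tumor == pytest.approx(60.0, abs=5.0)

    def test_label_list_mismatch_rejected(self):
        with pytest.raises(ValueError):
            quantify_labels(["tumor"], [])
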