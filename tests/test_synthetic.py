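"""Generator contracts: exact label allocation, geometry, determinism."""

import numpy as np
import pandas as pd
import pytest

from microtma import (
    EndmemberMatrix,
    IntensityLevels,
    SectionParams,
    TMALayout,
    generate_section,
    generate_spectral_stack,
    generate_tma_slide,
    generate_viability_plate,
)


class TestSectionGeneration:
    def test_exact_tumor_normal_allocation(self):
        params = SectionParams(n_cells=100, tumor_fraction=0.5, seed=1)
        _, truth = generate_section(params)
        counts = truth.cells["compartment"].value_counts()
        assert counts["tumor"] == 50
        assert counts["normal"] == 50

    def test_empty_section_is_background_only(self):
        params = SectionParams(n_cells=0, seed=2, noise_sd=0.0)
        image, truth = generate_section(params)
        assert truth.n_cells == 0
        for name, ch in image.channels.items():
            assert np.allclose(ch, params.intensity_levels.background), name

    def test_same_seed_bit_identical(self):
        p = SectionParams(n_cells=150, seed=33)
        img1, t1 = generate_section(p)
        img2, t2 = generate_section(SectionParams(n_cells=150, seed=33))
        for name in img1.channels:
            np.testing.assert_array_equal(img1.channels[name], img2.channels[name])
        pd.testing.assert_frame_equal(t1.cells, t2.cells)

    def test_different_seeds_differ(self):
        img1, _ = generate_section(SectionParams(n_cells=150, seed=1))
        img2, _ = generate_section(SectionParams(n_cells=150, seed=2))
        assert not np.array_equal(img1.nuclear, img2.nuclear)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    @pytest.mark.parametrize("n_cells", [50, 400])
    def test_geometry_invariants(self, seed, n_cells):
        """Centres inside the spheroid disc, pairwise >= one nucleus radius."""
        params = SectionParams(n_cells=n_cells, seed=seed, pixel_size_um=1.0)
        _, truth = generate_section(params)
        xy = truth.cells[["x", "y"]].to_numpy()
        cx, cy = truth.disc_center_px
        r = np.hypot(xy[:, 0] - cx, xy[:, 1] - cy)
        assert (r <= truth.disc_radius_px + 1e-9).all()
        from scipy.spatial.distance import pdist

        min_sep = params.nucleus_radius_um / params.pixel_size_um
        assert pdist(xy).min() >= min_sep - 1e-9

    def test_marker_counts_exact_per_compartment(self):
        params = SectionParams(
            n_cells=200, tumor_fraction=0.4, marker_frac_tumor=0.25,
            marker_frac_normal=0.1, seed=5,
        )
        _, truth = generate_section(params)
        df = truth.cells
        tumor = df[df.compartment == "tumor"]
        normal = df[df.compartment == "normal"]
        assert (tumor.marker == "positive").sum() == round(0.25 * len(tumor))
        assert (normal.marker == "positive").sum() == round(0.1 * len(normal))

    def test_true_quant_consistent_with_labels(self):
        params = SectionParams(n_cells=80, tumor_fraction=0.75, seed=9)
        _, truth = generate_section(params)
        q = truth.true_quant()
        assert q.n_tumor + q.n_normal == q.n_total == 80
        assert q.pct_tumor == pytest.approx(100 * q.n_tumor / 80)

    def test_overpacking_raises_with_capacity(self):
        params = SectionParams(n_cells=5000, seed=0)
        with pytest.raises(ValueError, match="capacity"):
            generate_section(params)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tumor_fraction": 1.5},
            {"marker_frac_tumor": -0.1},
            {"n_cells": -1},
            {"spheroid_diameter_um": 0},
            {"noise_sd": -1.0},
            {"pixel_size_um": 0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SectionParams(**kwargs)


class TestTMASlide:
    def _layout(self, rows, cols, pitch=500.0, skip=()):
        tmap = {
            (r, c): f"t{(r * cols + c) % 3}"
            for r in range(rows)
            for c in range(cols)
            if (r, c) not in skip
        }
        return TMALayout(rows=rows, cols=cols, spot_pitch_um=pitch, treatment_map=tmap)

    def test_full_2x3_slide(self):
        layout = self._layout(2, 3)
        params = SectionParams(pixel_size_um=1.0, n_cells=60)
        slide, truths, boxes = generate_tma_slide(layout, params, seed=1)
        assert len(truths) == 6 and len(boxes) == 6
        # ground-truth boxes are pairwise disjoint
        bx = list(boxes.values())
        for i in range(len(bx)):
            for j in range(i + 1, len(bx)):
                x0, y0, x1, y1 = bx[i]
                a0, b0, a1, b1 = bx[j]
                assert x1 <= a0 or a1 <= x0 or y1 <= b0 or b1 <= y0

    def test_unoccupied_spot_left_blank(self):
        layout = self._layout(2, 3, skip={(1, 1)})
        params = SectionParams(pixel_size_um=1.0, n_cells=60)
        slide, truths, boxes = generate_tma_slide(layout, params, seed=1)
        assert len(truths) == 5
        assert (1, 1) not in truths

    def test_96_spot_box_side_matches_pixel_size(self):
        """A 350 um spheroid at 0.5 um/px must occupy a ~700 px box."""
        layout = self._layout(8, 12)
        params = SectionParams(pixel_size_um=0.5, n_cells=30)
        _, truths, boxes = generate_tma_slide(layout, params, seed=3)
        assert len(boxes) == 96
        for (x0, y0, x1, y1) in boxes.values():
            assert abs((x1 - x0) - 700) <= 1
            assert abs((y1 - y0) - 700) <= 1

    def test_spot_larger_than_pitch_rejected(self):
        layout = self._layout(2, 2, pitch=300.0)
        params = SectionParams(pixel_size_um=1.0)  # 350 um spheroid
        with pytest.raises(ValueError, match="pitch"):
            generate_tma_slide(layout, params, seed=0)

    def test_slide_determinism(self):
        layout = self._layout(1, 2)
        params = SectionParams(pixel_size_um=1.0, n_cells=40)
        s1, t1, _ = generate_tma_slide(layout, params, seed=11)
        s2, t2, _ = generate_tma_slide(layout, params, seed=11)
        np.testing.assert_array_equal(s1.nuclear, s2.nuclear)
        for key in t1:
            pd.testing.assert_frame_equal(t1[key].cells, t2[key].cells)

    def test_grid_capped_at_96_wells(self):
        with pytest.raises(ValueError, match="96"):
            TMALayout(rows=10, cols=12, spot_pitch_um=500, treatment_map={})


class TestSpectralForwardModel:
    def test_identity_endmembers_reproduce_channels(self, fast_section):
        _, image, _ = fast_section
        em = EndmemberMatrix(
            matrix=np.eye(3), names=["nuclear", "red", "green"],
            wavelengths=[450.0, 570.0, 520.0],
        )
        stack = generate_spectral_stack(image, em)
        for i, name in enumerate(image.channels):
            np.testing.assert_allclose(stack.data[:, :, i], image.channels[name])

    def test_pure_autofluorescence_pixels(self):
        zero = np.zeros((4, 5), dtype=float)
        from microtma import MultiplexImage

        img = MultiplexImage(
            channels={"nuclear": zero, "red": zero, "green": zero}, pixel_size_um=1.0
        )
        em = EndmemberMatrix(
            matrix=np.array(
                [[1, 0, 0, 1.0], [0, 1, 0, 1.0], [0, 0, 1, 1.0], [0, 0, 0, 1.0]]
            ),
            names=["nuclear", "red", "green", "AF"],
            wavelengths=[450.0, 520, 570, 620],
        )
        c = 3.5
        stack = generate_spectral_stack(img, em, af_abundance_map=np.full((4, 5), c))
        np.testing.assert_allclose(stack.data, c)

    def test_dimension_mismatch_rejected(self, fast_section):
        _, image, _ = fast_section
        em = EndmemberMatrix(
            matrix=np.eye(2), names=["a", "b"], wavelengths=[450.0, 520.0]
        )
        with pytest.raises(ValueError, match="channels"):
            generate_spectral_stack(image, em)
        em3 = EndmemberMatrix(
            matrix=np.eye(3), names=["nuclear", "red", "green"],
            wavelengths=[450.0, 520.0, 570.0],
        )
        with pytest.raises(ValueError, match="shape"):
            generate_spectral_stack(image, em3, af_abundance_map=np.zeros((2, 2)))


class TestViabilityPlate:
    def test_zero_sd_reproduces_means(self):
        plate = generate_viability_plate(
            ["c", "d1"], [1000.0, 400.0], sd=0.0, n_replicates=3, seed=1
        )
        np.testing.assert_allclose(plate.values["c"], 1000.0)
        np.testing.assert_allclose(plate.values["d1"], 400.0)

    def test_replicate_counts(self):
        plate = generate_viability_plate(
            [f"d{i}" for i in range(6)], [100.0] * 6, sd=5.0, n_replicates=3, seed=2
        )
        assert sum(v.size for v in plate.values.values()) == 18

    def test_large_sample_mean_matches(self):
        """CLT check: with n=10^4 the sample mean sits within 3*sd/sqrt(n)."""
        n = 10_000
        plate = generate_viability_plate(
            ["c"], [500.0], sd=20.0, n_replicates=n, seed=3
        )
        assert abs(plate.values["c"].mean() - 500.0) < 3 * 20.0 / np.sqrt(n)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="sd"):
            generate_viability_plate(["c"], [100.0], sd=-1.0)
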