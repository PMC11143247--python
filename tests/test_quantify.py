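"""Image quantification: background, grid fitting, integrated intensities."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import riboscreen as rs
from riboscreen.quantify import GridDetectionError

from conftest import gradient_only_truth


class TestBackground:
    def test_constant_image_recovered(self):
        img = np.full((120, 150), 10.0)
        bg = rs.estimate_background(img, 31)
        assert np.allclose(bg, 10.0)

    def test_zero_image_gives_zero(self):
        bg = rs.estimate_background(np.zeros((100, 100)), 31)
        assert np.allclose(bg, 0.0)

    def test_window_larger_than_image_errors(self):
        with pytest.raises(ValueError, match="window"):
            rs.estimate_background(np.zeros((50, 50)), 51)

    def test_planar_background_recovered_under_colonies(self, spec):
        """Planted tilted-plane background recovered within 2% away from
        colonies."""
        pmap = rs.generate_plate_map(spec, 1400, 0, seed=4)
        strains = sorted(set(pmap["strain_id"]) - {rs.EMPTY})
        truth = gradient_only_truth(
            strains, amplitude=1.0, noise_cv=0.0, seed=4,
            background_level=200.0, background_tilt=(0.05, -0.03),
            read_noise_sd=0.5,
        )
        pairs, _ = rs.simulate_colony_plates(pmap, spec, truth, "WT", "24h")
        img = pairs[0].biomass_image.astype(float)
        h, w = img.shape
        plane = (truth.background_level
                 + truth.background_tilt[0] * np.arange(h)[:, None]
                 + truth.background_tilt[1] * np.arange(w)[None, :])
        bg = rs.estimate_background(img, 41)
        # colony-free mask: > 8 px from every grid node
        yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        ny = (yy - spec.margin_px) % spec.pitch_px
        nx = (xx - spec.margin_px) % spec.pitch_px
        dist = np.hypot(np.minimum(ny, spec.pitch_px - ny),
                        np.minimum(nx, spec.pitch_px - nx))
        free = dist > 8
        rel = np.abs(bg[free] - plane[free]) / plane[free]
        assert np.median(rel) < 0.02
        # residuals on colony-free pixels centered near zero
        resid = img[free] - bg[free]
        assert abs(np.median(resid)) < 0.02 * truth.background_level


class TestSubtract:
    def test_exact_and_clipped(self):
        assert rs.subtract_background(np.full((3, 3), 10.0),
                                      np.full((3, 3), 10.0)).sum() == 0
        out = rs.subtract_background(np.full((3, 3), 5.0),
                                     np.full((3, 3), 10.0))
        assert (out == 0).all()

    def test_shape_mismatch_errors(self):
        with pytest.raises(ValueError, match="shape"):
            rs.subtract_background(np.zeros((3, 3)), np.zeros((3, 4)))

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_naive_loop(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 500, size=(12, 9)).astype(float)
        bg = rng.integers(0, 500, size=(12, 9)).astype(float)
        out = rs.subtract_background(img, bg)
        for i in range(12):
            for j in range(9):
                assert out[i, j] == max(img[i, j] - bg[i, j], 0.0)


class TestGrid:
    def test_known_geometry_recovered(self, small_screen, spec):
        geom = rs.detect_grid(small_screen["pair"].biomass_image, spec)
        assert geom.pitch_yx[0] == pytest.approx(spec.pitch_px, abs=0.2)
        assert geom.pitch_yx[1] == pytest.approx(spec.pitch_px, abs=0.2)
        assert geom.origin_yx[0] == pytest.approx(spec.margin_px, abs=1.0)
        assert geom.origin_yx[1] == pytest.approx(spec.margin_px, abs=1.0)
        assert geom.nodes.shape == (32, 48, 2)

    def test_translated_plate_offset_recovered(self, small_screen, spec):
        img = np.roll(small_screen["pair"].biomass_image, (5, 7), axis=(0, 1))
        geom = rs.detect_grid(img, spec)
        assert geom.origin_yx[0] == pytest.approx(spec.margin_px + 5, abs=1.0)
        assert geom.origin_yx[1] == pytest.approx(spec.margin_px + 7, abs=1.0)

    def test_blank_image_fails_with_diagnostic(self, spec):
        img = np.full(spec.image_shape, 100, dtype=np.uint16)
        with pytest.raises(GridDetectionError, match="peaks"):
            rs.detect_grid(img, spec)


class TestMeasure:
    def test_ones_roi_sums_area(self):
        img = np.ones((40, 40))
        total, area, clipped = rs.measure_colony(img, (20, 20), 5)
        assert total == area == 121  # 11 x 11 square
        assert not clipped

    def test_sum_not_mean(self):
        img = np.tile(np.array([0.0, 2.0, 4.0]), (9, 3))
        total, area, _ = rs.measure_colony(img, (4, 4), 4)
        assert total == 9 * 3 * 6.0  # the integrated sum, not the mean 2.0

    def test_edge_roi_clipped_and_flagged(self):
        img = np.ones((20, 20))
        total, area, clipped = rs.measure_colony(img, (1, 1), 5)
        assert clipped
        assert total == area < 121

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.integers(0, 1000, size=(30, 30))
        cy, cx = rng.integers(5, 25, size=2)
        half = int(rng.integers(1, 5))
        total, _, _ = rs.measure_colony(img, (float(cy), float(cx)), half)
        acc = 0
        for i in range(cy - half, cy + half + 1):
            for j in range(cx - half, cx + half + 1):
                acc += int(img[i, j])
        assert total == acc

    def test_linearity_in_image_scale(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, size=(25, 25))
        t1, _, _ = rs.measure_colony(img, (12, 12), 6)
        t3, _, _ = rs.measure_colony(3.0 * img, (12, 12), 6)
        assert t3 == pytest.approx(3.0 * t1, rel=1e-12)


class TestQuantifyPlate:
    def test_zero_noise_proportional_to_planted(self, spec):
        pmap = rs.generate_plate_map(spec, 1300, 0, seed=6)
        strains = sorted(set(pmap["strain_id"]) - {rs.EMPTY})
        truth = gradient_only_truth(strains, amplitude=1.5, noise_cv=0.0,
                                    seed=6, biomass_edge_amplitude=1.3,
                                    read_noise_sd=0.0)
        pairs, tdf = rs.simulate_colony_plates(pmap, spec, truth, "WT", "24h")
        table = rs.quantify_plate(pairs[0], pmap, spec)
        assert len(table) == 1536
        mm = table.merge(tdf, on=["plate_id", "row", "col", "strain_id"])
        occ = mm[mm["strain_id"] != rs.EMPTY]
        r_b = np.corrcoef(occ["biomass_sum"], occ["planted_biomass"])[0, 1]
        r_f = np.corrcoef(occ["fluor_sum"], occ["planted_fluor"])[0, 1]
        assert r_b > 0.999
        assert r_f > 0.999

    def test_empty_flagged_with_near_zero_fluorescence(self, quantified):
        empty = quantified[quantified["flags"].str.contains("EMPTY")]
        occ = quantified[~quantified["flags"].str.contains("EMPTY")]
        assert (empty["strain_id"] == rs.EMPTY).all()
        assert empty["fluor_sum"].median() < 0.05 * occ["fluor_sum"].median()

    def test_one_row_per_map_entry(self, quantified, spec):
        assert len(quantified) == spec.density

    def test_translation_robustness(self, small_screen, spec):
        """Shifting the plate by < pitch/3 changes colony sums by < 2%."""
        pair = small_screen["pair"]
        shifted = rs.PlateImagePair(
            np.roll(pair.biomass_image, (5, 6), axis=(0, 1)),
            np.roll(pair.fluor_image, (5, 6), axis=(0, 1)),
            pair.plate_id, pair.replicate_id, pair.timepoint, pair.reporter,
        )
        a = rs.quantify_plate(pair, small_screen["map"], spec)
        b = rs.quantify_plate(shifted, small_screen["map"], spec)
        occ = (a["strain_id"] != rs.EMPTY).to_numpy()
        # ignore the image-border ring, which the roll wraps around
        inner = occ & (a["row"] > 1) & (a["col"] > 1) & \
            (a["row"] < spec.n_rows) & (a["col"] < spec.n_cols)
        rel = np.abs(b.loc[inner, "biomass_sum"].to_numpy()
                     / a.loc[inner, "biomass_sum"].to_numpy() - 1)
        assert np.quantile(rel, 0.99) < 0.02
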