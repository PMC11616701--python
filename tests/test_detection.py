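"""Detection pipeline: background, segmentation, measurement, filtering."""

import numpy as np
import pandas as pd
import pytest

from vdcyto.detection import (
    DetectionConfig,
    FrameRejected,
    estimate_background,
    estimate_velocity,
    measure_cell,
    presence_filter,
    process_sequence,
    segment_frame,
)
from vdcyto.io_formats import ArraySequence
from vdcyto.pipeline import measure_population
from vdcyto.shapes import bullet_shape, solve_bullet_parameter
from vdcyto.synth import ImagingConfig, PopulationSpec, render_frame, render_population

from conftest import place_shape

SQUARE_DEFICIT = 1.0 - np.sqrt(np.pi) / 2.0


class TestEstimateBackground:
    def test_mean_of_constant_frames(self):
        frames = [np.full((8, 16), 100.0), np.full((8, 16), 102.0)]
        bg = estimate_background(frames, method="mean")
        assert np.allclose(bg.image, 101.0)

    def test_noise_sd_of_known_gaussian(self):
        rng = np.random.default_rng(3)
        frames = [100.0 + rng.normal(0, 2.0, (40, 60)) for _ in range(200)]
        bg = estimate_background(frames)
        assert bg.noise_sd == pytest.approx(2.0, rel=0.1)

    def test_median_robust_to_transiting_cells(self):
        # one dark blob per frame at changing positions, ~5% pixel occupancy
        rng = np.random.default_rng(4)
        frames = []
        for _ in range(100):
            f = 180.0 + rng.normal(0, 2.0, (40, 40))
            r, c = rng.integers(0, 32, 2)
            f[r : r + 8, c : c + 8] -= 80.0
            frames.append(f)
        bg = estimate_background(frames)
        # bias stays within a fraction of a count (noise floor dominates)
        assert np.abs(bg.image - 180.0).mean() < 0.5
        assert np.abs(bg.image - 180.0).max() < 2.0

    def test_single_frame_warns(self):
        with pytest.warns(UserWarning, match="single-frame"):
            bg = estimate_background([np.full((4, 4), 7.0)])
        assert np.allclose(bg.image, 7.0)


class TestSegmentFrame:
    def test_cell_free_noise_has_no_candidates(self, imaging, flat_background):
        config = DetectionConfig()
        hits = 0
        for seed in range(5):
            frame = render_frame([], imaging, seed=seed)
            bg = flat_background
            bg = type(bg)(bg.image, bg.noise_sd_image * 0 + 6.3, 6.3)
            hits += len(segment_frame(frame, bg, config))
        assert hits == 0

    def test_noise_free_disk_area(self, imaging, flat_background):
        cell = place_shape(bullet_shape(0.0, base_radius_um=5.0), 128.3, 20.2)
        frame = render_frame([cell], imaging, noise=False)
        contours = segment_frame(frame, flat_background, DetectionConfig())
        assert len(contours) == 1
        rec = measure_cell(contours[0], frame, imaging)
        assert rec.area_um2 == pytest.approx(np.pi * 25.0, rel=0.02)
        assert rec.perimeter_um == pytest.approx(2 * np.pi * 5.0, rel=0.02)
        assert abs(rec.deformability) <= 0.005

    def test_two_cells_two_channels(self, imaging, flat_background):
        c1 = place_shape(bullet_shape(0.5, base_radius_um=4.0), 25.6, 20.0)
        c2 = place_shape(bullet_shape(0.5, base_radius_um=4.0), 128.0, 20.0)
        frame = render_frame([c1, c2], imaging, noise=False)
        contours = segment_frame(frame, flat_background, DetectionConfig())
        assert len(contours) == 2
        channels = {measure_cell(c, frame, imaging).channel_id for c in contours}
        assert channels == {0, 2}

    def test_saturated_frame_rejected(self, imaging, flat_background):
        frame = np.full((imaging.roi_height_px, imaging.roi_width_px), 255, np.uint8)
        with pytest.raises(FrameRejected, match="saturated"):
            segment_frame(frame, flat_background, DetectionConfig())

    def test_shape_mismatch_error(self, flat_background):
        with pytest.raises(ValueError, match="shapes differ"):
            segment_frame(np.zeros((4, 4)), flat_background, DetectionConfig())


class TestMeasureCell:
    def test_ideal_circle_deformability(self, imaging):
        frame = np.full((80, 1024), 180, np.uint8)
        t = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        contour = np.column_stack([512 + 12 * np.cos(t), 40 + 12 * np.sin(t)])
        rec = measure_cell(contour, frame, imaging)
        assert abs(rec.deformability) <= 0.005
        assert rec.area_ratio == pytest.approx(1.0, abs=1e-6)

    def test_square_contour_closed_form(self, imaging):
        frame = np.full((80, 1024), 180, np.uint8)
        side = 20.0
        t = np.linspace(0, 4, 256, endpoint=False)
        pts = []
        for u in t:
            if u < 1:
                pts.append((500 + side * u, 30.0))
            elif u < 2:
                pts.append((500 + side, 30 + side * (u - 1)))
            elif u < 3:
                pts.append((500 + side - side * (u - 2), 30 + side))
            else:
                pts.append((500.0, 30 + side - side * (u - 3)))
        rec = measure_cell(np.array(pts), frame, imaging)
        assert rec.deformability == pytest.approx(SQUARE_DEFICIT, abs=1e-6)

    def test_ellipse_aspect_ratio(self, imaging):
        frame = np.full((80, 1024), 180, np.uint8)
        t = np.linspace(0, 2 * np.pi, 512, endpoint=False)
        contour = np.column_stack([512 + 20 * np.cos(t), 40 + 10 * np.sin(t)])
        rec = measure_cell(contour, frame, imaging)
        assert rec.aspect_ratio == pytest.approx(2.0, abs=0.05)

    def test_brightness_inside_contour(self, imaging):
        frame = np.full((80, 1024), 200, np.uint8)
        frame[30:51, 500:521] = 90
        t = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        contour = np.column_stack([510 + 8 * np.cos(t), 40 + 8 * np.sin(t)])
        rec = measure_cell(contour, frame, imaging)
        assert rec.brightness == pytest.approx(90.0, abs=1.0)

    def test_degenerate_contour_rejected(self, imaging):
        frame = np.full((80, 1024), 180, np.uint8)
        tiny = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        rec = measure_cell(tiny, frame, imaging)
        assert not rec.accepted and rec.reject_reason == "degenerate"


class TestPresenceFilter:
    def test_convex_cell_accepted(self, imaging, flat_background):
        cell = place_shape(bullet_shape(1.0, base_radius_um=4.0), 128.0, 20.0)
        frame = render_frame([cell], imaging, noise=False)
        (contour,) = segment_frame(frame, flat_background, DetectionConfig())
        rec = measure_cell(contour, frame, imaging)
        ok, reason = presence_filter(rec, DetectionConfig(), imaging)
        assert ok and reason == ""
        assert rec.area_ratio <= 1.05

    def test_crescent_rejected_by_area_ratio(self, imaging):
        # open "C" (annular arc): convex hull much larger than enclosed area
        frame = np.full((80, 1024), 180, np.uint8)
        a0, a1 = np.deg2rad(40), np.deg2rad(320)
        t_out = np.linspace(a0, a1, 128)
        t_in = np.linspace(a1, a0, 128)
        crescent = np.vstack([
            np.column_stack([512 + 15 * np.cos(t_out), 40 + 15 * np.sin(t_out)]),
            np.column_stack([512 + 9 * np.cos(t_in), 40 + 9 * np.sin(t_in)]),
        ])
        rec = measure_cell(crescent, frame, imaging)
        assert rec.area_ratio > 1.3
        ok, reason = presence_filter(rec, DetectionConfig(), imaging)
        assert not ok and reason == "area_ratio"

    def test_border_cell_rejected(self, imaging):
        frame = np.full((80, 1024), 180, np.uint8)
        t = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        contour = np.column_stack([512 + 8 * np.cos(t), 8 + 8 * np.sin(t)])
        rec = measure_cell(contour, frame, imaging)
        ok, reason = presence_filter(rec, DetectionConfig(border_margin_px=3), imaging)
        assert not ok and reason == "border"

    def test_area_bounds(self, imaging):
        frame = np.full((80, 1024), 180, np.uint8)
        t = np.linspace(0, 2 * np.pi, 128, endpoint=False)
        small = np.column_stack([512 + 3 * np.cos(t), 40 + 3 * np.sin(t)])
        rec = measure_cell(small, frame, imaging)
        ok, reason = presence_filter(rec, DetectionConfig(), imaging)
        assert not ok and reason == "area_min"


class TestProcessSequence:
    def test_empty_sequence(self, imaging):
        table = process_sequence(ArraySequence(np.zeros((0, 8, 8), np.uint8), imaging))
        assert len(table) == 0
        assert table.attrs["counters"]["frames"] == 0

    def test_clean_stream_detects_every_cell(self):
        spec = PopulationSpec("s", mean_D=0.06, sd_D=0.015,
                              mean_area_um2=60.0, sd_area_um2=8.0)
        table, manifest = measure_population(spec, 200, seed=5)
        n_clipped = sum(c.border_clipped for c in manifest.cells)
        assert n_clipped == 0
        assert int(table["accepted"].sum()) == len(manifest.cells)

    def test_idempotent(self):
        spec = PopulationSpec("s", mean_D=0.05, sd_D=0.01,
                              mean_area_um2=40.0, sd_area_um2=4.0)
        frames, manifest = render_population(spec, 40, seed=6)
        seq = ArraySequence(frames, manifest.config)
        t1 = process_sequence(seq)
        t2 = process_sequence(seq)
        pd.testing.assert_frame_equal(t1, t2)

    def test_counters_logged(self, tmp_path):
        spec = PopulationSpec("s", mean_D=0.05, sd_D=0.01,
                              mean_area_um2=40.0, sd_area_um2=4.0)
        frames, manifest = render_population(spec, 20, seed=6)
        log = tmp_path / "run.log"
        process_sequence(ArraySequence(frames, manifest.config), log_path=log)
        text = log.read_text()
        assert "frames=" in text and "accepted=" in text


class TestEstimateVelocity:
    @staticmethod
    def _row(frame, channel, x_um, y_um):
        return {
            "frame_index": frame, "channel_id": channel,
            "centroid_x_um": x_um, "centroid_y_um": y_um,
            "area_um2": 50.0, "perimeter_um": 30.0, "deformability": 0.05,
            "brightness": 100.0, "aspect_ratio": 1.2, "area_ratio": 1.0,
            "accepted": True, "reject_reason": "",
        }

    def test_known_displacement(self):
        # 0.2 m/s at 10 kHz and 0.5 um/px -> 40 px = 20 um per frame
        imaging = ImagingConfig(frame_rate_hz=10000.0)
        table = pd.DataFrame([
            self._row(0, 1, 76.8, 10.0),
            self._row(1, 1, 76.8, 30.0),
        ])
        v = estimate_velocity(table, imaging)
        assert v.iloc[0] == pytest.approx(0.2, rel=1e-6)

    def test_single_appearance_no_estimate(self):
        imaging = ImagingConfig(frame_rate_hz=10000.0)
        table = pd.DataFrame([self._row(0, 1, 76.8, 10.0)])
        v = estimate_velocity(table, imaging)
        assert np.isnan(v.iloc[0])

    def test_zero_displacement(self):
        imaging = ImagingConfig(frame_rate_hz=10000.0)
        table = pd.DataFrame([
            self._row(0, 1, 76.8, 10.0),
            self._row(1, 1, 76.8, 10.0),
        ])
        v = estimate_velocity(table, imaging)
        assert v.iloc[0] == 0.0

    def test_ambiguous_match_skipped(self):
        imaging = ImagingConfig(frame_rate_hz=10000.0)
        table = pd.DataFrame([
            self._row(0, 1, 76.8, 10.0),
            self._row(1, 1, 76.8, 14.0),
            self._row(1, 1, 76.8, 6.0),
        ])
        v = estimate_velocity(table, imaging)
        assert np.isnan(v.iloc[0])


class TestAccuracyInvariants:
    def test_measured_deformability_never_below_minus_epsilon(self):
        spec = PopulationSpec("s", mean_D=0.02, sd_D=0.015,
                              mean_area_um2=80.0, sd_area_um2=10.0)
        table, _ = measure_population(spec, 150, seed=8)
        acc = table[table["accepted"]]
        assert (acc["deformability"] >= -0.005).all()

    def test_monotone_measured_vs_true_deformability(self, imaging, flat_background):
        from scipy.stats import spearmanr

        measured = []
        for target in np.linspace(0.0, 0.25, 20):
            p = solve_bullet_parameter(target)
            shape = bullet_shape(p, base_radius_um=1.0)
            from vdcyto.shapes import shape_truth

            a1 = shape_truth(shape)[0]
            shape = shape.scaled(np.sqrt(95.0 / a1))
            cell = place_shape(shape, 128.0, 20.0, velocity=0.7)
            frame = render_frame([cell], imaging, noise=False)
            (contour,) = segment_frame(frame, flat_background, DetectionConfig())
            measured.append(measure_cell(contour, frame, imaging).deformability)
        assert np.all(np.diff(measured) > 0)
        assert spearmanr(measured, np.arange(20)).statistic == 1.0
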