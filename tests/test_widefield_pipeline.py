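"""Spot detection, ROI spectra, sweep decomposition, and the full pipeline."""

import dataclasses

import numpy as np
import pytest

from nvtherm import (
    AnalyzeConfig,
    ImageStack,
    MEAN_PARAMS,
    NoiseModel,
    SceneConfig,
    Spectrum,
    SweepGrid,
    analyze_stack,
    decompose_sweep,
    detect_bright_spots,
    extract_spot_spectrum,
    generate_widefield_stack,
)
from nvtherm.widefield_pipeline import SpotROI


class TestDetectBrightSpots:
    def test_blank_image_yields_nothing(self):
        assert detect_bright_spots(np.zeros((64, 64)), 0.5) == []

    def test_single_clean_blob_found_within_one_pixel(self, clean_single_spot_scene):
        stack, truth = generate_widefield_stack(clean_single_spot_scene, 21)
        rois = detect_bright_spots(stack.mean_image(), stack.pixel_size_um)
        assert len(rois) == 1
        spot = truth.spots[0]
        assert abs(rois[0].center[0] - spot.row) <= 1.0
        assert abs(rois[0].center[1] - spot.col) <= 1.0

    def test_many_spots_recall_against_ground_truth(self):
        scene = SceneConfig(
            image_shape=(220, 220), n_spots=20, n_repeats=2,
            background=10.0, background_noise_sd=2.0, brightness=500.0,
            grid=SweepGrid(2850, 2890, 12),
        )
        stack, truth = generate_widefield_stack(scene, 22)
        rois = detect_bright_spots(stack.mean_image(), stack.pixel_size_um)
        matched = 0
        for spot in truth.spots:
            if any(
                np.hypot(r.center[0] - spot.row, r.center[1] - spot.col) < 3
                for r in rois
            ):
                matched += 1
        assert matched >= 0.95 * len(truth.spots)
        assert len(rois) - matched <= 1  # at most one false positive


class TestExtractSpotSpectrum:
    def test_uniform_stack_gives_flat_unit_spectrum(self):
        grid = SweepGrid(2850, 2890, 20)
        stack = ImageStack(
            data=np.full((40, 64, 64), 7.0), grid=grid, n_repeats=2,
            pixel_size_um=0.5,
        )
        spec = extract_spot_spectrum(stack, SpotROI(0, (32, 32)), 0)
        assert np.allclose(spec.intensities, 1.0)

    def test_repeat_index_bounds(self):
        grid = SweepGrid(2850, 2890, 20)
        stack = ImageStack(
            data=np.ones((40, 64, 64)), grid=grid, n_repeats=2, pixel_size_um=0.5
        )
        with pytest.raises(IndexError):
            extract_spot_spectrum(stack, SpotROI(0, (32, 32)), 2)

    def test_roi_outside_image_rejected(self):
        grid = SweepGrid(2850, 2890, 20)
        stack = ImageStack(
            data=np.ones((40, 64, 64)), grid=grid, n_repeats=2, pixel_size_um=0.5
        )
        with pytest.raises(ValueError):
            extract_spot_spectrum(stack, SpotROI(0, (2, 2)), 0)


class TestDecomposeSweep:
    def test_standard_hundred_point_composition(self):
        grid = SweepGrid(2850.0, 2890.0, 100)
        spec = Spectrum(grid, np.arange(100, dtype=float) + 1, sweep_time=2.0)
        narrow, wide = decompose_sweep(spec)
        assert narrow.grid.f_start == pytest.approx(2860.0)
        assert narrow.grid.f_end == pytest.approx(2880.0)
        assert narrow.grid.n_points == 50
        assert narrow.grid.spacing == pytest.approx(0.4)
        assert wide.grid.f_start == pytest.approx(2850.0)
        assert wide.grid.f_end == pytest.approx(2890.0)
        assert wide.grid.spacing == pytest.approx(0.8)
        assert narrow.sweep_time == wide.sweep_time == 1.0

    def test_lossless_exact_subset(self):
        grid = SweepGrid(2850.0, 2890.0, 100)
        rng = np.random.default_rng(1)
        spec = Spectrum(grid, rng.random(100), sweep_time=2.0)
        narrow, wide = decompose_sweep(spec)
        parent = {f: v for f, v in zip(spec.frequencies, spec.intensities)}
        for sub in (narrow, wide):
            for f, v in zip(sub.frequencies, sub.intensities):
                match = [pf for pf in parent if abs(pf - f) < 1e-9]
                assert len(match) == 1
                assert parent[match[0]] == v

    def test_eight_point_toy_grid(self):
        spec = Spectrum(SweepGrid(0.0, 8.0, 8), np.arange(8.0), sweep_time=0.16)
        narrow, wide = decompose_sweep(spec)
        assert np.array_equal(narrow.intensities, [2, 3, 4, 5])
        assert np.array_equal(wide.intensities, [0, 2, 4, 6])
        assert np.array_equal(narrow.frequencies, [2, 3, 4, 5])
        assert np.array_equal(wide.frequencies, [0, 2, 4, 6])

    def test_indivisible_grid_rejected(self):
        spec = Spectrum(SweepGrid(0.0, 10.0, 10), np.ones(10), sweep_time=0.2)
        with pytest.raises(ValueError):
            decompose_sweep(spec)


class TestAnalyzeStack:
    def test_noiseless_stack_all_ties(self, clean_single_spot_scene):
        scene = dataclasses.replace(clean_single_spot_scene, n_repeats=5)
        stack, _ = generate_widefield_stack(scene, 30)
        reports, summary = analyze_stack(stack)
        assert summary.n_spots == 1
        rep = reports[0]
        assert rep.narrow.sd_accuracy.value < 1e-3
        assert rep.wide.sd_accuracy.value < 1e-3
        assert rep.winner == "tie"
        assert summary.n_ties == 1

    def test_injected_d_jitter_read_back_as_unity(self, clean_single_spot_scene):
        # parameters redrawn per repeat with SD(D) = 0.077 MHz and no
        # intensity noise: both sub-sweeps must read ~1.0 K/Hz^1/2
        scene = dataclasses.replace(
            clean_single_spot_scene, n_repeats=100, d_jitter_sd=0.077
        )
        stack, _ = generate_widefield_stack(scene, 31)
        reports, _ = analyze_stack(stack)
        rep = reports[0]
        assert rep.narrow.sd_accuracy.value == pytest.approx(1.0, abs=0.15)
        assert rep.wide.sd_accuracy.value == pytest.approx(1.0, abs=0.15)

    def test_pipeline_deterministic(self):
        scene = SceneConfig(
            image_shape=(96, 96), n_spots=4, n_repeats=10, noise=NoiseModel(0.08),
            background=0.0, background_noise_sd=0.0,
        )
        stack, _ = generate_widefield_stack(scene, 32)
        _, s1 = analyze_stack(stack)
        _, s2 = analyze_stack(stack)
        assert s1 == s2

    def test_sd_and_fit_error_accuracies_agree(self):
        scene = SceneConfig(
            image_shape=(96, 96), n_spots=3, n_repeats=60, noise=NoiseModel(0.10),
            background=0.0, background_noise_sd=0.0, draw_params_per_spot=False,
        )
        stack, _ = generate_widefield_stack(scene, 33)
        reports, summary = analyze_stack(stack)
        assert summary.n_analyzed == 3
        for rep in reports:
            for res in (rep.narrow, rep.wide):
                assert res.fit_error_accuracy_mean == pytest.approx(
                    res.sd_accuracy.value, rel=0.25
                )

    def test_requires_two_repeats(self):
        grid = SweepGrid(2850, 2890, 20)
        stack = ImageStack(
            data=np.ones((20, 64, 64)), grid=grid, n_repeats=1, pixel_size_um=0.5
        )
        with pytest.raises(ValueError):
            analyze_stack(stack)

    def test_reports_csv_export(self, tmp_path):
        from nvtherm.widefield_pipeline import reports_to_csv

        scene = SceneConfig(
            image_shape=(96, 96), n_spots=2, n_repeats=5, noise=NoiseModel(0.05),
            background=0.0, background_noise_sd=0.0,
        )
        stack, _ = generate_widefield_stack(scene, 34)
        reports, _ = analyze_stack(stack)
        out = tmp_path / "spots.csv"
        reports_to_csv(reports, out)
        lines = out.read_text().strip().splitlines()
        assert lines[0] == "spot_id,range,method,accuracy_k_per_sqrthz"
        assert len(lines) >= 1 + 2 * len(reports)
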