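"""Parameter draws, noisy spectra, and synthetic wide-field stacks."""

import math

import numpy as np
import pytest

from nvtherm import (
    MEAN_PARAMS,
    NoiseModel,
    ParamDistribution,
    SceneConfig,
    SweepGrid,
    draw_params,
    evaluate_spectrum,
    generate_widefield_stack,
    simulate_replicates,
    simulate_spectrum,
)
from nvtherm.synthetic_data import GroundTruth


class TestDrawParams:
    def test_zero_sds_return_the_means(self):
        dist = ParamDistribution(sd_D=0, sd_E=0, sd_a1=0, sd_a2=0, sd_gamma=0)
        p = draw_params(dist, 0)
        assert p == dist.means()

    def test_sample_mean_of_d_matches_distribution(self):
        # SE of the mean over 1e4 draws is 1.31/100; allow 3 SEs
        dist = ParamDistribution()
        rng = np.random.default_rng(7)
        ds = np.array([draw_params(dist, rng).D for _ in range(10_000)])
        assert abs(ds.mean() - 2869.34) < 3 * 1.31 / 100

    def test_same_seed_is_deterministic(self):
        dist = ParamDistribution()
        assert draw_params(dist, 123) == draw_params(dist, 123)

    def test_invalid_means_rejected_at_construction(self):
        with pytest.raises(ValueError):
            # dip depth a1/(gamma*pi) >= 1 at the mean vector
            ParamDistribution(mean_gamma=5.07, mean_a1=16.5)

    def test_rejection_loop_bails_out(self):
        # valid means but draws almost surely violate the dip-depth bound
        dist = ParamDistribution(
            mean_gamma=1e-4, sd_gamma=0.0,
            mean_a1=0.0, sd_a1=1.0, mean_a2=0.0, sd_a2=1.0,
        )
        with pytest.raises(RuntimeError):
            draw_params(dist, 0)


class TestSimulateSpectrum:
    def test_zero_noise_identity(self, narrow_grid):
        spec = simulate_spectrum(MEAN_PARAMS, narrow_grid, NoiseModel(0.0), 0)
        clean = evaluate_spectrum(MEAN_PARAMS, narrow_grid.frequencies)
        assert np.array_equal(spec.intensities, clean)
        assert spec.sweep_time == pytest.approx(1.0)  # 50 points at 0.02 s

    def test_noise_sd_calibration(self):
        # residual SD must equal level * deeper-dip depth within 3% at 1e4 points
        grid = SweepGrid(2770, 2970, 10_000)
        spec = simulate_spectrum(MEAN_PARAMS, grid, NoiseModel(0.10), 42)
        resid = spec.intensities - evaluate_spectrum(MEAN_PARAMS, grid.frequencies)
        expected = 0.10 * 0.80 / (5.07 * math.pi)
        assert resid.std(ddof=1) == pytest.approx(expected, rel=0.03)

    def test_fixed_seed_bit_identical(self, narrow_grid):
        a = simulate_spectrum(MEAN_PARAMS, narrow_grid, NoiseModel(0.1), 5)
        b = simulate_spectrum(MEAN_PARAMS, narrow_grid, NoiseModel(0.1), 5)
        assert np.array_equal(a.intensities, b.intensities)

    def test_replicates_shape_and_common_draws(self, narrow_grid):
        z = np.random.default_rng(1).standard_normal((20, 50))
        a = simulate_replicates(MEAN_PARAMS, narrow_grid, NoiseModel(0.1), 20, 0, z)
        b = simulate_replicates(MEAN_PARAMS, narrow_grid, NoiseModel(0.2), 20, 0, z)
        assert a.shape == (20, 50)
        clean = evaluate_spectrum(MEAN_PARAMS, narrow_grid.frequencies)
        # same normals scaled by 2x the noise level: residuals double exactly
        assert np.allclose(2 * (a - clean), b - clean)


class TestWidefieldStack:
    def test_zero_spots_is_pure_background(self):
        scene = SceneConfig(
            image_shape=(48, 48), n_spots=0, n_repeats=2, background=50.0,
            background_noise_sd=1.0, grid=SweepGrid(2850, 2890, 20),
        )
        stack, truth = generate_widefield_stack(scene, 0)
        assert truth.spots == []
        n = stack.data.size
        assert abs(stack.data.mean() - 50.0) < 3 * 1.0 / math.sqrt(n)

    def test_flat_spectrum_flux_constant_across_frames(self, clean_single_spot_scene):
        import dataclasses

        flat = ParamDistribution(mean_a1=0.0, sd_a1=0, mean_a2=0.0, sd_a2=0)
        scene = dataclasses.replace(clean_single_spot_scene, params=flat)
        stack, truth = generate_widefield_stack(scene, 3)
        per_frame = stack.data.sum(axis=(1, 2))
        assert np.all(np.abs(per_frame - per_frame[0]) < 1e-9 * per_frame[0])

    def test_noiseless_roi_spectrum_round_trip(self, clean_single_spot_scene):
        from nvtherm import detect_bright_spots, extract_spot_spectrum

        stack, truth = generate_widefield_stack(clean_single_spot_scene, 3)
        roi = detect_bright_spots(stack.mean_image(), stack.pixel_size_um)[0]
        spec = extract_spot_spectrum(stack, roi, 0)
        clean = evaluate_spectrum(truth.spots[0].params, spec.frequencies)
        clean /= np.sort(clean)[-len(clean) // 10 :].mean()
        assert np.abs(spec.intensities - clean).max() < 1e-6

    def test_flux_conservation_no_noise(self, clean_single_spot_scene):
        # total rendered flux per frame = brightness * spectrum value, up to
        # PSF truncation (< 0.1% for a window of >= 6 PSF sigmas)
        stack, truth = generate_widefield_stack(clean_single_spot_scene, 4)
        spot = truth.spots[0]
        expected = spot.brightness * evaluate_spectrum(
            spot.params, stack.frame_frequencies
        )
        total = stack.data.sum(axis=(1, 2))
        assert np.all(np.abs(total / expected - 1.0) < 1e-3)

    def test_impossible_placement_raises(self):
        scene = SceneConfig(image_shape=(48, 48), n_spots=40, n_repeats=2,
                            grid=SweepGrid(2850, 2890, 8))
        with pytest.raises(RuntimeError):
            generate_widefield_stack(scene, 0)

    def test_generation_is_deterministic(self):
        scene = SceneConfig(image_shape=(64, 64), n_spots=3, n_repeats=2,
                            grid=SweepGrid(2850, 2890, 20))
        s1, t1 = generate_widefield_stack(scene, 99)
        s2, t2 = generate_widefield_stack(scene, 99)
        assert np.array_equal(s1.data, s2.data)
        assert t1.spots[0].params == t2.spots[0].params

    def test_truth_sidecar_round_trip(self, tmp_path):
        scene = SceneConfig(image_shape=(64, 64), n_spots=2, n_repeats=2,
                            grid=SweepGrid(2850, 2890, 20))
        _, truth = generate_widefield_stack(scene, 5)
        path = tmp_path / "scene.truth.json"
        truth.to_json(path)
        back = GroundTruth.from_json(path)
        assert back.grid == truth.grid
        assert back.spots[1].params == truth.spots[1].params
        assert back.noise_level == truth.noise_level

    def test_stack_tiff_round_trip(self, tmp_path):
        scene = SceneConfig(image_shape=(48, 48), n_spots=1, n_repeats=2,
                            grid=SweepGrid(2850, 2890, 12))
        stack, _ = generate_widefield_stack(scene, 5)
        from nvtherm import ImageStack

        path = tmp_path / "stack.tiff"
        stack.save(path)
        back = ImageStack.load(path)
        assert np.array_equal(back.data, stack.data)
        assert back.grid == stack.grid
        assert back.n_repeats == stack.n_repeats
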