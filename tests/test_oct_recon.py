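"""OCT reconstruction: reference subtraction, dispersion, depth transform."""

import numpy as np
import pytest

from pars_oxi.oct_recon import (BScan, DispersionModel, NonConvergenceError,
                                SearchSpec, compensate_dispersion,
                                estimate_dispersion, fundus_projection,
                                peak_width_bins, subtract_reference,
                                transform_to_depth)
from pars_oxi.synthetic_data import OCTFrameSpec, simulate_oct_frame

SPEC = OCTFrameSpec(n_alines=8, n_samples=512)


def _bin_centered_depth(spec: OCTFrameSpec, bin_index: int) -> float:
    k = spec.k_grid()
    dk = (k[-1] - k[0]) / (len(k) - 1)
    return np.pi * bin_index / (len(k) * dk)


class TestSubtractReference:
    def test_zero_scene_zero_noise_gives_zero(self):
        frame = simulate_oct_frame([], SPEC)
        out = subtract_reference(frame)
        np.testing.assert_allclose(out, 0.0, atol=1e-14)

    def test_second_subtraction_flagged(self):
        frame = simulate_oct_frame([(100.0, 1.0)], SPEC)
        subtract_reference(frame)
        with pytest.warns(UserWarning, match="already subtracted"):
            subtract_reference(frame)

    def test_residual_dc_below_one_percent_of_fringe(self):
        frame = simulate_oct_frame([(0.3 * SPEC.max_depth_um, 1.0)], SPEC)
        out = subtract_reference(frame)
        assert abs(out.mean()) < 0.01 * np.abs(out).max()


class TestCompensateDispersion:
    def test_zero_coefficients_is_identity(self):
        frame = simulate_oct_frame([(0.3 * SPEC.max_depth_um, 1.0)], SPEC)
        model = DispersionModel(frame.k0, frame.k_halfspan, (0, 0, 0, 0))
        sp = frame.spectra - frame.reference_spectrum
        np.testing.assert_array_equal(
            compensate_dispersion(sp, model, frame.k_grid), sp)

    def test_exact_negation_restores_transform_limited_peak(self):
        scene = [(_bin_centered_depth(SPEC, 60), 1.0)]
        disp = simulate_oct_frame(scene, SPEC, dispersion_coeffs=(8, 0, 0, 0))
        free = simulate_oct_frame(scene, SPEC)
        model = DispersionModel(disp.k0, disp.k_halfspan, (8, 0, 0, 0))
        corr = compensate_dispersion(disp.spectra - disp.reference_spectrum,
                                     model, disp.k_grid)
        w_corr = peak_width_bins(
            transform_to_depth(corr, disp.k_grid).depth_profiles[0])
        w_free = peak_width_bins(
            transform_to_depth(free.spectra - free.reference_spectrum,
                               free.k_grid).depth_profiles[0])
        assert abs(w_corr - w_free) <= 1.0

    def test_wrong_sign_broadens_peak(self):
        scene = [(_bin_centered_depth(SPEC, 60), 1.0)]
        disp = simulate_oct_frame(scene, SPEC, dispersion_coeffs=(8, 0, 0, 0))
        sp = disp.spectra - disp.reference_spectrum
        wrong = DispersionModel(disp.k0, disp.k_halfspan, (-8, 0, 0, 0))
        right = DispersionModel(disp.k0, disp.k_halfspan, (8, 0, 0, 0))
        w_wrong = peak_width_bins(transform_to_depth(
            compensate_dispersion(sp, wrong, disp.k_grid),
            disp.k_grid).depth_profiles[0])
        w_raw = peak_width_bins(transform_to_depth(sp, disp.k_grid)
                                .depth_profiles[0])
        w_right = peak_width_bins(transform_to_depth(
            compensate_dispersion(sp, right, disp.k_grid),
            disp.k_grid).depth_profiles[0])
        assert w_wrong > w_raw > w_right

    def test_missing_k_grid_rejected(self):
        model = DispersionModel(10.0, 1.0, (1, 0, 0, 0))
        with pytest.raises(ValueError, match="k grid"):
            compensate_dispersion(np.ones((2, 16)), model, None)


class TestTransformToDepth:
    def test_pure_cosine_peaks_at_expected_bin(self):
        n_bin = 40
        z = _bin_centered_depth(SPEC, n_bin)
        k = SPEC.k_grid()
        spectra = np.cos(2 * k * z)[None, :]
        bscan = transform_to_depth(spectra, k)
        assert int(bscan.depth_profiles[0].argmax()) == n_bin

    def test_two_reflectors_at_depth_ratio_two(self):
        z = _bin_centered_depth(SPEC, 30)
        k = SPEC.k_grid()
        spectra = (np.cos(2 * k * z) + np.cos(2 * k * 2 * z))[None, :]
        prof = transform_to_depth(spectra, k).depth_profiles[0]
        peaks = np.sort(np.argsort(prof)[-2:])
        assert peaks[1] == 2 * peaks[0]

    def test_depth_axis_monotone_and_positive_half(self):
        frame = simulate_oct_frame([(100.0, 1.0)], SPEC)
        bscan = transform_to_depth(frame.spectra, frame.k_grid)
        assert np.all(np.diff(bscan.depth_axis_um) > 0)
        assert bscan.depth_profiles.shape[1] == SPEC.n_samples // 2 + 1

    def test_transform_limited_width_matches_bandwidth(self):
        """A full-band fringe at a bin-centered depth collapses to ~1 bin,
        the resolution implied by the simulated spectral span."""
        z = _bin_centered_depth(SPEC, 80)
        k = SPEC.k_grid()
        prof = transform_to_depth(np.cos(2 * k * z)[None, :], k).depth_profiles[0]
        assert peak_width_bins(prof) <= 2.0

    def test_nonuniform_grid_requires_resample(self):
        k = SPEC.k_grid() ** 1.01        # mildly non-uniform
        spectra = np.cos(2 * k * 50.0)[None, :]
        with pytest.raises(ValueError, match="resample"):
            transform_to_depth(spectra, k)
        bscan = transform_to_depth(spectra, k, resample=True)
        assert np.all(np.isfinite(bscan.depth_profiles))

    def test_tissue_depth_scaling(self):
        frame = simulate_oct_frame([(100.0, 1.0)], SPEC)
        bscan = transform_to_depth(frame.spectra, frame.k_grid)
        scaled = bscan.in_tissue()
        np.testing.assert_allclose(scaled.depth_axis_um * 1.38,
                                   bscan.depth_axis_um)


class TestEstimateDispersion:
    def test_dispersion_free_frame_yields_near_zero_coefficients(self):
        spec = OCTFrameSpec(n_alines=16, n_samples=512)
        scene = [(0.2 * spec.max_depth_um, 1.0), (0.5 * spec.max_depth_um, 0.6)]
        frame = simulate_oct_frame(scene, spec, noise_sigma=0.01, seed=5)
        model = estimate_dispersion(frame)
        assert np.max(np.abs(model.coeffs)) < 0.1

    def test_pure_noise_frame_raises_nonconvergence(self):
        spec = OCTFrameSpec(n_alines=16, n_samples=512)
        frame = simulate_oct_frame([], spec, noise_sigma=0.05, seed=6)
        with pytest.raises(NonConvergenceError, match="contrast"):
            estimate_dispersion(frame)

    def test_compensation_never_blunter_than_uncompensated(self):
        """Energy monotonicity: estimated compensation sharpens the peak
        relative to the raw dispersed frame."""
        spec = OCTFrameSpec(n_alines=16, n_samples=512)
        scene = [(0.25 * spec.max_depth_um, 1.0)]
        frame = simulate_oct_frame(scene, spec, dispersion_coeffs=(10, 2, 0, 0),
                                   noise_sigma=0.01, seed=7)
        model = estimate_dispersion(frame)
        sp = frame.spectra - frame.reference_spectrum
        w_raw = peak_width_bins(
            transform_to_depth(sp, frame.k_grid).depth_profiles.mean(axis=0))
        w_corr = peak_width_bins(transform_to_depth(
            compensate_dispersion(sp, model, frame.k_grid),
            frame.k_grid).depth_profiles.mean(axis=0))
        assert w_corr <= w_raw


class TestFundusProjection:
    def test_zero_volume_projects_to_zero(self):
        vol = np.zeros((4, 6, 10))
        np.testing.assert_array_equal(fundus_projection(vol), np.zeros((4, 6)))

    def test_single_bright_voxel(self):
        vol = np.zeros((4, 6, 10))
        vol[2, 3, 7] = 5.0
        proj = fundus_projection(vol)
        assert proj[2, 3] == 5.0 and proj.sum() == 5.0

    def test_additivity_over_scenes(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(size=(3, 5, 8))
        b = rng.uniform(size=(3, 5, 8))
        np.testing.assert_allclose(fundus_projection(a + b),
                                   fundus_projection(a) + fundus_projection(b))

    def test_bscan_list_dimension_mismatch_rejected(self):
        b1 = BScan(np.ones((4, 8)), np.arange(8.0) + 1)
        b2 = BScan(np.ones((4, 6)), np.arange(6.0) + 1)
        with pytest.raises(ValueError, match="dimensions"):
            fundus_projection([b1, b2])

    def test_two_layer_projection_matches_depth_integral(self):
        """Summed projection of a simulated two-layer scene equals the
        depth integral of the reconstructed magnitudes by construction;
        here we check the projection equals the per-A-line sums."""
        spec = OCTFrameSpec(n_alines=8, n_samples=256)
        scene = [(0.2 * spec.max_depth_um, 1.0), (0.4 * spec.max_depth_um, 0.5)]
        frame = simulate_oct_frame(scene, spec)
        bscan = transform_to_depth(frame.spectra - frame.reference_spectrum,
                                   frame.k_grid)
        proj = fundus_projection([bscan])
        np.testing.assert_allclose(proj[0], bscan.depth_profiles.sum(axis=1))
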