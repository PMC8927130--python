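"""Focus-region selection, mean-value unmixing, per-vessel SO2 maps."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pars_oxi.chromophores import BloodOpticalState
from pars_oxi.oximetry import (ConditioningError, UndefinedSO2Error,
                               UnmixingInput, accuracy_report,
                               build_unmixing_input, mean_signal,
                               select_focus_region, so2_map, unmix)
from pars_oxi.pars_recon import EnFaceImage, GridSpec


def _image(values, mask=None, grid=None, wavelength=None):
    ny, nx = values.shape
    grid = grid or GridSpec(nx=nx, ny=ny, pitch_um=1.0)
    if mask is None:
        mask = np.ones_like(values, dtype=bool)
    return EnFaceImage(values=np.asarray(values, float), valid_mask=mask,
                       grid=grid, wavelength_nm=wavelength)


def _basis(table, wavelengths=(532.0, 558.0)):
    return np.column_stack([
        [table.extinction(w, "HbO2") for w in wavelengths],
        [table.extinction(w, "Hb") for w in wavelengths],
    ])


class TestSelectFocusRegion:
    def test_uniform_image_returns_entire_valid_mask(self):
        img = _image(np.full((12, 12), 3.0))
        region = select_focus_region(img)
        np.testing.assert_array_equal(region, img.valid_mask)

    def test_bright_disk_selected(self):
        vals = np.zeros((40, 40))
        yy, xx = np.mgrid[:40, :40]
        disk = (yy - 20) ** 2 + (xx - 20) ** 2 <= 36
        vals[disk] = 5.0
        region = select_focus_region(_image(vals), percentile=90)
        assert region[disk].all()
        assert not region[~disk].any()

    def test_gaussian_focus_falloff_centers_region_on_waist(self, table):
        """Simulated capillary with a focal waist: the selected sub-region
        must sit on the focus center, not the vessel ends."""
        from pars_oxi.experiments import DEFAULT_WAVELENGTHS
        from pars_oxi.pars_recon import reconstruct
        from pars_oxi.synthetic_data import SimConfig, generate_vessel_phantom, \
            simulate_pars_stream
        ph = generate_vessel_phantom("capillary", so2=0.6, focus_falloff_um=60.0)
        sim = SimConfig(seed=0, target_snr_db=None, raster=(48, 48, None))
        stream = simulate_pars_stream(ph, table, sim, [532.0])
        grid = GridSpec.from_fov(ph.field_of_view, pixels=64)
        img = reconstruct(stream, grid, 532.0)
        region = select_focus_region(img)
        gx, gy = grid.mesh()
        cx = gx[region].mean()
        w, h = ph.field_of_view
        assert abs(cx - w / 2) < 30.0     # centroid within 30 um of the waist

    def test_empty_percentile_result_advises_lower_threshold(self):
        img = _image(np.zeros((5, 5)), mask=np.zeros((5, 5), bool))
        with pytest.raises(ValueError, match="valid"):
            select_focus_region(img)


class TestMeanSignal:
    def test_constant_region(self):
        img = _image(np.full((6, 6), 4.2))
        mean, n = mean_signal(img, np.ones((6, 6), bool))
        assert mean == pytest.approx(4.2) and n == 36

    def test_two_pixel_mean(self):
        vals = np.zeros((2, 2)); vals[0, 0] = 2.0; vals[0, 1] = 4.0
        region = np.zeros((2, 2), bool); region[0, :] = True
        mean, n = mean_signal(_image(vals), region)
        assert mean == pytest.approx(3.0) and n == 2

    def test_empty_region_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mean_signal(_image(np.ones((4, 4))), np.zeros((4, 4), bool))

    def test_region_averaging_shrinks_estimator_dispersion(self, rng):
        """Mean over a 1000-pixel region is ~sqrt(1000) tighter than a
        single pixel under iid noise, and dispersion falls with region size."""
        base = 10.0
        n_seeds = 150
        region_sizes = (1, 25, 1000)
        sds = []
        for m in region_sizes:
            means = [base + rng.normal(0, 1.0, m).mean() for _ in range(n_seeds)]
            sds.append(np.std(means, ddof=1))
        assert sds[0] > sds[1] > sds[2]
        ratio = sds[0] / sds[2]
        assert ratio == pytest.approx(np.sqrt(1000), rel=0.35)


class TestUnmix:
    def test_pure_oxyhemoglobin(self, table):
        A = _basis(table)
        s = A @ np.array([1.0, 0.0])
        res = unmix(UnmixingInput({532.0: s[0], 558.0: s[1]}), table)
        assert res.so2 == pytest.approx(1.0, abs=1e-12)
        assert res.residual == pytest.approx(0.0, abs=1e-9)
        assert not res.clamped

    def test_equal_concentrations_give_half(self, table):
        A = _basis(table)
        s = A @ np.array([0.7, 0.7])
        res = unmix(UnmixingInput({532.0: s[0], 558.0: s[1]}), table)
        assert res.so2 == pytest.approx(0.5, abs=1e-12)

    def test_forward_inverse_round_trip_073(self, table):
        A = _basis(table)
        state = BloodOpticalState.from_so2(0.73, total=2.0)
        s = A @ np.array([state.c_hbo2, state.c_hb])
        res = unmix(UnmixingInput({532.0: s[0], 558.0: s[1]}), table)
        assert res.so2 == pytest.approx(0.73, abs=1e-10)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(scale=st.floats(1e-3, 1e3), so2=st.floats(0.0, 1.0))
    def test_scale_invariance(self, table, scale, so2):
        A = _basis(table)
        s = A @ np.array([so2, 1.0 - so2])
        r1 = unmix(UnmixingInput({532.0: s[0], 558.0: s[1]}), table)
        r2 = unmix(UnmixingInput({532.0: scale * s[0], 558.0: scale * s[1]}),
                   table)
        assert r2.so2 == pytest.approx(r1.so2, abs=1e-9)

    def test_exact_recovery_sweep(self, table):
        A = _basis(table)
        for so2 in np.arange(0.0, 1.0001, 0.05):
            s = A @ np.array([so2, 1.0 - so2])
            res = unmix(UnmixingInput({532.0: s[0], 558.0: s[1]}), table)
            assert res.so2 == pytest.approx(so2, abs=1e-6)

    def test_clamping_matches_grid_search_projection(self, table):
        """Inputs outside the physical cone: result must equal the best
        non-negative solution found by brute-force grid search."""
        A = _basis(table)
        s = A @ np.array([1.0, -0.08])       # slightly outside the cone
        res = unmix(UnmixingInput({532.0: max(s[0], 0), 558.0: max(s[1], 0)}),
                    table)
        assert res.clamped
        assert 0.0 <= res.so2 <= 1.0
        # oracle: dense scan over c >= 0
        c1 = np.linspace(0, 2.0, 4001)
        best = None
        s_clip = np.array([max(s[0], 0), max(s[1], 0)])
        for a in c1:
            for b in (0.0,):                 # boundary face c_hb = 0
                r = np.linalg.norm(A @ np.array([a, b]) - s_clip)
                if best is None or r < best[0]:
                    best = (r, a, b)
        assert res.residual <= best[0] + 1e-9

    def test_gain_hook_corrects_wavelength_imbalance(self, table):
        A = _basis(table)
        s = A @ np.array([0.3, 0.7])
        skewed = {532.0: 1.5 * s[0], 558.0: s[1]}   # 532 channel over-gained
        biased = unmix(UnmixingInput(skewed), table)
        corrected = unmix(UnmixingInput(skewed), table,
                          gains={532.0: 1.5, 558.0: 1.0})
        assert biased.so2 != pytest.approx(0.3, abs=1e-3)
        assert corrected.so2 == pytest.approx(0.3, abs=1e-10)

    def test_conditioning_error_for_close_wavelengths(self, table):
        with pytest.raises(ConditioningError):
            unmix(UnmixingInput({532.0: 1.0, 532.0001: 1.0}), table)

    def test_zero_signal_undefined(self, table):
        with pytest.raises(UndefinedSO2Error):
            unmix(UnmixingInput({532.0: 0.0, 558.0: 0.0}), table)

    def test_single_wavelength_rejected(self):
        with pytest.raises(ValueError, match="2"):
            UnmixingInput({532.0: 1.0})


class TestSo2Map:
    def _vessel_images(self, table, so2_values=(0.95, 0.70)):
        from pars_oxi.chromophores import LN10
        shape = (30, 30)
        seg = np.zeros(shape, int)
        seg[5:10, :] = 1
        seg[20:25, :] = 2
        images = {}
        for wl in (532.0, 558.0):
            vals = np.zeros(shape)
            for label, so2 in zip((1, 2), so2_values):
                mu = LN10 * (so2 * table.extinction(wl, "HbO2")
                             + (1 - so2) * table.extinction(wl, "Hb"))
                vals[seg == label] = mu
            images[wl] = _image(vals, wavelength=wl)
        return images, seg

    def test_two_vessels_painted_exactly(self, table):
        images, seg = self._vessel_images(table)
        res = so2_map(images, seg, table)
        assert np.nanmax(np.abs(res.per_pixel_map[seg == 1] - 0.95)) < 1e-10
        assert np.nanmax(np.abs(res.per_pixel_map[seg == 2] - 0.70)) < 1e-10
        assert np.isnan(res.per_pixel_map[seg == 0]).all()
        assert res.confidence_mask[seg == 1].all()

    def test_zero_signal_vessel_excluded(self, table):
        images, seg = self._vessel_images(table)
        for img in images.values():
            img.values[seg == 2] = 0.0
        res = so2_map(images, seg, table)
        assert np.isnan(res.per_pixel_map[seg == 2]).all()
        assert set(res.per_vessel["label"]) == {1}

    def test_grid_mismatch_rejected(self, table):
        images, seg = self._vessel_images(table)
        images[558.0] = _image(images[558.0].values,
                               grid=GridSpec(nx=30, ny=30, pitch_um=2.0))
        with pytest.raises(ValueError, match="grid"):
            so2_map(images, seg, table)


class TestAccuracyReport:
    def test_identical_lists(self):
        rep = accuracy_report([0.4, 0.6], [0.4, 0.6])
        assert (rep.bias, rep.sd, rep.max_abs) == (0.0, 0.0, 0.0)

    def test_hand_arithmetic_example(self):
        rep = accuracy_report([0.42, 0.38], [0.40, 0.40])
        assert rep.bias == pytest.approx(0.0, abs=1e-15)
        assert rep.sd == pytest.approx(0.02 * np.sqrt(2))
        assert rep.max_abs == pytest.approx(0.02)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            accuracy_report([0.4], [0.4, 0.6])
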