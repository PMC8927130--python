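"""MAP projection, Delaunay gridding, reconstruction, image SNR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pars_oxi.pars_recon import (DegenerateGeometryError, EnFaceImage,
                                 GridSpec, grid_interpolate, map_project,
                                 measure_snr, reconstruct)
from pars_oxi.synthetic_data import (ScanStream, SimConfig,
                                     generate_fiber_phantom,
                                     simulate_pars_stream)


class TestMapProject:
    def test_definition_on_mixed_sign_trace(self):
        assert map_project(np.array([0.0, 3.0, -5.0, 2.0])) == 5.0

    def test_all_zero_trace(self):
        assert map_project(np.zeros(8)) == 0.0

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=20))
    def test_sign_flip_invariance(self, values):
        trace = np.array(values)
        assert map_project(trace) == map_project(-trace)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            map_project(np.array([]))


def _affine(x, y):
    return 2.0 * x + y


class TestGridInterpolate:
    def test_affine_field_reproduced_to_machine_precision(self, rng):
        pts = rng.uniform(0, 100, size=(60, 2))
        samples = np.column_stack([pts, _affine(pts[:, 0], pts[:, 1])])
        grid = GridSpec(nx=20, ny=20, pitch_um=100 / 19)
        img = grid_interpolate(samples, grid)
        gx, gy = grid.mesh()
        expected = _affine(gx, gy)
        np.testing.assert_allclose(img.values[img.valid_mask],
                                   expected[img.valid_mask], rtol=1e-10)

    def test_nodes_outside_hull_masked(self):
        # samples confined to the lower-left; far corner must be invalid
        pts = np.array([[0, 0, 1.0], [40, 0, 1.0], [0, 40, 1.0], [30, 30, 1.0]])
        grid = GridSpec(nx=11, ny=11, pitch_um=10.0)
        img = grid_interpolate(pts, grid)
        assert not img.valid_mask[-1, -1]
        assert img.values[-1, -1] == 0.0

    def test_sample_coincident_node_is_exact(self):
        pts = np.array([[0, 0, 2.0], [100, 0, 5.0], [0, 100, 7.0],
                        [100, 100, 3.0], [50, 50, 11.0]])
        grid = GridSpec(nx=3, ny=3, pitch_um=50.0)
        img = grid_interpolate(pts, grid)
        assert img.values[1, 1] == pytest.approx(11.0, abs=1e-12)

    def test_collinear_points_raise_degenerate_geometry(self):
        pts = np.column_stack([np.arange(5.0), np.arange(5.0), np.ones(5)])
        with pytest.raises(DegenerateGeometryError):
            grid_interpolate(pts, GridSpec(nx=4, ny=4, pitch_um=1.0))

    def test_conflicting_duplicates_averaged_with_warning(self):
        pts = np.array([[0, 0, 1.0], [0, 0, 3.0], [50, 0, 1.0], [0, 50, 1.0]])
        grid = GridSpec(nx=2, ny=2, pitch_um=50.0)
        with pytest.warns(UserWarning, match="averaged"):
            img = grid_interpolate(pts, grid)
        assert img.values[0, 0] == pytest.approx(2.0)

    def test_hull_honesty_valid_count_bounded(self, rng):
        pts = rng.uniform(10, 90, size=(50, 2))
        samples = np.column_stack([pts, np.ones(50)])
        grid = GridSpec(nx=21, ny=21, pitch_um=5.0)
        img = grid_interpolate(samples, grid)
        from scipy.spatial import Delaunay
        tri = Delaunay(pts)
        gx, gy = grid.mesh()
        nodes = np.column_stack([gx.ravel(), gy.ravel()])
        inside = tri.find_simplex(nodes) >= 0
        assert img.valid_mask.sum() <= inside.sum()


class TestReconstruct:
    def test_missing_wavelength_rejected(self, table):
        ph = generate_fiber_phantom("fiber-rat-eye", seed=0)
        sim = SimConfig(seed=0, target_snr_db=None, raster=(12, 12, None))
        stream = simulate_pars_stream(ph, None, sim, [532.0])
        grid = GridSpec.from_fov(ph.field_of_view, pixels=16)
        with pytest.raises(ValueError, match="558"):
            reconstruct(stream, grid, 558.0)

    def test_deterministic_and_permutation_invariant(self):
        ph = generate_fiber_phantom("fiber-rat-eye", seed=1)
        sim = SimConfig(seed=4, target_snr_db=None, raster=(24, 24, None))
        stream = simulate_pars_stream(ph, None, sim, [532.0])
        grid = GridSpec.from_fov(ph.field_of_view, pixels=32)
        img1 = reconstruct(stream, grid, 532.0)
        img2 = reconstruct(stream, grid, 532.0)
        np.testing.assert_array_equal(img1.values, img2.values)
        perm = np.random.default_rng(0).permutation(len(stream))
        shuffled = ScanStream(stream.shot_index[perm], stream.positions[perm],
                              stream.commanded[perm], stream.wavelength_nm[perm],
                              stream.traces[perm], stream.prr_hz)
        img3 = reconstruct(shuffled, grid, 532.0)
        np.testing.assert_allclose(img3.values, img1.values, atol=1e-12)

    def test_fiber_phantom_ridges_at_string_locations(self):
        """Noiseless reconstruction shows the 7 um strings where they are."""
        ph = generate_fiber_phantom("fiber-rat-eye", seed=2)
        sim = SimConfig(seed=0, target_snr_db=None, raster=(96, 96, None))
        stream = simulate_pars_stream(ph, None, sim, [532.0])
        grid = GridSpec.from_fov(ph.field_of_view, pixels=96)
        img = reconstruct(stream, grid, 532.0)
        gx, gy = grid.mesh()
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        on_string = ph.signal_mask(pts).reshape(img.values.shape)
        # bright pixels concentrate on the strings; off-string stays dark
        far = ~on_string
        assert img.values[on_string & img.valid_mask].max() > 0
        assert img.values[far & img.valid_mask].mean() < \
            0.5 * img.values[on_string & img.valid_mask].max()


def _flat_image(values: np.ndarray) -> EnFaceImage:
    ny, nx = values.shape
    grid = GridSpec(nx=nx, ny=ny, pitch_um=1.0)
    return EnFaceImage(values=values, valid_mask=np.ones_like(values, bool),
                       grid=grid)


class TestMeasureSnr:
    def test_closed_form_twenty_db(self, rng):
        vals = np.zeros((40, 40))
        vals[:20] = 10.0                            # signal mean 10
        noise = rng.normal(0, 1.0, size=(20, 40))
        noise = (noise - noise.mean()) / noise.std(ddof=1)   # sd exactly 1
        vals[20:] = noise
        img = _flat_image(vals)
        sig = np.zeros_like(vals, bool); sig[:20] = True
        bg = ~sig
        assert measure_snr(img, sig, bg) == pytest.approx(20.0, abs=1e-9)

    def test_zero_background_sd_rejected(self):
        img = _flat_image(np.ones((10, 10)))
        sig = np.zeros((10, 10), bool); sig[:5] = True
        with pytest.raises(ValueError, match="undefined"):
            measure_snr(img, sig, ~sig)

    def test_overlapping_regions_rejected(self):
        img = _flat_image(np.ones((10, 10)))
        sig = np.ones((10, 10), bool)
        with pytest.raises(ValueError, match="disjoint"):
            measure_snr(img, sig, sig)
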