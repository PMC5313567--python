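import numpy as np
import pytest
from scipy.ndimage import map_coordinates

from pbirecon.core import Geometry, ScanMode
from pbirecon.simulator import (
    CorruptionModel,
    EllipseSpec,
    analytic_sinogram,
    corrupt,
    make_phantom,
    make_drift_components,
    propagate,
    simulate_half_acquisition,
)

PIXEL = 3.05e-6


def grid_line_integrals(image, angles_deg, axis, pixel_size):
    """Independent Radon oracle: dense sampling along each ray with
    bilinear interpolation (scipy.ndimage), trapezoid-summed."""
    n = image.shape[0]
    c = (n - 1) / 2.0
    step = 0.25  # sample every quarter pixel along the ray
    t = np.arange(-n, n, step)
    width = image.shape[1]
    out = np.empty((len(angles_deg), width))
    for i, ang in enumerate(np.deg2rad(angles_deg)):
        cos_t, sin_t = np.cos(ang), np.sin(ang)
        for col in range(width):
            s = col - axis
            x = s * cos_t - t * sin_t + c
            y = s * sin_t + t * cos_t + c
            vals = map_coordinates(image, [y, x], order=1, cval=0.0)
            out[i, col] = vals.sum() * step * pixel_size
    return out


class TestMakePhantom:
    def test_empty_list_gives_zero_maps(self):
        ph = make_phantom([], 32, PIXEL)
        assert not ph.delta.any() and not ph.beta.any()

    def test_disk_area_matches_analytic(self):
        r = 60 * PIXEL
        ph = make_phantom([EllipseSpec(0, 0, r, r, 0, delta_value=1e-7)], 256, PIXEL)
        area_pixels = np.count_nonzero(ph.delta)
        expected = np.pi * r**2 / PIXEL**2
        assert area_pixels == pytest.approx(expected, rel=0.02)

    def test_overlapping_ellipses_add(self):
        e = EllipseSpec(0, 0, 20 * PIXEL, 20 * PIXEL, 0, delta_value=1.0, beta_value=0.5)
        ph = make_phantom([e, e], 64, PIXEL)
        assert ph.delta.max() == pytest.approx(2.0)
        assert ph.beta.max() == pytest.approx(1.0)

    def test_out_of_circle_ellipse_warns(self):
        with pytest.warns(UserWarning, match="inscribed circle"):
            make_phantom(
                [EllipseSpec(30 * PIXEL, 0, 10 * PIXEL, 10 * PIXEL, 0, delta_value=1.0)],
                64, PIXEL,
            )


class TestAnalyticSinogram:
    def test_central_ray_chord(self):
        r, v = 30 * PIXEL, 2.0e-7
        geom = Geometry(40.0, PIXEL, 0.0, [0.0], axis_position=63.5)
        sino = analytic_sinogram([EllipseSpec(0, 0, r, r, 0, delta_value=v)],
                                 geom, "delta", width=128)
        centre = sino.values[0, 63:65].max()
        assert centre == pytest.approx(2 * r * v, rel=1e-3)

    def test_zero_outside_support(self):
        r = 30 * PIXEL
        geom = Geometry(40.0, PIXEL, 0.0, [0.0, 45.0, 90.0, 135.0], axis_position=63.5)
        sino = analytic_sinogram([EllipseSpec(0, 0, r, r, 0, delta_value=1.0)],
                                 geom, "delta", width=128)
        s = (np.arange(128) - 63.5) * PIXEL
        assert np.all(sino.values[:, np.abs(s) > r + PIXEL] == 0)

    def test_matches_grid_integration_oracle(self):
        ells = [
            EllipseSpec(0, 0, 40 * PIXEL, 40 * PIXEL, 0, delta_value=1.0),
            EllipseSpec(15 * PIXEL, -10 * PIXEL, 12 * PIXEL, 20 * PIXEL, 30.0,
                        delta_value=0.5),
        ]
        angles = np.linspace(0.0, 180.0, 8, endpoint=False)
        geom = Geometry(40.0, PIXEL, 0.0, angles, axis_position=63.5)
        exact = analytic_sinogram(ells, geom, "delta", width=128).values
        phantom = make_phantom(ells, 128, PIXEL).delta
        numeric = grid_line_integrals(phantom, angles, 63.5, PIXEL)
        rel = np.linalg.norm(exact - numeric) / np.linalg.norm(exact)
        assert rel < 0.01


class TestPropagate:
    def test_zero_distance_is_beer_lambert(self, beamline_geometry, rng):
        geom = beamline_geometry.replace(distance=0.0)
        B = rng.uniform(0, 1e-12, size=64)
        D = rng.uniform(0, 1e-10, size=64)
        intensity = propagate(D, B, geom)
        np.testing.assert_allclose(
            intensity, np.exp(-(4 * np.pi / geom.wavelength) * B), rtol=1e-12
        )

    def test_empty_beam_stays_unity(self, beamline_geometry):
        zeros = np.zeros((32, 32))
        intensity = propagate(zeros, zeros, beamline_geometry)
        np.testing.assert_allclose(intensity, 1.0, atol=1e-10)

    def test_pure_phase_object_invisible_at_contact(self, beamline_geometry, rng):
        geom = beamline_geometry.replace(distance=0.0)
        D = rng.uniform(0, 1e-10, size=(16, 16))
        np.testing.assert_allclose(propagate(D, np.zeros_like(D), geom), 1.0,
                                   atol=1e-12)

    def test_mean_intensity_conserved(self, beamline_geometry, rng):
        # unitary propagator with periodic boundaries (Parseval)
        D = rng.uniform(0, 5e-11, size=128)
        B = rng.uniform(0, 5e-13, size=128)
        i0 = propagate(D, B, beamline_geometry.replace(distance=0.0))
        i_d = propagate(D, B, beamline_geometry)
        assert i_d.mean() == pytest.approx(i0.mean(), rel=1e-6)

    def test_rejects_non_finite(self, beamline_geometry):
        bad = np.full(16, np.nan)
        with pytest.raises(ValueError):
            propagate(bad, np.zeros(16), beamline_geometry)


class TestCorrupt:
    def _geom(self, n):
        return Geometry(40.0, PIXEL, 0.0,
                        np.linspace(0, 180, n, endpoint=False), 31.5)

    def test_noise_free_is_expectation(self):
        n = 10
        clean = np.full((n, 2, 64), 0.5)
        model = CorruptionModel(gain_map=np.ones((2, 64)), photon_count=1000.0,
                                dark_level=7.0, seed=0, poisson=False)
        ps = corrupt(clean, np.ones((2, 64)), model, self._geom(n),
                     n_flats_before=2, n_darks=1)
        np.testing.assert_allclose(ps.projections, 0.5 * 1000.0 + 7.0)
        np.testing.assert_allclose(ps.flats_before, 1000.0 + 7.0)
        np.testing.assert_allclose(ps.darks, 7.0)

    def test_same_seed_reproduces_dataset(self):
        n = 12
        clean = np.random.default_rng(3).uniform(0.3, 1.0, size=(n, 2, 32))
        comps = make_drift_components((2, 32), n + 4, 2, seed=5)
        def build():
            model = CorruptionModel(gain_map=np.ones((2, 32)),
                                    drift_components=comps,
                                    photon_count=5000.0, seed=42)
            return corrupt(clean, np.ones((2, 32)), model, self._geom(n),
                           n_flats_before=4, n_darks=1)
        a, b = build(), build()
        np.testing.assert_array_equal(a.projections, b.projections)
        np.testing.assert_array_equal(a.flats_before, b.flats_before)

    def test_gain_columns_become_angle_constant_stripes(self):
        n = 30
        clean = np.full((n, 1, 64), 0.8)
        gain = np.ones((1, 64))
        cols = [5, 17, 33, 40, 59]
        gain[:, cols] = 1.02
        model = CorruptionModel(gain_map=gain, photon_count=1000.0, seed=0,
                                poisson=False)
        ps = corrupt(clean, np.ones((1, 64)), model, self._geom(n),
                     n_flats_before=2, n_darks=1)
        # flat fielding with the (un-gained-column-free) mean flat keeps the
        # gain stripes: the corrupted flats share the gain, so normalising
        # against them removes it -- use the ideal flat instead
        sino = ps.projections[:, 0, :] / 1000.0
        stripe_profile = sino.mean(axis=0)
        assert np.all(stripe_profile[cols] > stripe_profile[cols[0] - 1] * 1.015)
        assert np.ptp(sino[:, cols[0]]) < 1e-12  # constant in angle

    def test_drift_weight_length_validated(self):
        n = 8
        clean = np.ones((n, 1, 16))
        comps = [(np.ones((1, 16)), np.zeros(n))]  # too short: needs n + flats
        model = CorruptionModel(gain_map=np.ones((1, 16)), drift_components=comps)
        with pytest.raises(ValueError, match="n_proj"):
            corrupt(clean, np.ones((1, 16)), model, self._geom(n),
                    n_flats_before=2, n_darks=1)


class TestHalfAcquisition:
    def test_centred_axis_gives_mirror_rows(self):
        geom = Geometry(40.0, PIXEL, 0.0,
                        np.linspace(0, 360, 60, endpoint=False), 0.0,
                        scan_mode=ScanMode.FULL_TURN_360_OFFSET)
        ells = [EllipseSpec(10 * PIXEL, 5 * PIXEL, 15 * PIXEL, 20 * PIXEL, 30.0,
                            beta_value=1e-9)]
        ps = simulate_half_acquisition(ells, geom, 0.0, 63, height=1)
        proj = ps.projections[:, 0, :]
        np.testing.assert_allclose(proj[0], proj[30][::-1], atol=1e-6)

    def test_records_true_axis(self, half_acquisition_set):
        ps, _, offset = half_acquisition_set
        width = ps.frame_shape[1]
        assert ps.geometry.axis_position == (width - 1) / 2 + offset

    def test_axis_outside_detector_rejected(self):
        geom = Geometry(40.0, PIXEL, 0.0,
                        np.linspace(0, 360, 8, endpoint=False), 0.0,
                        scan_mode=ScanMode.FULL_TURN_360_OFFSET)
        with pytest.raises(ValueError, match="outside the detector"):
            simulate_half_acquisition([], geom, 40.0, 64)
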