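import numpy as np
import pytest
from scipy.linalg import subspace_angles

from pbirecon.core import Geometry
from pbirecon.flat_fielding import (
    compute_eigen_flats,
    conventional_flat_field,
    detect_air_region,
    dynamic_flat_field,
    flat_field_stack,
)
from pbirecon.simulator import (
    CorruptionModel,
    EllipseSpec,
    make_drift_components,
    simulate_scan,
)

PIXEL = 3.05e-6


@pytest.fixture
def drifting_scan():
    """Scan with two-mode beam drift, Poisson noise and 32 flats."""
    height, width, n_proj, n_flats = 8, 64, 60, 32
    geom = Geometry(40.0, PIXEL, 0.0,
                    np.linspace(0, 180, n_proj, endpoint=False), 31.5)
    comps = make_drift_components((height, width), n_proj + n_flats,
                                  n_components=2, amplitude=0.04, seed=1)
    model = CorruptionModel(gain_map=np.ones((height, width)),
                            drift_components=comps, photon_count=1.0e6,
                            dark_level=10.0, seed=2, poisson=True)
    ells = [EllipseSpec(0, 0, 12 * PIXEL, 12 * PIXEL, 0, beta_value=5e-9)]
    ps = simulate_scan(ells, geom, width, height=height, corruption=model,
                       n_flats_before=n_flats // 2, n_flats_after=n_flats // 2)
    air = np.ones((height, width), dtype=bool)
    air[:, width // 2 - 16: width // 2 + 16] = False
    return ps, comps, air


class TestConventional:
    def test_projection_equal_flat_gives_unity(self, rng):
        flat = rng.uniform(900, 1100, size=(8, 16))
        dark = rng.uniform(5, 15, size=(8, 16))
        np.testing.assert_allclose(conventional_flat_field(flat, flat, dark), 1.0)

    def test_projection_equal_dark_gives_zero(self, rng):
        flat = rng.uniform(900, 1100, size=(8, 16))
        dark = rng.uniform(5, 15, size=(8, 16))
        np.testing.assert_allclose(conventional_flat_field(dark, flat, dark), 0.0)

    def test_midpoint_gives_half(self, rng):
        flat = rng.uniform(900, 1100, size=(8, 16))
        dark = rng.uniform(5, 15, size=(8, 16))
        proj = dark + 0.5 * (flat - dark)
        np.testing.assert_allclose(conventional_flat_field(proj, flat, dark), 0.5)

    def test_bad_flats_rejected(self):
        flat = np.zeros((8, 16))
        dark = np.ones((8, 16))
        with pytest.raises(ValueError, match="bad flats"):
            conventional_flat_field(np.ones((8, 16)), flat, dark)

    def test_output_clipped_non_negative(self, rng):
        flat = np.full((4, 4), 100.0)
        dark = np.zeros((4, 4))
        proj = np.full((4, 4), -50.0)
        out = conventional_flat_field(proj, flat, dark)
        assert np.all(out >= 0)


class TestEigenFlats:
    def test_identical_flats_give_empty_basis(self):
        flats = np.ones((5, 4, 8)) * 100
        basis = compute_eigen_flats(flats, np.zeros((1, 4, 8)), 2)
        assert basis.n_components == 0
        assert basis.explained_variance.size == 0

    def test_two_flats_give_single_component(self, rng):
        mean = rng.uniform(900, 1100, size=(4, 8))
        wiggle = rng.normal(0, 10, size=(4, 8))
        basis = compute_eigen_flats(np.stack([mean + wiggle, mean - wiggle]),
                                    np.zeros((1, 4, 8)), 1)
        assert basis.n_components == 1
        np.testing.assert_allclose(basis.explained_variance, [1.0])
        comp = basis.components[0].ravel()
        w = wiggle.ravel() / np.linalg.norm(wiggle)
        assert abs(np.dot(comp, w)) == pytest.approx(1.0, abs=1e-12)

    def test_components_orthonormal(self, drifting_scan):
        ps, _, _ = drifting_scan
        basis = compute_eigen_flats(ps.flats, ps.darks, 4)
        flat = basis.components.reshape(basis.n_components, -1)
        np.testing.assert_allclose(flat @ flat.T, np.eye(basis.n_components),
                                   atol=1e-10)
        assert np.all(np.diff(basis.explained_variance) <= 1e-12)

    def test_recovers_true_drift_subspace(self, drifting_scan):
        ps, comps, _ = drifting_scan
        basis = compute_eigen_flats(ps.flats, ps.darks, 2)
        estimated = np.stack([c.ravel() for c in basis.components], axis=1)
        truth = np.stack([comps[0][0].ravel(), comps[1][0].ravel()], axis=1)
        angles = np.rad2deg(subspace_angles(estimated, truth))
        assert np.max(angles) < 5.0

    def test_too_many_components_rejected(self):
        flats = np.random.default_rng(0).uniform(size=(3, 4, 4))
        with pytest.raises(ValueError, match="n_components"):
            compute_eigen_flats(flats, np.zeros((1, 4, 4)), 3)


class TestDynamic:
    def test_empty_basis_equals_conventional(self, rng):
        flats = np.ones((4, 4, 8)) * 100
        darks = np.zeros((1, 4, 8))
        basis = compute_eigen_flats(flats, darks, 2)
        proj = rng.uniform(20, 90, size=(4, 8))
        conv = conventional_flat_field(proj, flats.mean(0), darks.mean(0))
        np.testing.assert_array_equal(dynamic_flat_field(proj, basis), conv)

    def test_exact_weight_recovery_for_drifted_flat(self, drifting_scan):
        ps, _, _ = drifting_scan
        basis = compute_eigen_flats(ps.flats, ps.darks, 2)
        denom = basis.mean_flat - basis.mean_dark
        proj = basis.mean_dark + denom + 0.3 * basis.components[0]
        out = dynamic_flat_field(proj, basis)
        np.testing.assert_allclose(out, 1.0, atol=1e-6)

    def test_reduces_background_variation_under_drift(self, drifting_scan):
        ps, _, air = drifting_scan
        conv = flat_field_stack(ps, "conventional")
        dyn = flat_field_stack(ps, "dynamic", n_components=2,
                               estimation_region=air)
        cov = lambda x: x[:, air].std() / x[:, air].mean()
        assert cov(dyn) <= 0.5 * cov(conv)

    def test_constant_flats_bitwise_equal_conventional(self):
        geom = Geometry(40.0, PIXEL, 0.0,
                        np.linspace(0, 180, 10, endpoint=False), 15.5)
        model = CorruptionModel(gain_map=np.ones((2, 32)), photon_count=1e4,
                                dark_level=5.0, seed=0, poisson=False)
        ells = [EllipseSpec(0, 0, 8 * PIXEL, 8 * PIXEL, 0, beta_value=3e-9)]
        ps = simulate_scan(ells, geom, 32, height=2, corruption=model,
                           n_flats_before=4, n_darks=1)
        conv = flat_field_stack(ps, "conventional")
        dyn = flat_field_stack(ps, "dynamic", n_components=2)
        np.testing.assert_array_equal(conv, dyn)

    def test_air_detection_avoids_deep_object_shadow(self, drifting_scan):
        ps, _, _ = drifting_scan
        conv = flat_field_stack(ps, "conventional")
        detected = detect_air_region(conv)
        assert detected is not None
        # the 12-px-radius object always shadows the central columns
        width = conv.shape[-1]
        deep = np.abs(np.arange(width) - (width - 1) / 2.0) <= 10
        assert not detected[:, deep].any()
        # while the outermost columns are genuinely air
        assert detected[:, :6].all() and detected[:, -6:].all()
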