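import numpy as np
import pytest

from pbirecon.core import Geometry
from pbirecon.phase_retrieval import (
    RetrievalConfig,
    RetrievalReport,
    compare_retrievals,
    ctf_retrieve,
    paganin_filter,
    paganin_retrieve,
)
from pbirecon.simulator import propagate

PIXEL = 3.05e-6


@pytest.fixture
def contact_geometry(beamline_geometry):
    return beamline_geometry.replace(distance=0.0)


class TestPaganin:
    def test_contact_regime_is_beer_lambert(self, contact_geometry, rng):
        intensity = np.exp(-rng.uniform(0.05, 2.0, size=(32, 32)))
        cfg = RetrievalConfig(method="paganin", delta_beta_ratio=50.0, mu=1.0,
                              padding=0)
        res = paganin_retrieve(intensity, contact_geometry, cfg)
        np.testing.assert_allclose(res.thickness, -np.log(intensity), rtol=1e-12)
        np.testing.assert_allclose(res.pseudo_absorption, np.log(intensity),
                                   rtol=1e-12)

    def test_unit_intensity_gives_zero_thickness(self, beamline_geometry):
        cfg = RetrievalConfig(method="paganin", delta_beta_ratio=100.0, mu=1.0)
        res = paganin_retrieve(np.ones((64, 64)), beamline_geometry, cfg)
        np.testing.assert_allclose(res.thickness, 0.0, atol=1e-12)

    def test_filter_is_monotone_lorentzian_low_pass(self, beamline_geometry):
        H = paganin_filter((256,), beamline_geometry, 100.0)
        assert H[0] == 1.0
        assert np.all(np.diff(H[:128]) < 0)  # strictly decreasing up to Nyquist
        assert np.all(H > 0)

    def test_flat_scaling_shifts_thickness_by_log(self, beamline_geometry, rng):
        cfg = RetrievalConfig(method="paganin", delta_beta_ratio=100.0, mu=1.0,
                              padding=32)
        intensity = np.exp(-rng.uniform(0.1, 1.0, size=64))
        base = paganin_retrieve(intensity, beamline_geometry, cfg).thickness
        scaled = paganin_retrieve(1.1 * intensity, beamline_geometry, cfg).thickness
        np.testing.assert_allclose(scaled, base - np.log(1.1), rtol=1e-6,
                                   atol=1e-9)

    def test_mostly_nonpositive_input_rejected(self, beamline_geometry):
        cfg = RetrievalConfig(method="paganin", delta_beta_ratio=100.0, mu=1.0)
        bad = np.ones((16, 16))
        bad[:8] = -1.0
        with pytest.raises(ValueError, match="non-positive"):
            paganin_retrieve(bad, beamline_geometry, cfg)

    def test_mu_from_ratio_and_reference_delta(self, beamline_geometry):
        cfg = RetrievalConfig(method="paganin", delta_beta_ratio=200.0,
                              delta_ref=1e-7)
        beta = 1e-7 / 200.0
        expected = 4 * np.pi * beta / beamline_geometry.wavelength
        assert cfg.attenuation_mu(beamline_geometry) == pytest.approx(expected)


class TestCTF:
    def test_unit_intensity_gives_zero_phase(self, beamline_geometry):
        cfg = RetrievalConfig(method="ctf_pure_phase")
        phi = ctf_retrieve(np.ones((64, 64)), beamline_geometry, cfg)
        np.testing.assert_allclose(phi, 0.0, atol=1e-12)

    def test_linearity_in_contrast(self, beamline_geometry, rng):
        cfg = RetrievalConfig(method="ctf_pure_phase", regularization=1e-6,
                              padding=0)
        contrast = rng.normal(0, 1e-3, size=(64, 64))
        phi1 = ctf_retrieve(1.0 + contrast, beamline_geometry, cfg)
        phi3 = ctf_retrieve(1.0 + 3.0 * contrast, beamline_geometry, cfg)
        np.testing.assert_allclose(phi3, 3.0 * phi1, rtol=1e-8, atol=1e-14)

    def test_sine_zeros_stay_finite(self, beamline_geometry, rng):
        # white-noise contrast exercises every frequency incl. sin(chi) = 0
        cfg = RetrievalConfig(method="ctf_pure_phase", regularization=1e-4,
                              padding=0)
        intensity = 1.0 + rng.normal(0, 1e-2, size=(128, 128))
        intensity = np.clip(intensity, 0.5, None)
        phi = ctf_retrieve(intensity, beamline_geometry, cfg)
        assert np.all(np.isfinite(phi))

    def test_contact_distance_rejected(self, contact_geometry):
        cfg = RetrievalConfig(method="ctf_pure_phase")
        with pytest.raises(ValueError, match="distance"):
            ctf_retrieve(np.ones((16, 16)), contact_geometry, cfg)

    def test_projected_variant_clamps_response(self, beamline_geometry, rng):
        # beyond the clamp the projected response no longer oscillates, so
        # the two variants must differ on broadband input
        base = RetrievalConfig(method="ctf_pure_phase", regularization=1e-6,
                               padding=0)
        proj = RetrievalConfig(method="projected_ctf", regularization=1e-6,
                               padding=0)
        intensity = np.clip(1.0 + rng.normal(0, 1e-2, size=(128, 128)), 0.5, None)
        phi_a = ctf_retrieve(intensity, beamline_geometry, base)
        phi_b = ctf_retrieve(intensity, beamline_geometry, proj)
        assert np.all(np.isfinite(phi_b))
        assert not np.allclose(phi_a, phi_b)


class TestWeakPhaseRecovery:
    def test_band_limited_pure_phase_recovered(self, beamline_geometry):
        from pbirecon.benchmarks import ctf_recovery

        scores = ctf_recovery(seed=7, n=128)
        assert scores["relative_rmse"] < 0.02


class TestCompareRetrievals:
    def _edge_phantom(self, geometry, n=128, phi_max=0.02):
        lam = geometry.wavelength
        x = np.arange(n)
        edge = 0.5 * (1 + np.tanh((x - n / 2) / 1.0))
        phi = phi_max * np.tile(edge, (n, 1))
        D = phi * lam / (2 * np.pi)
        return propagate(D, np.zeros_like(D), geometry, pad=64), phi

    def test_paganin_is_softer_than_ctf_on_edges(self, beamline_geometry):
        intensity, phi = self._edge_phantom(beamline_geometry)
        pag = paganin_retrieve(
            intensity, beamline_geometry,
            RetrievalConfig(method="paganin", delta_beta_ratio=2.0e5, mu=1.0,
                            padding=64),
        ).thickness
        ctf = ctf_retrieve(
            intensity, beamline_geometry,
            RetrievalConfig(method="ctf_pure_phase", regularization=1e-8,
                            padding=64),
        )
        report = compare_retrievals(pag, ctf, -phi)
        assert report.paganin_rise_distance >= report.ctf_rise_distance
        assert np.isfinite(report.paganin_rmse) and np.isfinite(report.ctf_rmse)

    def test_metrics_finite_at_tiny_distance(self, beamline_geometry):
        geom = beamline_geometry.replace(distance=1e-3)
        intensity, phi = self._edge_phantom(geom)
        pag = paganin_retrieve(
            intensity, geom,
            RetrievalConfig(method="paganin", delta_beta_ratio=500.0, mu=1.0,
                            padding=64),
        ).thickness
        ctf = ctf_retrieve(
            intensity, geom,
            RetrievalConfig(method="ctf_pure_phase", regularization=1e-8,
                            padding=64),
        )
        report = compare_retrievals(pag, ctf, -phi)
        for value in (report.paganin_rise_distance, report.ctf_rise_distance,
                      report.paganin_rmse, report.ctf_rmse):
            assert np.isfinite(value)

    def test_report_round_trips_through_json(self):
        report = RetrievalReport(2.5, 1.25, 0.01, 0.005)
        assert RetrievalReport.from_json(report.to_json()) == report
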