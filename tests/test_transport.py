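"""Photon transport baselines, scaled reflectance and the diffusion oracle."""

import numpy as np
import pytest

from marginspec.spectral import ChromophoreSet, ScatteringModel
from marginspec.transport import (
    ExtrapolationError,
    NoPhotonsCollectedError,
    ProbeGeometry,
    TransportConfig,
    diffusion_reflectance,
    diffusion_reflectance_radial,
    run_baseline,
    scaled_reflectance,
    simulate_spectrum,
)


class TestBaseline:
    def test_fixed_seed_reproducibility(self, geometry):
        cfg = TransportConfig(n_photons=60_000, seed=11)
        t1 = run_baseline(geometry, cfg, 7.5)
        t2 = run_baseline(geometry, cfg, 7.5)
        np.testing.assert_array_equal(t1.weights, t2.weights)
        np.testing.assert_array_equal(t1.path_cm, t2.path_cm)
        np.testing.assert_array_equal(t1.n_scatter, t2.n_scatter)

    def test_collected_fraction_stable_when_doubling_photons(self, geometry):
        """Collection probability agrees within 3 binomial standard errors."""
        cfg1 = TransportConfig(n_photons=150_000, seed=5)
        cfg2 = TransportConfig(n_photons=300_000, seed=6)
        t1 = run_baseline(geometry, cfg1, 11.0)
        t2 = run_baseline(geometry, cfg2, 11.0)
        p1 = t1.weights.size / cfg1.n_photons
        p2 = t2.weights.size / cfg2.n_photons
        se = np.sqrt(p1 * (1 - p1) / cfg1.n_photons + p2 * (1 - p2) / cfg2.n_photons)
        assert abs(p1 - p2) < 3 * se

    def test_zero_collection_raises_informative_error(self, geometry):
        cfg = TransportConfig(n_photons=10, seed=0)
        with pytest.raises(NoPhotonsCollectedError, match="n_photons"):
            run_baseline(geometry, cfg, 2.0)

    def test_collected_weights_and_paths_valid(self, lookup):
        for t in lookup.tables:
            assert np.all(t.weights > 0) and np.all(t.weights <= 1)
            assert np.all(t.path_cm > 0)
            assert 0 < t.collected_fraction < 1


class TestScaledReflectance:
    def test_zero_absorption_matches_baseline_sum(self, lookup):
        t = lookup.tables[2]
        r = scaled_reflectance(t, 0.0, t.musp_ref)
        assert r == pytest.approx(t.collected_fraction, rel=1e-12)

    def test_lookup_zero_absorption_at_grid_node(self, lookup):
        t = lookup.tables[2]
        r = lookup.reflectance(0.0, t.musp_ref)
        assert r == pytest.approx(t.collected_fraction, rel=1e-9)

    def test_strong_absorption_kills_reflectance(self, lookup):
        r0 = lookup.reflectance(0.0, 10.0)
        r100 = lookup.reflectance(100.0, 10.0)
        assert r100 < 0.01 * r0

    def test_monotone_lattice(self, lookup):
        """Non-increasing in mua, non-decreasing in musp on a lattice."""
        mua = np.linspace(0.0, 15.0, 16)
        for musp in (3.0, 6.0, 9.0, 14.0, 20.0):
            r = lookup.reflectance(mua, np.full_like(mua, musp))
            assert np.all(np.diff(r) < 0)
        musp = np.linspace(2.5, 24.5, 23)
        for m in (0.3, 1.0, 3.0, 8.0):
            r = lookup.reflectance(np.full_like(musp, m), musp)
            assert np.all(np.diff(r) > 0)

    def test_extrapolation_outside_hull_raises(self, lookup):
        with pytest.raises(ExtrapolationError):
            lookup.reflectance(1.0, 30.0)
        with pytest.raises(ExtrapolationError):
            lookup.reflectance(1.0, 1.0)

    def test_single_table_rejects_foreign_musp(self, lookup):
        with pytest.raises(ExtrapolationError):
            scaled_reflectance(lookup.tables[0], 1.0, 9.0)


class TestSimulateSpectrum:
    def test_zero_chromophores_flat_scattering_flat_spectrum(
        self, basis, grid, lookup
    ):
        spec = simulate_spectrum(
            ChromophoreSet(), ScatteringModel(a=11.0, b=0.0), basis, grid, lookup
        )
        np.testing.assert_allclose(spec, spec[0], rtol=1e-9)
        t = [t for t in lookup.tables if t.musp_ref == 11.0][0]
        assert spec[0] == pytest.approx(t.collected_fraction, rel=1e-9)

    def test_reflectance_dip_tracks_absorption_peak(self, basis, grid, lookup):
        """With hemoglobin present the spectral minimum sits at the composed
        absorption maximum (the Q-band region)."""
        from marginspec.spectral import compose_mua

        c = ChromophoreSet(c_hbo2=24.0, c_dhb=16.0, c_bcar=5.0)
        spec = simulate_spectrum(c, ScatteringModel(a=9.0, b=0.0), basis, grid, lookup)
        mua = compose_mua(c, basis, grid)
        lam_min = grid.wavelengths[np.argmin(spec)]
        lam_max = grid.wavelengths[np.argmax(mua)]
        assert abs(lam_min - lam_max) <= 5.0

    def test_physiologic_presets_positive_spectra(self, basis, grid, lookup):
        from marginspec.synthetic import PRESETS
        from marginspec.synthetic import _amplitude_for_target

        for preset in PRESETS.values():
            b = sum(preset.b_range) / 2
            a = float(_amplitude_for_target(preset.musp[0], b, grid)[0])
            c = ChromophoreSet(
                c_hbo2=preset.thb[0] * preset.so2[0],
                c_dhb=preset.thb[0] * (1 - preset.so2[0]),
                c_bcar=preset.bcar[0],
                a_gauss=0.012 * preset.bcar[0],
            )
            spec = simulate_spectrum(
                c, ScatteringModel(a=a, b=b), basis, grid, lookup
            )
            assert np.all(spec > 0)
            assert np.all(spec <= 1)


class TestDiffusionOracle:
    def test_bounds_and_absorption_limit(self):
        r = diffusion_reflectance(0.1, 10.0)
        assert 0 < r < 1
        # overwhelming absorption drives reflectance to zero
        assert diffusion_reflectance(1e6, 10.0) < 1e-4 * r

    def test_monotone_in_mua_and_musp(self):
        mua = np.linspace(0.01, 10.0, 40)
        r = diffusion_reflectance(mua, 10.0)
        assert np.all(np.diff(r) < 0)
        musp = np.linspace(2.0, 30.0, 40)
        r = diffusion_reflectance(0.5, musp)
        assert np.all(np.diff(r) > 0)

    def test_similarity_invariance(self):
        """Scaling mua and musp together leaves the closed form unchanged
        (lengths rescale; the dimensionless albedo and optical depths do not)."""
        assert diffusion_reflectance(0.2, 12.0) == pytest.approx(
            diffusion_reflectance(2.0, 120.0), rel=1e-12
        )

    def test_monte_carlo_tracks_diffusion_dipole_shape_in_mua(
        self, geometry, lookup
    ):
        """In the diffusive (high-albedo) regime the probe reflectance vs
        mua follows the radial diffusion-dipole shape at the collection
        radius after one scalar normalization. Diffusion theory degrades at
        sub-transport-length separations, so the check stays at albedo
        >= 0.94 with a 15% band."""
        mua = np.array([0.1, 0.3, 0.6])
        musp = 10.0
        r_mc = lookup.reflectance(mua, np.full_like(mua, musp))
        r_df = diffusion_reflectance_radial(
            mua, musp, geometry.collection_radius_cm
        )
        np.testing.assert_allclose(
            r_mc / r_mc[0], r_df / r_df[0], rtol=0.15
        )

    def test_radial_dipole_bounds_and_monotonicity(self, geometry):
        rho = geometry.collection_radius_cm
        mua = np.linspace(0.05, 5.0, 30)
        r = diffusion_reflectance_radial(mua, 10.0, rho)
        assert np.all(r > 0) and np.all(np.diff(r) < 0)
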