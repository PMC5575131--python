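"""Imaging route: anisotropy, sector integration, tilt inversion, lifetimes,
confocal volume, band integration."""

import numpy as np
import pytest

from xanthotilt.constants import rt_kcal_per_mol
from xanthotilt.imaging import (
    AnisotropyObservation,
    ConfocalGeometry,
    LifetimeModel,
    RingOrientationEstimator,
    SectorIntensities,
    anisotropy,
    confocal_volume,
    fit_lifetimes,
    fit_ring,
    integrate_band,
    mol_percent_from_surface_density,
    orientation_angle,
    sector_integrate,
)
from xanthotilt.synthetic import (
    GuvGeometry,
    GuvRenderSpec,
    RamanCube,
    render_guv_image,
    render_raman_map,
)


class TestAnisotropy:
    @pytest.mark.parametrize(
        "i_vv,i_vh,g,expected",
        [
            (100.0, 100.0, 1.0, 0.0),       # isotropic
            (50.0, 0.0, 1.0, 1.0),          # fully polarized limit
            (300.0, 100.0, 0.99, 201.0 / 498.0),  # direct evaluation
        ],
    )
    def test_pointwise_values(self, i_vv, i_vh, g, expected):
        assert anisotropy(AnisotropyObservation(i_vv, i_vh, g)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_map_marks_undefined_pixels_nan(self):
        vv = np.array([[100.0, 0.0]])
        vh = np.array([[100.0, 0.0]])
        r = anisotropy(i_vv=vv, i_vh=vh, g=1.0)
        assert r[0, 0] == pytest.approx(0.0)
        assert np.isnan(r[0, 1])

    def test_isotropic_emitter_population(self, rng):
        """A shot-noise image of an isotropic solution has r = 0 within noise."""
        lam = 500.0
        vv = rng.poisson(lam, 10_000).astype(float)
        vh = rng.poisson(lam, 10_000).astype(float)
        r = anisotropy(i_vv=vv, i_vh=vh, g=1.0)
        assert abs(np.nanmean(r)) < 3.0 / np.sqrt(10_000)


class TestSectorsAndOrientation:
    @pytest.mark.parametrize(
        "ratio,expected",
        [(0.5, 45.0), (1.0, 54.7356), (0.0, 0.0)],
    )
    def test_reduced_formula_inversion(self, ratio, expected):
        s = SectorIntensities(f_up_down=ratio, f_left_right=1.0)
        assert orientation_angle(s) == pytest.approx(expected, abs=1e-3)

    def test_zero_parallel_signal_hits_boundary(self):
        s = SectorIntensities(f_up_down=1.0, f_left_right=0.0)
        assert orientation_angle(s) == 90.0

    def test_monotone_in_ratio(self):
        ratios = np.linspace(0.0, 5.0, 40)
        angles = [
            orientation_angle(SectorIntensities(r, 1.0)) for r in ratios
        ]
        assert np.all(np.diff(angles) > 0)

    def test_uniform_ring_gives_unit_ratio(self):
        geom = GuvGeometry(center=(79.5, 79.5), radius_px=60.0, ring_sigma_px=2.0)
        rr = np.hypot(*np.meshgrid(np.arange(160) - 79.5, np.arange(160) - 79.5))
        ring = np.exp(-0.5 * ((rr - 60.0) / 1.5) ** 2)
        s = sector_integrate(ring, geom)
        assert s.ratio == pytest.approx(1.0, abs=1e-6)

    def test_magic_angle_ring_ratio_unity(self):
        pair = render_guv_image(
            GuvRenderSpec(tilt_nu=54.7356, shot_noise=False, photons_per_px=50)
        )
        s = sector_integrate(pair.total_intensity(), pair.geometry)
        assert s.ratio == pytest.approx(1.0, abs=1e-3)

    def test_45_degree_ring_ratio_half(self):
        pair = render_guv_image(
            GuvRenderSpec(tilt_nu=45.0, shot_noise=False, photons_per_px=50)
        )
        s = sector_integrate(pair.total_intensity(), pair.geometry)
        assert s.ratio == pytest.approx(0.5, abs=1e-2)

    @pytest.mark.parametrize("nu", [20.0, 30.0, 40.0, 50.0, 60.0])
    def test_noise_free_round_trip(self, nu):
        """Render → sector-integrate → invert recovers the tilt to 0.5°."""
        pair = render_guv_image(
            GuvRenderSpec(tilt_nu=nu, shot_noise=False, photons_per_px=50)
        )
        est = RingOrientationEstimator().fit(pair)
        assert est.nu_ == pytest.approx(nu, abs=0.5)

    @pytest.mark.parametrize("nu", [30.0, 45.0])
    def test_noisy_round_trip_within_two_degrees(self, nu):
        """With ~1e4 photons collected per sector, shot noise moves the
        estimate by well under 2 degrees."""
        pair = render_guv_image(
            GuvRenderSpec(tilt_nu=nu, shot_noise=True, photons_per_px=90.0, seed=21)
        )
        est = RingOrientationEstimator().fit(pair)
        assert est.sectors_.f_left_right + est.sectors_.f_up_down > 1e4
        assert est.nu_ == pytest.approx(nu, abs=2.0)

    def test_rotation_invariance_with_corotated_metadata(self):
        """Rotating the image and the polarization-axis metadata together
        leaves the estimated tilt unchanged (up to interpolation noise)."""
        base = render_guv_image(
            GuvRenderSpec(tilt_nu=40.0, shot_noise=False, photons_per_px=50,
                          polarization_angle_deg=90.0)
        )
        rotated = render_guv_image(
            GuvRenderSpec(tilt_nu=40.0, shot_noise=False, photons_per_px=50,
                          polarization_angle_deg=30.0)
        )
        nu0 = RingOrientationEstimator().fit(base).nu_
        nu1 = RingOrientationEstimator().fit(rotated).nu_
        assert nu1 == pytest.approx(nu0, abs=0.2)

    def test_ring_localization(self):
        pair = render_guv_image(
            GuvRenderSpec(tilt_nu=54.7356, shot_noise=False, photons_per_px=50)
        )
        center, radius = fit_ring(pair.total_intensity())
        assert center[0] == pytest.approx(79.5, abs=0.5)
        assert center[1] == pytest.approx(79.5, abs=0.5)
        assert radius == pytest.approx(60.0, abs=1.0)

    def test_empty_sector_mask_signalled(self):
        geom = GuvGeometry(center=(5.0, 5.0), radius_px=200.0)
        with pytest.raises(ValueError, match="empty"):
            sector_integrate(np.ones((16, 16)), geom)


class TestLifetimes:
    def test_exact_single_exponential(self):
        t = np.linspace(0.0, 20.0, 400)
        counts = 1000.0 * np.exp(-t / 2.0)
        fit = fit_lifetimes(t, counts, n_components=1)
        assert fit.mean_lifetime_ == pytest.approx(2.0, rel=1e-4)
        assert fit.amplitudes_[0] == pytest.approx(1.0)

    def test_amplitude_weighted_mean_of_two_components(self):
        t = np.linspace(0.0, 30.0, 600)
        counts = 500.0 * np.exp(-t / 1.0) + 500.0 * np.exp(-t / 3.0)
        fit = fit_lifetimes(t, counts, n_components=2, tau_init=(0.8, 3.5))
        assert np.isclose(fit.amplitudes_.sum(), 1.0, atol=1e-9)
        assert fit.mean_lifetime_ == pytest.approx(2.0, rel=1e-3)

    def test_recovery_from_poisson_noise(self, rng):
        """Two-exponential fit on a noisy histogram with ~1e5 total counts
        recovers both lifetimes within 10%."""
        t = np.linspace(0.0, 25.0, 500)
        model = 1300.0 * np.exp(-t / 1.0) + 1300.0 * np.exp(-t / 3.0)
        counts = rng.poisson(model).astype(float)
        assert counts.sum() > 1e5
        fit = fit_lifetimes(t, counts, n_components=2, tau_init=(0.5, 5.0))
        assert fit.lifetimes_[0] == pytest.approx(1.0, rel=0.10)
        assert fit.lifetimes_[1] == pytest.approx(3.0, rel=0.10)

    def test_predict_matches_normalized_model(self):
        t = np.linspace(0.0, 20.0, 100)
        fit = fit_lifetimes(t, np.exp(-t / 2.0), n_components=1)
        assert fit.predict(np.array([0.0]))[0] == pytest.approx(1.0, rel=1e-6)


class TestConfocalVolumeAndConcentration:
    def test_reference_alignment_volume(self):
        v = confocal_volume(ConfocalGeometry(x0_nm=202.0, z0_nm=1010.0))
        assert v == pytest.approx(0.23, abs=0.005)

    def test_direct_evaluation(self):
        v = confocal_volume(ConfocalGeometry(100.0, 100.0))
        assert v == pytest.approx(np.pi**1.5 * 1e6 / 1e9, rel=1e-12)
        assert v == pytest.approx(5.568e-3, rel=1e-3)

    def test_scaling_laws(self):
        base = confocal_volume(ConfocalGeometry(150.0, 600.0))
        assert confocal_volume(ConfocalGeometry(300.0, 600.0)) == pytest.approx(
            4 * base
        )
        assert confocal_volume(ConfocalGeometry(150.0, 1200.0)) == pytest.approx(
            2 * base
        )

    def test_macular_surface_density_mol_percent(self):
        assert mol_percent_from_surface_density(62.0, 0.6, 2) == pytest.approx(
            0.48, abs=0.01
        )


class TestBandIntegration:
    def test_flat_spectrum_zero_after_baseline(self):
        wn = np.arange(350.0, 1901.0, 2.0)
        cube = RamanCube(np.ones((2, 2, wn.size)), wn)
        img = integrate_band(cube)
        assert np.allclose(img, 0.0, atol=1e-9)

    def test_gaussian_band_area_recovered(self):
        wn = np.arange(350.0, 1901.0, 1.0)
        width, amp = 6.0, 10.0
        spec = 3.0 + amp * np.exp(-0.5 * ((wn - 1520.0) / width) ** 2)
        cube = RamanCube(spec[None, None, :], wn)
        area = amp * width * np.sqrt(2 * np.pi)
        assert integrate_band(cube)[0, 0] == pytest.approx(area, rel=0.01)

    def test_band_outside_axis_rejected(self):
        wn = np.arange(350.0, 1000.0, 2.0)
        cube = RamanCube(np.ones((1, 1, wn.size)), wn)
        with pytest.raises(ValueError, match="outside"):
            integrate_band(cube)

    def test_raman_image_orientation_consistent_with_fluorescence(self):
        """Sector analysis of the band-integral image returns the same tilt
        as the fluorescence route (same photoselection physics)."""
        geom = GuvGeometry(center=(31.5, 31.5), radius_px=20.0,
                           ring_sigma_px=1.5)
        cube = render_raman_map(geom, tilt_nu=35.0, image_shape=(64, 64),
                                shot_noise=False, band_amplitude=100.0)
        img = integrate_band(cube)
        from xanthotilt.imaging import (
            orientation_angle_finite_cone,
        )
        s = sector_integrate(img, geom)
        assert orientation_angle_finite_cone(s) == pytest.approx(35.0, abs=1.0)
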