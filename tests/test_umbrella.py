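"""Free-energy route: WHAM, bootstrap, angle mapping, distributions."""

import numpy as np
import pytest

from xanthotilt.constants import rt_kcal_per_mol
from xanthotilt.pipeline import true_mean_phi
from xanthotilt.umbrella import (
    FreeEnergyProfile,
    UmbrellaWindow,
    WhamConnectivityError,
    WhamEstimator,
    angle_distribution,
    bootstrap_uncertainty,
    classify_orientation,
    horizontal_penalty,
    integrated_autocorrelation_time,
    map_z_to_angle,
    population_ratio,
    wham,
)

RT320 = rt_kcal_per_mol(320.0)


def double_well(z):
    return 1.5 * ((z - 5.0) / 2.5) ** 4 - 2.0 * ((z - 5.0) / 2.5) ** 2


def boltzmann_samples(u_func, lo, hi, n, rng, rt=RT320):
    """Direct inverse-CDF sampling from exp(-U/RT): the independent oracle."""
    grid = np.linspace(lo, hi, 4001)
    p = np.exp(-(u_func(grid) - u_func(grid).min()) / rt)
    cdf = np.cumsum(p)
    cdf /= cdf[-1]
    return np.interp(rng.uniform(size=n), cdf, grid)


class TestWham:
    def test_unbiased_window_recovers_boltzmann_inversion(self, rng):
        """A single unbiased window sampled exactly from exp(-U/RT) must give
        back U (direct Boltzmann-inversion oracle), RMSD < 0.15 kcal/mol on
        well-sampled bins."""
        samples = boltzmann_samples(double_well, 0.0, 10.0, 200_000, rng)
        w = UmbrellaWindow(center=5.0, spring_k=0.0, samples=samples)
        est = WhamEstimator(bin_width=0.1).fit([w])
        counts = est.counts_[0]
        good = counts >= 100
        g_true = double_well(est.grid_)
        diff = est.free_energy_[good] - g_true[good]
        diff -= diff.mean()  # free additive constant
        assert np.sqrt(np.mean(diff**2)) < 0.15

    def test_duplicated_window_changes_nothing(self, rng):
        samples = boltzmann_samples(double_well, 0.0, 10.0, 20_000, rng)
        w = UmbrellaWindow(5.0, 0.0, samples)
        p1 = wham([w], bin_width=0.2)
        p2 = wham([w, UmbrellaWindow(5.0, 0.0, samples.copy())], bin_width=0.2)
        ok = np.isfinite(p1.values)
        assert np.allclose(p1.values[ok], p2.values[ok], atol=1e-6)

    def test_offset_initialization_invariance(self, umbrella_windows):
        est0 = WhamEstimator(bin_width=0.2).fit(umbrella_windows)
        est1 = WhamEstimator(bin_width=0.2).fit(
            umbrella_windows, init_offsets=np.full(len(umbrella_windows), 3.7)
        )
        ok = np.isfinite(est0.free_energy_)
        assert np.allclose(est0.free_energy_[ok], est1.free_energy_[ok], atol=1e-5)

    def test_eleven_window_layout_recovers_input_pmf(
        self, umbrella_windows, reference_pmf
    ):
        """The full umbrella layout (11 windows, k = 3 kcal/mol/Å², 320 K)
        reconstructs the prescribed landscape within 0.2 kcal/mol RMSD."""
        from scipy.interpolate import CubicSpline
        est = WhamEstimator(bin_width=0.1, z_range=(0.0, 11.8))
        est.fit(umbrella_windows)
        g_true = CubicSpline(reference_pmf.grid, reference_pmf.values)(est.grid_)
        ok = np.isfinite(est.free_energy_)
        diff = est.free_energy_[ok] - g_true[ok]
        diff -= diff.mean()
        assert np.sqrt(np.mean(diff**2)) < 0.2

    def test_disconnected_windows_signalled(self, rng):
        w1 = UmbrellaWindow(0.0, 3.0, rng.normal(0.0, 0.2, 1000))
        w2 = UmbrellaWindow(10.0, 3.0, rng.normal(10.0, 0.2, 1000))
        with pytest.raises(WhamConnectivityError, match="overlap"):
            WhamEstimator(bin_width=0.1).fit([w1, w2])

    def test_min_of_profile_is_zero(self, umbrella_windows):
        prof = wham(umbrella_windows, bin_width=0.2)
        assert np.nanmin(prof.values) == pytest.approx(0.0, abs=1e-12)


class TestBootstrap:
    def test_constant_series_zero_stderr(self):
        w = UmbrellaWindow(5.0, 3.0, np.full(500, 5.0))
        est = WhamEstimator(bin_width=0.5).fit([w])
        stderr = est.bootstrap(n_boot=20, seed=0)
        ok = np.isfinite(stderr)
        assert np.all(stderr[ok] < 1e-9)

    def test_clt_scaling_with_sample_size(self, rng):
        """For independent samples the per-bin error shrinks as 1/sqrt(N)."""
        def run(n, seed):
            s = boltzmann_samples(lambda z: 0.5 * 3.0 * (z - 5.0) ** 2,
                                  2.0, 8.0, n, np.random.default_rng(seed))
            est = WhamEstimator(bin_width=0.25, z_range=(2.0, 8.0)).fit(
                [UmbrellaWindow(5.0, 0.0, s)]
            )
            stderr = est.bootstrap(n_boot=120, seed=1)
            # compare the same well-populated central bins in both runs
            good = np.abs(est.grid_ - 5.0) < 1.0
            return np.nanmedian(stderr[good])

        e1, e4 = run(4_000, 11), run(16_000, 12)
        assert e1 / e4 == pytest.approx(2.0, rel=0.20)

    def test_ar1_autocorrelation_time(self, rng):
        """Block estimator reproduces the analytic tau_int of an AR(1)
        series, 1 + 2 phi/(1 - phi), within a factor of two."""
        phi = 0.9
        n = 200_000
        eps = rng.normal(size=n)
        x = np.empty(n)
        x[0] = eps[0]
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        tau_true = 1 + 2 * phi / (1 - phi)  # = 19
        tau_est = integrated_autocorrelation_time(x)
        assert tau_true / 2 < tau_est < tau_true * 2

    def test_white_noise_tau_is_one(self, rng):
        tau = integrated_autocorrelation_time(rng.normal(size=50_000))
        assert tau == pytest.approx(1.0, abs=0.2)

    def test_window_too_short_for_blocks_signalled(self):
        # strongly correlated, tiny series: block length ~ series length
        x = np.concatenate([np.zeros(5), np.ones(5)]) + np.linspace(0, 1e-6, 10)
        w = UmbrellaWindow(0.0, 0.0, x)
        est = WhamEstimator(bin_width=1.0).fit([w])
        with pytest.raises(ValueError, match="block"):
            est.bootstrap(n_boot=10, seed=0)


class TestAngleMapping:
    def test_endpoints(self):
        prof = FreeEnergyProfile(np.array([0.0, 5.9, 11.8]),
                                 np.array([1.0, 0.0, 2.0]))
        mapped = map_z_to_angle(prof, ell=11.8)
        assert mapped.grid[0] == pytest.approx(0.0)    # z = ell -> vertical
        assert mapped.grid[-1] == pytest.approx(90.0)  # z = 0 -> horizontal
        assert mapped.coordinate_kind == "phi_angle"

    def test_argmin_preserved_under_substitution(self):
        ell = 11.8
        z = np.linspace(0.0, ell, 200)
        z_min = ell * np.cos(np.deg2rad(25.0))
        prof = FreeEnergyProfile(z, (z - z_min) ** 2)
        mapped = map_z_to_angle(prof, ell=ell)
        assert mapped.argmin == pytest.approx(25.0, abs=0.5)

    def test_out_of_range_z_rejected(self):
        prof = FreeEnergyProfile(np.array([0.0, 12.5]), np.array([0.0, 1.0]))
        with pytest.raises(ValueError, match="ell"):
            map_z_to_angle(prof, ell=11.8)

    def test_stderr_carried_through(self):
        prof = FreeEnergyProfile(np.array([0.0, 5.9, 11.8]),
                                 np.array([1.0, 0.0, 2.0]),
                                 np.array([0.1, 0.2, 0.3]))
        mapped = map_z_to_angle(prof)
        assert set(mapped.stderr) == {0.1, 0.2, 0.3}


class TestAngleDistribution:
    def grid_profile(self, g):
        phi = np.linspace(0.0, 90.0, 901)
        return FreeEnergyProfile(phi, g(phi), None, "phi_angle")

    def test_delta_well_mean(self):
        prof = self.grid_profile(lambda p: 200.0 * (np.abs(p - 36.5) > 0.5))
        dist = angle_distribution(prof)
        assert dist.mean_angle == pytest.approx(36.5, abs=0.1)

    def test_flat_profile_with_jacobian(self):
        """Uniform G with the sin(phi) factor: mean = 1 rad = 57.296°."""
        dist = angle_distribution(self.grid_profile(lambda p: np.zeros_like(p)))
        assert dist.mean_angle == pytest.approx(np.degrees(1.0), abs=0.05)

    def test_flat_profile_without_jacobian(self):
        dist = angle_distribution(
            self.grid_profile(lambda p: np.zeros_like(p)), jacobian=False
        )
        assert dist.mean_angle == pytest.approx(45.0, abs=1e-6)

    def test_normalization_exact(self):
        prof = self.grid_profile(lambda p: 0.01 * (p - 30.0) ** 2)
        dist = angle_distribution(prof)
        assert np.trapezoid(dist.density, dist.grid) == pytest.approx(1.0, abs=1e-6)
        assert 0.0 <= dist.mean_angle <= 90.0


class TestPopulationAndClassification:
    def test_reference_penalty_ratio(self):
        """A 1.4 kcal/mol penalty difference at 320 K gives a ~10x population
        ratio (exp(1.4/RT) = 9.0)."""
        ratio = population_ratio(1.4, 320.0)
        assert ratio == pytest.approx(np.exp(1.4 / RT320), rel=1e-12)
        assert ratio == pytest.approx(9.04, abs=0.01)

    def test_identity_and_e_point(self):
        assert population_ratio(0.0) == 1.0
        assert population_ratio(RT320, 320.0) == pytest.approx(np.e)

    def test_strictly_increasing(self):
        dgs = np.linspace(-2, 2, 50)
        vals = [population_ratio(d) for d in dgs]
        assert np.all(np.diff(vals) > 0)

    @pytest.mark.parametrize(
        "phi,expected",
        [(71.0, "horizontal"), (70.0, "vertical"), (25.0, "vertical")],
    )
    def test_orientation_classes(self, phi, expected):
        assert classify_orientation(phi) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            classify_orientation(95.0)

    def test_horizontal_penalty_reads_region_minimum(self):
        phi = np.linspace(0.0, 90.0, 91)
        g = 0.001 * (phi - 25.0) ** 2
        g[phi > 70] = 2.5
        prof = FreeEnergyProfile(phi, g, None, "phi_angle")
        assert horizontal_penalty(prof) == pytest.approx(2.5, abs=1e-9)
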