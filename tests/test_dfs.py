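"""Rupture-CDF fitting, subgroup statistics and the global landscape fit."""

import numpy as np
import pytest

from flospec import EnergyLandscape, LoadingRate
from flospec import evans
from flospec.dfs import (RuptureDataset, analyze_rupture_datasets,
                         empirical_cdf, fit_cdf_points, fit_force_vs_loading_rate,
                         fit_rupture_cdf, project_single_bond, random_partition,
                         subgroup_statistics)


class TestEmpiricalCdf:
    def test_three_points(self):
        grid, probs = empirical_cdf([2.0, 1.0, 3.0])
        assert np.array_equal(grid, [1.0, 2.0, 3.0])
        assert np.allclose(probs, [1 / 3, 2 / 3, 1.0])

    def test_ties_share_highest_position(self):
        grid, probs = empirical_cdf([1.0, 2.0, 2.0, 3.0])
        assert np.allclose(probs, [0.25, 0.75, 0.75, 1.0])

    def test_matches_true_cdf_within_dkw_band(self, env, dig_landscape, rate_05):
        f = evans.sample_rupture_forces(dig_landscape, rate_05, env, 10_000,
                                        seed=13)
        grid, probs = empirical_cdf(f)
        true = evans.rupture_cdf(grid, dig_landscape, rate_05, env)
        crit_1pct = 1.63 / np.sqrt(f.size)
        assert np.max(np.abs(probs - true)) < crit_1pct


class TestFitRuptureCdf:
    def test_noiseless_quantile_points_recover_exactly(self, env, dig_landscape,
                                                       rate_05):
        # equi-probability points on the exact CDF: a noiseless inverse problem
        probs = (np.arange(1, 201) - 0.5) / 200
        forces = evans.quantile(probs, dig_landscape, rate_05, env)
        fit = fit_cdf_points(forces, probs, rate_05, env)
        assert fit.landscape.delta_x == pytest.approx(0.76, rel=1e-4)
        assert fit.landscape.k_off == pytest.approx(4.0e-4, rel=1e-4)

    def test_sampled_data_recovery(self, env, dig_landscape, rate_05):
        f = evans.sample_rupture_forces(dig_landscape, rate_05, env, 2000,
                                        seed=1)
        fit = fit_rupture_cdf(RuptureDataset(f, rate_05), env)
        assert fit.landscape.delta_x == pytest.approx(0.76, rel=0.15)
        assert abs(np.log10(fit.landscape.k_off / 4.0e-4)) < 0.5

    def test_exact_and_series_methods_agree(self, env, dig_landscape, rate_05):
        f = evans.sample_rupture_forces(dig_landscape, rate_05, env, 2000,
                                        seed=2)
        data = RuptureDataset(f, rate_05)
        fit_e = fit_rupture_cdf(data, env, method="exact")
        fit_s = fit_rupture_cdf(data, env, method="series", n_terms=50)
        assert fit_s.landscape.delta_x == pytest.approx(
            fit_e.landscape.delta_x, rel=0.02)

    def test_below_sample_floor_rejected(self, env, rate_05):
        with pytest.raises(ValueError, match="at least"):
            fit_rupture_cdf(RuptureDataset(np.linspace(1, 10, 10), rate_05), env)


class TestSubgroupStatistics:
    def test_partition_is_disjoint_and_exhaustive(self):
        parts = random_partition(100, 3, seed=0)
        sizes = [p.size for p in parts]
        assert max(sizes) - min(sizes) <= 1
        combined = np.concatenate(parts)
        assert np.array_equal(np.sort(combined), np.arange(100))

    def test_subgroup_sd_is_small_at_large_n(self, env, dig_landscape, rate_05):
        f = evans.sample_rupture_forces(dig_landscape, rate_05, env, 3000,
                                        seed=3)
        res = subgroup_statistics(RuptureDataset(f, rate_05), env, seed=4)
        assert len(res.fits) == 3
        assert res.f_star_sd < 1.0
        assert res.f_star_mean == pytest.approx(
            evans.most_probable_force(dig_landscape, rate_05, env), abs=1.5)

    def test_insufficient_n_rejected(self, env, rate_05):
        f = np.linspace(1.0, 30.0, 50)
        with pytest.raises(ValueError):
            subgroup_statistics(RuptureDataset(f, rate_05), env, n_groups=3)

    def test_reproducible_under_seed(self, env, dig_landscape, rate_05):
        f = evans.sample_rupture_forces(dig_landscape, rate_05, env, 300, seed=5)
        a = subgroup_statistics(RuptureDataset(f, rate_05), env, seed=6)
        b = subgroup_statistics(RuptureDataset(f, rate_05), env, seed=6)
        assert a.f_star_mean == b.f_star_mean
        assert a.f_star_sd == b.f_star_sd


class TestGlobalFit:
    def test_exact_points_recover_landscape(self, env):
        truth = EnergyLandscape(k_off=1e-4, delta_x=1.0)
        rates = [0.5, 1.5, 5.0]
        points = [(fd, evans.most_probable_force(truth, LoadingRate(fd), env))
                  for fd in rates]
        fit = fit_force_vs_loading_rate(points, env)
        assert fit.landscape.delta_x == pytest.approx(1.0, rel=1e-9)
        assert fit.landscape.k_off == pytest.approx(1e-4, rel=1e-9)

    def test_serial_bond_consistency_and_bias(self, env):
        truth = EnergyLandscape(k_off=1e-4, delta_x=1.0)
        rates = [0.5, 1.5, 5.0]
        points = [(fd, evans.most_probable_force(truth, LoadingRate(fd), env,
                                                 n_serial=3))
                  for fd in rates]
        fit3 = fit_force_vs_loading_rate(points, env, n_serial=3)
        assert fit3.landscape.k_off == pytest.approx(1e-4, rel=1e-9)
        # ignoring the serial correction inflates k_off exactly 3-fold
        fit1 = fit_force_vs_loading_rate(points, env, n_serial=1)
        assert fit1.landscape.k_off == pytest.approx(3e-4, rel=1e-9)
        assert fit1.landscape.delta_x == pytest.approx(
            fit3.landscape.delta_x, rel=1e-12)

    def test_order_invariant(self, env):
        truth = EnergyLandscape(k_off=1e-4, delta_x=1.0)
        pts = [(fd, evans.most_probable_force(truth, LoadingRate(fd), env))
               for fd in (0.2, 0.9, 3.0, 12.0)]
        a = fit_force_vs_loading_rate(pts, env)
        b = fit_force_vs_loading_rate(pts[::-1], env)
        assert a.landscape.delta_x == pytest.approx(b.landscape.delta_x,
                                                    rel=1e-12)

    def test_non_positive_slope_rejected(self, env):
        with pytest.raises(ValueError, match="slope"):
            fit_force_vs_loading_rate([(0.5, 30.0), (5.0, 20.0)], env)


class TestProjection:
    def test_single_bond_sits_above_triple_by_log3(self, env):
        landscape = EnergyLandscape(k_off=4.7e-6, delta_x=0.95)
        grid = np.logspace(-1, 1, 5)
        single = project_single_bond(landscape, env, grid)
        triple = np.array([evans.most_probable_force(
            landscape, LoadingRate(fd), env, n_serial=3) for fd in grid])
        shift = env.thermal_energy / landscape.delta_x * np.log(3.0)
        assert np.allclose(single - triple, shift, rtol=1e-12)
        assert np.all(np.diff(single) > 0)

    def test_projection_matches_density_argmax(self, env):
        landscape = EnergyLandscape(k_off=4.7e-6, delta_x=0.95)
        rate = LoadingRate(1.0)
        grid = np.arange(0.0, 100.0, 1e-3)
        dens = evans.rupture_density(grid, landscape, rate, env)
        proj = project_single_bond(landscape, env, [1.0])[0]
        assert abs(grid[np.argmax(dens)] - proj) <= 1e-3


@pytest.mark.parametrize("k_off,delta_x,n_serial", [
    (4.0e-4, 0.76, 1),   # antibody bond, ramp chip
    (7.9e-5, 1.1, 1),    # antibody bond, multiplexed chip
    (4.7e-6, 0.95, 3),   # triple biotin-streptavidin anchor
    (2.2e-4, 4.1, 1),    # 9 bp duplex unzipping
])
def test_end_to_end_parameter_recovery(env, k_off, delta_x, n_serial):
    """Sample -> per-rate fit -> global fit recovers the generating landscape."""
    truth = EnergyLandscape(k_off=k_off, delta_x=delta_x)
    rates = (0.5, 1.5, 5.0)
    recovered_dx, recovered_logk = [], []
    for seed in (1, 2, 3):
        rng = np.random.default_rng(seed)
        datasets = []
        for fd in rates:
            rate = LoadingRate(fd)
            f = evans.sample_rupture_forces(truth, rate, env, 2000, seed=rng)
            datasets.append(RuptureDataset(f, rate))
        res = analyze_rupture_datasets(datasets, env, n_serial=n_serial,
                                       seed=seed)
        recovered_dx.append(res.global_fit.landscape.delta_x)
        recovered_logk.append(np.log10(res.global_fit.landscape.k_off))
    assert np.mean(recovered_dx) == pytest.approx(delta_x, rel=0.15)
    assert abs(np.mean(recovered_logk) - np.log10(k_off)) < 0.5


def test_f_star_shift_under_doubled_loading_rate(env, dig_landscape):
    """Regenerating all samples at 2x the rate shifts fitted F* by (kBT/dx)ln2."""
    shift_true = env.thermal_energy / dig_landscape.delta_x * np.log(2.0)
    rate1, rate2 = LoadingRate(1.0), LoadingRate(2.0)
    f1 = evans.sample_rupture_forces(dig_landscape, rate1, env, 4000, seed=21)
    f2 = evans.sample_rupture_forces(dig_landscape, rate2, env, 4000, seed=22)
    fit1 = fit_rupture_cdf(RuptureDataset(f1, rate1), env)
    fit2 = fit_rupture_cdf(RuptureDataset(f2, rate2), env)
    assert fit2.f_star - fit1.f_star == pytest.approx(shift_true, abs=0.5)
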