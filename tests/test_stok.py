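"""Kriging: covariance estimation/fitting, solver exactness, field behavior."""

import numpy as np
import pandas as pd
import pytest

import airtier as at
from airtier.stok import (
    KrigingError,
    _solve_ok_system,
    empirical_covariance,
    validate_hard_data,
)


def _hours(n, start="2012-01-01"):
    return pd.date_range(start, periods=n, freq="h")


def make_hard_data(xy, hours, values):
    """Long monitor table from station coords, hour index and (S, T) values."""
    xy = np.asarray(xy, dtype=float)
    values = np.asarray(values, dtype=float)
    return pd.DataFrame(
        {
            "station_id": np.repeat([f"s{i}" for i in range(len(xy))], len(hours)),
            "x_km": np.repeat(xy[:, 0], len(hours)),
            "y_km": np.repeat(xy[:, 1], len(hours)),
            "hour": np.tile(hours, len(xy)),
            "value": values.ravel(),
        }
    )


class TestEmpiricalCovariance:
    def test_origin_bin_is_sample_variance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(10, 2, (4, 50))
        hd = make_hard_data(rng.uniform(0, 30, (4, 2)), _hours(50), vals)
        out = empirical_covariance(hd, [0.0, 1e-6, 10.0, 40.0], [0, 1, 2])
        origin = out[(out["spatial_lag"] == 0.0) & (out["temporal_lag"] == 0.0)]
        assert origin["covariance"].iloc[0] == pytest.approx(vals.var(), rel=1e-12)

    def test_white_noise_off_origin_near_zero(self):
        rng = np.random.default_rng(1)
        sigma = 2.0
        vals = rng.normal(0, sigma, (10, 400))
        hd = make_hard_data(rng.uniform(0, 50, (10, 2)), _hours(400), vals)
        out = empirical_covariance(hd, [0.0, 1e-6, 20.0, 80.0], [0, 2, 5])
        off = out[(out["spatial_lag"] > 0) | (out["temporal_lag"] > 0)]
        # SE of a mean of ~N products of independent sigma^2 variables
        se = sigma**2 / np.sqrt(off["n_pairs"].to_numpy())
        assert (np.abs(off["covariance"]) < 4 * se).all()

    def test_single_station_rejected(self):
        hd = make_hard_data([[0, 0]], _hours(10), np.zeros((1, 10)))
        with pytest.raises(KrigingError, match="2 stations"):
            empirical_covariance(hd, [0, 1, 2], [0, 1])

    def test_duplicate_observations_rejected(self):
        hd = make_hard_data([[0, 0], [1, 0]], _hours(5), np.ones((2, 5)))
        with pytest.raises(ValueError, match="duplicate"):
            validate_hard_data(pd.concat([hd, hd.iloc[:1]]))


class TestFitCovariance:
    @staticmethod
    def _exact_bins(cov, h_lags, t_lags, n_pairs=100):
        rows = []
        for h in h_lags:
            for t in t_lags:
                rows.append(
                    {
                        "spatial_lag": h,
                        "temporal_lag": t,
                        "covariance": cov.sill
                        * cov.spatial_corr(h)
                        * cov.temporal_corr(t),
                        "n_pairs": n_pairs,
                    }
                )
        return pd.DataFrame(rows)

    def test_recovers_exact_bins(self):
        true = at.SpaceTimeCovariance(sill=4.0, spatial_range=18.0, temporal_range=9.0)
        bins = self._exact_bins(true, [0, 4, 9, 15, 25], [0, 2, 5, 10])
        fit, info = at.fit_covariance(bins)
        assert info["converged"]
        assert fit.sill == pytest.approx(4.0, rel=1e-6)
        assert fit.spatial_range == pytest.approx(18.0, rel=1e-6)
        assert fit.temporal_range == pytest.approx(9.0, rel=1e-6)

    def test_flat_covariance_flags_range_bound(self):
        bins = pd.DataFrame(
            {
                "spatial_lag": [0, 5, 10, 0, 5, 10, 0, 5, 10],
                "temporal_lag": [0, 0, 0, 3, 3, 3, 6, 6, 6],
                "covariance": 2.0,
                "n_pairs": 100,
            }
        )
        fit, info = at.fit_covariance(bins)
        assert any("upper_bound" in f for f in info["flags"])

    def test_too_few_lags_rejected(self):
        bins = pd.DataFrame(
            {"spatial_lag": [0, 1], "temporal_lag": [0, 1], "covariance": 1.0,
             "n_pairs": 10}
        )
        with pytest.raises(KrigingError, match="3 distinct"):
            at.fit_covariance(bins)

    def test_simulation_recovery_within_20pct(self):
        true = at.SpaceTimeCovariance(sill=4.0, spatial_range=15.0, temporal_range=10.0)
        rng = np.random.default_rng(0)
        sills, s_ranges, t_ranges = [], [], []
        for seed in range(20):
            xy = rng.uniform(0, 40, (30, 2))
            vals = at.sample_gaussian_field(xy, _hours(150), true, mean=0.0, seed=seed)
            hd = make_hard_data(xy, _hours(150), vals)
            binned = empirical_covariance(
                hd, np.concatenate([[0.0, 1e-6], np.linspace(3, 45, 7)]), np.arange(12)
            )
            fit, _ = at.fit_covariance(binned)
            sills.append(fit.sill)
            s_ranges.append(fit.spatial_range)
            t_ranges.append(fit.temporal_range)
        assert np.mean(sills) == pytest.approx(4.0, rel=0.2)
        assert np.mean(s_ranges) == pytest.approx(15.0, rel=0.2)
        assert np.mean(t_ranges) == pytest.approx(10.0, rel=0.2)


class TestKrigingSolver:
    def test_exact_interpolation_at_hard_point(self):
        rng = np.random.default_rng(3)
        xy = rng.uniform(0, 20, (6, 2))
        vals = rng.normal(10, 2, (6, 24))
        hd = make_hard_data(xy, _hours(24), vals)
        cov = at.SpaceTimeCovariance(sill=4, spatial_range=15, temporal_range=8, nugget=0)
        est = at.krige_point(xy[2], _hours(24)[5], hd, cov)
        assert est.estimate == pytest.approx(vals[2, 5], abs=1e-8)
        assert est.variance <= 1e-8

    def test_constant_data_estimated_exactly(self):
        xy = np.array([[0, 0], [5, 0], [10, 10]])
        hd = make_hard_data(xy, _hours(12), np.full((3, 12), 7.5))
        cov = at.SpaceTimeCovariance(sill=2, spatial_range=10, temporal_range=6)
        est = at.krige_point([3.3, 4.4], _hours(12)[6], hd, cov)
        assert est.estimate == pytest.approx(7.5, abs=1e-10)

    def test_weights_match_dense_brute_force(self):
        """Collinear stations: compare against an independent dense solve."""
        cov = at.SpaceTimeCovariance(sill=3.0, spatial_range=12.0, temporal_range=6.0)
        xy = np.array([[0.0, 0.0], [4.0, 0.0], [9.0, 0.0]])
        hours = _hours(4)
        rng = np.random.default_rng(5)
        vals = rng.normal(8, 1.5, (3, 4))
        hd = make_hard_data(xy, hours, vals)
        target_xy, target_t = np.array([6.0, 0.0]), hours[2]

        # brute force: explicit covariance over all 12 data, scipy dense solve
        import itertools
        from scipy.linalg import solve as dense_solve

        pts = list(itertools.product(range(3), range(4)))
        n = len(pts)
        big = np.zeros((n + 1, n + 1))
        rhs = np.zeros(n + 1)
        jitter = 1e-10 * cov.sill
        for a, (i, t) in enumerate(pts):
            for b_, (j, s) in enumerate(pts):
                d = abs(xy[i, 0] - xy[j, 0])
                tau = abs(t - s)
                big[a, b_] = 3.0 * np.exp(-3 * d / 12.0) * np.exp(-3 * tau / 6.0)
                if a == b_:
                    big[a, b_] += jitter
            d0 = abs(xy[i, 0] - target_xy[0])
            tau0 = abs(t - 2)
            rhs[a] = 3.0 * np.exp(-3 * d0 / 12.0) * np.exp(-3 * tau0 / 6.0)
        big[:n, n] = 1.0
        big[n, :n] = 1.0
        rhs[n] = 1.0
        sol = dense_solve(big, rhs)
        oracle_est = sol[:n] @ np.array([vals[i, t] for i, t in pts])

        est = at.krige_point(target_xy, target_t, hd, cov, n_neighbors=n)
        assert est.estimate == pytest.approx(oracle_est, abs=1e-10)

    def test_weight_sums_on_random_systems(self):
        rng = np.random.default_rng(11)
        cov = at.SpaceTimeCovariance(sill=2.0, spatial_range=10.0, temporal_range=5.0)
        for _ in range(100):
            m = rng.integers(3, 20)
            w, var = _solve_ok_system(
                cov, rng.uniform(0, 30, (m, 2)), rng.uniform(0, 48, m),
                rng.uniform(0, 30, 2), float(rng.uniform(0, 48)),
            )
            assert abs(w.sum() - 1.0) < 1e-10


class TestKrigeField:
    def test_daily_cadence_is_constant_within_day(self):
        rng = np.random.default_rng(7)
        xy = rng.uniform(0, 20, (5, 2))
        hours = _hours(72)
        vals = rng.normal(10, 2, (5, 72))
        hd = make_hard_data(xy, hours, vals)
        blocks = pd.DataFrame({"block_id": ["b0", "b1"], "x_km": [5.0, 15.0],
                               "y_km": [5.0, 15.0]})
        cov = at.SpaceTimeCovariance(sill=4, spatial_range=15, temporal_range=8)
        f = at.krige_field(blocks, hours, hd, cov, cadence="daily")
        for day in range(3):
            day_vals = f.values[:, day * 24 : (day + 1) * 24]
            assert np.ptp(day_vals, axis=1).max() == 0.0

    def test_hourly_field_reproduces_monitor_at_coincident_block(self):
        rng = np.random.default_rng(8)
        xy = rng.uniform(0, 20, (6, 2))
        hours = _hours(36)
        vals = rng.normal(10, 2, (6, 36))
        hd = make_hard_data(xy, hours, vals)
        blocks = pd.DataFrame({"block_id": ["b0"], "x_km": [xy[0, 0]], "y_km": [xy[0, 1]]})
        cov = at.SpaceTimeCovariance(sill=4, spatial_range=15, temporal_range=8, nugget=0)
        f = at.krige_field(blocks, hours, hd, cov)
        np.testing.assert_allclose(f.values[0], vals[0], atol=1e-7)

    def test_kriging_beats_nearest_monitor_on_average(self):
        cov = at.SpaceTimeCovariance(sill=4.0, spatial_range=20.0, temporal_range=12.0)
        rng = np.random.default_rng(0)
        rmse_k, rmse_n = [], []
        for seed in range(20):
            n_mon, n_blk = 8, 10
            mon_xy = rng.uniform(0, 30, (n_mon, 2))
            blk_xy = rng.uniform(0, 30, (n_blk, 2))
            hours = _hours(48)
            all_vals = at.sample_gaussian_field(
                np.vstack([blk_xy, mon_xy]), hours, cov, mean=10.0, seed=seed
            )
            truth, mon_vals = all_vals[:n_blk], all_vals[n_blk:]
            hd = make_hard_data(mon_xy, hours, mon_vals)
            blocks = pd.DataFrame(
                {"block_id": [f"b{i}" for i in range(n_blk)],
                 "x_km": blk_xy[:, 0], "y_km": blk_xy[:, 1]}
            )
            kriged = at.krige_field(blocks, hours, hd, cov)
            nearest = at.nearest_monitor_field(blocks, hours, hd)
            rmse_k.append(np.sqrt(np.mean((kriged.values - truth) ** 2)))
            rmse_n.append(np.sqrt(np.mean((nearest.values - truth) ** 2)))
        assert np.mean(rmse_k) < np.mean(rmse_n)

    def test_loo_standardized_errors_calibrated(self):
        cov = at.SpaceTimeCovariance(sill=4.0, spatial_range=20.0, temporal_range=12.0)
        rng = np.random.default_rng(1)
        means, variances = [], []
        for seed in range(20):
            xy = rng.uniform(0, 30, (8, 2))
            hours = _hours(72)
            vals = at.sample_gaussian_field(xy, hours, cov, mean=10.0, seed=100 + seed)
            hd = make_hard_data(xy, hours, vals)
            cv = at.loo_cross_validation(hd, cov)
            means.append(cv["std_error"].mean())
            variances.append(cv["std_error"].var())
        assert -0.1 < np.mean(means) < 0.1
        assert 0.8 < np.mean(variances) < 1.2
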