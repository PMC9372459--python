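"""Variogram estimation and ordinary-kriging depth restoration."""

import numpy as np
import pytest

from citrus3d.kriging import (
    KrigingConfig,
    VariogramModel,
    empirical_variogram,
    fit_variogram,
    krige_fill,
    krige_fill_dense,
    make_missing_mask,
    restoration_error,
)
from conftest import disc_mask


def line_coords(n):
    return np.column_stack([np.arange(n), np.zeros(n)])


class TestEmpiricalVariogram:
    def test_constant_field_has_zero_semivariance(self):
        table = empirical_variogram(line_coords(30), np.full(30, 7.0))
        assert (table[:, 1] == 0.0).all()
        assert (table[:, 2] > 0).all()

    def test_matches_brute_force_pair_enumeration(self):
        """Independent O(n^2) loop over all pairs reproduces each bin."""
        rng = np.random.default_rng(1)
        coords = rng.integers(0, 15, (40, 2)).astype(float)
        coords = np.unique(coords, axis=0)
        values = rng.normal(1000, 30, len(coords))
        cfg = KrigingConfig(n_lag_bins=8, max_pairs=10**9)
        table = empirical_variogram(coords, values, cfg)
        # oracle: plain python loops
        dists, svs = [], []
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                dists.append(np.hypot(*(coords[i] - coords[j])))
                svs.append(0.5 * (values[i] - values[j]) ** 2)
        dists, svs = np.array(dists), np.array(svs)
        edges = np.linspace(0, dists.max() / 2, cfg.n_lag_bins + 1)
        for lag_c, sv, cnt in table:
            b = np.searchsorted(edges, lag_c) - 1
            sel = (dists >= edges[b]) & (dists < edges[b + 1])
            assert cnt == sel.sum()
            assert sv == pytest.approx(svs[sel].mean(), rel=1e-12)

    def test_linear_ramp_quadratic_semivariance(self):
        """On Z(u) = a*u each pair at lag h contributes a^2 h^2 / 2 exactly;
        a bin's value is the pair-count-weighted mean of that closed form."""
        a = 3.0
        n = 41
        values = a * np.arange(n)
        cfg = KrigingConfig(n_lag_bins=10, max_pairs=10**9)
        table = empirical_variogram(line_coords(n), values, cfg)
        edges = np.linspace(0.0, (n - 1) / 2.0, cfg.n_lag_bins + 1)
        for lag_c, sv, cnt in table:
            b = np.searchsorted(edges, lag_c) - 1
            lags = np.arange(1, n)
            in_bin = (lags >= edges[b]) & (lags < edges[b + 1])
            h = lags[in_bin]
            weights = n - h  # pairs at integer lag h on a line of n points
            expected = (weights * a**2 * h**2 / 2.0).sum() / weights.sum()
            assert cnt == weights.sum()
            assert sv == pytest.approx(expected, rel=1e-12)

    def test_white_noise_flat_semivariance(self):
        """For i.i.d. noise the semivariance is flat at the variance; pairs
        share points, so the spread is judged across replicate fields."""
        s = 5.0
        coords = np.column_stack(np.unravel_index(np.arange(400), (20, 20))).astype(float)
        cfg = KrigingConfig(max_pairs=10**9)
        replicates = []
        for seed in range(15):
            values = np.random.default_rng(100 + seed).normal(0, s, 400)
            replicates.append(empirical_variogram(coords, values, cfg)[:, 1])
        reps = np.asarray(replicates)
        mean = reps.mean(axis=0)
        sem = reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
        assert (np.abs(mean - s**2) < 3 * sem + 1e-9).all()

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            empirical_variogram(np.array([[0.0, 0.0]]), np.array([1.0]))


class TestFitVariogram:
    def test_noiseless_exponential_round_trip(self):
        true = VariogramModel("exponential", nugget=2.0, sill=50.0, range_=6.0)
        lags = np.linspace(0.5, 20, 15)
        table = np.column_stack([lags, true(lags), np.full(15, 100)])
        fit = fit_variogram(table, "exponential")
        assert fit.nugget == pytest.approx(2.0, rel=0.01, abs=0.02)
        assert fit.sill == pytest.approx(50.0, rel=0.01)
        assert fit.range_ == pytest.approx(6.0, rel=0.01)

    def test_constant_field_triggers_fallback(self):
        table = empirical_variogram(line_coords(20), np.full(20, 3.0))
        model = fit_variogram(table)
        assert model.sill > 0 and model.nugget == 0.0

    def test_noisy_sill_within_twenty_percent(self):
        rng = np.random.default_rng(4)
        true = VariogramModel("spherical", nugget=0.0, sill=40.0, range_=8.0)
        lags = np.linspace(0.5, 24, 20)
        noisy = true(lags) * (1 + rng.normal(0, 0.05, 20))
        table = np.column_stack([lags, noisy, np.full(20, 200)])
        fit = fit_variogram(table, "spherical")
        assert fit.sill == pytest.approx(40.0, rel=0.2)


class TestKrigeFill:
    @staticmethod
    def grid_case(seed, n=12, frac_obs=0.6):
        rng = np.random.default_rng(seed)
        vv, uu = np.mgrid[0:n, 0:n]
        depth = 900.0 + 2.0 * uu + 1.5 * vv + 20 * np.sin(uu / 3) * np.cos(vv / 4)
        obs = rng.random((n, n)) < frac_obs
        d = np.where(obs, depth, 0.0)
        region = np.ones((n, n), dtype=bool)
        return d, region, obs, depth

    def test_constant_field_filled_exactly(self):
        region = disc_mask((20, 20), (10, 10), 8)
        obs = region & (np.arange(20)[None, :] % 2 == 0)
        depth = np.where(obs, 850.0, 0.0)
        out = krige_fill(depth, region, obs, KrigingConfig(seed=0))
        assert out[region] == pytest.approx(850.0, abs=1e-6)

    def test_observed_pixels_never_altered(self):
        d, region, obs, _ = self.grid_case(2)
        out = krige_fill(d, region, obs, KrigingConfig(seed=0))
        assert (out[obs] == d[obs]).all()
        assert (out[region] > 0).all()

    @pytest.mark.parametrize("seed", range(20))
    def test_local_path_matches_dense_solver(self, seed):
        """With the neighbourhood covering all observations the local path
        must agree with the whole-system solver to 1e-6 mm."""
        d, region, obs, _ = self.grid_case(seed)
        cfg = KrigingConfig(n_neighbors=200, seed=0)
        a = krige_fill(d, region, obs, cfg)
        b = krige_fill_dense(d, region, obs, cfg)
        assert np.abs(a - b).max() < 1e-6

    def test_planar_field_restored_through_a_hole(self):
        n = 16
        vv, uu = np.mgrid[0:n, 0:n]
        plane = 500.0 + 2.0 * uu + 3.0 * vv
        obs = np.ones((n, n), dtype=bool)
        obs[6:10, 6:10] = False
        d = np.where(obs, plane, 0.0)
        out = krige_fill(d, np.ones((n, n), dtype=bool), obs, KrigingConfig(seed=0))
        assert np.abs(out - plane).max() < 1.0

    def test_weights_sum_to_one(self):
        from citrus3d.kriging import _obs_arrays, _solve_ok_batched

        rng = np.random.default_rng(8)
        coords = rng.uniform(0, 30, (50, 2))
        values = rng.normal(1000, 40, 50)
        model = VariogramModel("exponential", 0.5, 100.0, 5.0)
        idx = np.argsort(rng.random((40, 50)), axis=1)[:, :16]
        targets = rng.uniform(0, 30, (40, 2))
        _, wsum = _solve_ok_batched(coords, values, idx, targets, model)
        assert np.abs(wsum - 1.0).max() < 1e-9

    def test_bounded_noise_keeps_fill_bounded(self):
        rng = np.random.default_rng(5)
        eps = 2.0
        region = disc_mask((24, 24), (12, 12), 10)
        noise = rng.uniform(-eps, eps, (24, 24))
        field = 700.0 + noise
        obs = region & (rng.random((24, 24)) < 0.6)
        d = np.where(obs, field, 0.0)
        out = krige_fill(d, region, obs, KrigingConfig(seed=1))
        lo, hi = d[obs].min(), d[obs].max()
        filled = out[region & ~obs]
        assert filled.min() >= lo - 3 * eps and filled.max() <= hi + 3 * eps

    def test_too_few_observations_named_in_error(self):
        depth = np.zeros((8, 8))
        depth[0, 0] = depth[1, 1] = 500.0
        obs = depth > 0
        with pytest.raises(ValueError, match="2"):
            krige_fill(depth, np.ones((8, 8), dtype=bool), obs, KrigingConfig())


class TestMissingMask:
    def test_right_half_of_square(self):
        region = np.zeros((12, 12), dtype=bool)
        region[1:11, 1:11] = True
        m = make_missing_mask(region, "right_half", 0.5, seed=0)
        assert m.sum() == 50
        assert m[1:11, 6:11].all() and not m[:, :6].any()

    def test_checkerboard_no_adjacent_missing(self):
        region = disc_mask((40, 40), (20, 20), 15)
        m = make_missing_mask(region, "checkerboard", 0.5, seed=0)
        assert not (m[:, 1:] & m[:, :-1]).any()
        assert not (m[1:, :] & m[:-1, :]).any()
        assert abs(m.sum() / region.sum() - 0.5) <= 0.02

    @pytest.mark.parametrize("scheme", ["vertical_band", "horizontal_band", "random"])
    def test_fraction_met_on_disc(self, scheme):
        region = disc_mask((60, 60), (30, 30), 22)
        m = make_missing_mask(region, scheme, 0.5, seed=3)
        assert (m & ~region).sum() == 0
        assert 0.48 <= m.sum() / region.sum() <= 0.52

    def test_vertical_band_straddles_column_centroid(self):
        region = disc_mask((60, 60), (30, 30), 20)
        m = make_missing_mask(region, "vertical_band", 0.5, seed=0)
        cols = np.nonzero(m.any(axis=0))[0]
        assert cols.min() < 30 < cols.max()

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            make_missing_mask(np.ones((4, 4), dtype=bool), "random", 1.0)


class TestRestorationError:
    def test_perfect_restoration(self):
        t = np.full((5, 5), 900.0)
        rep = restoration_error(t, t, np.ones((5, 5), dtype=bool))
        assert rep.mean_abs_error == 0.0 and rep.mean_relative_error == 0.0

    def test_constant_offset(self):
        t = np.full((4, 4), 1000.0)
        rep = restoration_error(t, t + 5.0, np.ones((4, 4), dtype=bool))
        assert rep.mean_abs_error == pytest.approx(5.0)
        assert rep.mean_relative_error == pytest.approx(0.5)

    def test_hand_arithmetic(self):
        t = np.full((1, 3), 100.0)
        r = t + np.array([[1.0, -2.0, 3.0]])
        rep = restoration_error(t, r, np.ones((1, 3), dtype=bool))
        assert rep.mean_abs_error == pytest.approx(2.0)
        assert rep.mean_relative_error == pytest.approx(2.0)
        assert rep.n_evaluated == 3

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            restoration_error(np.ones((3, 3)), np.ones((3, 3)), np.zeros((3, 3), bool))
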