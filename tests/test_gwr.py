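"""Distance covariates and geographically weighted regression."""

import numpy as np
import pytest

from lerisk import (
    LandCoverRaster,
    build_grid,
    coefficient_maps,
    distance_to_class,
    fit_gwr,
)


def _raster_with_water(shape=(30, 30), water_pixels=((10, 12),), cell=100.0):
    vals = np.full(shape, 5, dtype=np.int32)
    for r, c in water_pixels:
        vals[r, c] = 4
    return LandCoverRaster(vals, cell, (0.0, shape[0] * cell))


class TestDistance:
    def test_zero_at_own_pixel(self):
        # water fills one grid cell; 5 pixels per cell edge puts the cell
        # center exactly on a pixel center
        vals = np.full((20, 20), 5, dtype=np.int32)
        vals[:5, :5] = 4
        r = LandCoverRaster(vals, 100.0, (0.0, 2000.0))
        g = build_grid(r, 500.0)
        d = distance_to_class(r, g, "water").set_index("cell_id")["d_water_km"]
        assert d.loc[0] == 0.0
        assert (d >= 0).all()

    def test_single_pixel_analytic(self):
        r = _raster_with_water((30, 30), [(10, 12)])
        g = build_grid(r, 500.0)
        d = distance_to_class(r, g, "water")
        wx, wy = 12.5 * 100, 3000 - 10.5 * 100
        expected = np.hypot(g.cells["x"] - wx, g.cells["y"] - wy) / 1000.0
        np.testing.assert_allclose(d["d_water_km"], expected, atol=1e-9)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        vals = np.where(rng.random((30, 30)) < 0.03, 4, 5).astype(np.int32)
        if not (vals == 4).any():
            vals[0, 0] = 4
        r = LandCoverRaster(vals, 100.0, (0.0, 3000.0))
        g = build_grid(r, 600.0)
        d = distance_to_class(r, g, "water")["d_water_km"].to_numpy()
        xs, ys = r.pixel_centers()
        rr, cc = np.nonzero(r.values == 4)
        wpts = np.column_stack([xs[cc], ys[rr]])
        for i, (cx, cy) in enumerate(zip(g.cells["x"], g.cells["y"])):
            brute = np.min(np.hypot(wpts[:, 0] - cx, wpts[:, 1] - cy)) / 1000.0
            assert d[i] == pytest.approx(brute, abs=1e-12)

    def test_absent_class_error_names_class(self):
        r = _raster_with_water((10, 10), [])
        r.values[:] = 5
        g = build_grid(r, 500.0)
        with pytest.raises(ValueError, match="class absent: water"):
            distance_to_class(r, g, "water")

    def test_distance_is_lipschitz_in_center_position(self):
        # 1-Lipschitz: |d(p) - d(q)| <= |p - q| for any two query points
        r = _raster_with_water((30, 30), [(5, 5), (20, 22)])
        g = build_grid(r, 600.0)
        d = distance_to_class(r, g, "water")["d_water_km"].to_numpy()
        x, y = g.centers()
        dx = np.hypot(x[:, None] - x[None, :], y[:, None] - y[None, :]) / 1000.0
        assert np.all(np.abs(d[:, None] - d[None, :]) <= dx + 1e-12)


class TestGWR:
    def _sim(self, n=100, seed=0):
        rng = np.random.default_rng(seed)
        x, y = rng.uniform(0, 10_000, n), rng.uniform(0, 10_000, n)
        d = rng.uniform(0, 20, n)
        return x, y, d

    def test_zero_noise_global_linear_law_exact(self):
        x, y, d = self._sim(80, 1)
        resp = 2.0 * d  # beta0 = 0, beta = 2 everywhere
        for bw in (500.0, 5_000.0, 1e8):
            fit = fit_gwr(x, y, resp, d[:, None], bandwidth=bw)
            np.testing.assert_allclose(fit.params["beta_x0"], 2.0, atol=1e-6)
            np.testing.assert_allclose(fit.params["beta_intercept"], 0.0, atol=1e-5)

    @pytest.mark.parametrize("seed", range(5))
    def test_infinite_bandwidth_equals_ols(self, seed):
        rng = np.random.default_rng(seed)
        x, y, d = self._sim(60, seed)
        resp = 1.0 + 0.5 * d + rng.normal(0, 0.3, 60)
        fit = fit_gwr(x, y, resp, d[:, None], bandwidth=1e9)
        X = np.column_stack([np.ones(60), d])
        b = np.linalg.lstsq(X, resp, rcond=None)[0]
        np.testing.assert_allclose(fit.params["beta_intercept"], b[0], rtol=1e-6)
        np.testing.assert_allclose(fit.params["beta_x0"], b[1], rtol=1e-6)

    def test_planted_varying_slope_recovered(self):
        rng = np.random.default_rng(2024)
        n = 400
        x = rng.uniform(0, 50_000, n)
        y = rng.uniform(0, 50_000, n)
        d = rng.uniform(0, 10, n)
        beta = 0.002 + 0.008 * (x / 50_000)
        resp = 0.1 + beta * d + rng.normal(0, 0.005, n)
        fit = fit_gwr(x, y, resp, d[:, None], bandwidth="select")
        err = np.abs(fit.params["beta_x0"].to_numpy() - beta)
        assert np.median(err) < 0.002

    def test_gradient_direction_recovered(self):
        rng = np.random.default_rng(7)
        n = 300
        x = rng.uniform(0, 50_000, n)
        y = rng.uniform(0, 50_000, n)
        d = rng.uniform(0, 10, n)
        beta = 0.002 + 0.008 * (x / 50_000)
        resp = beta * d + rng.normal(0, 0.005, n)
        fit = fit_gwr(x, y, resp, d[:, None], bandwidth="select")
        from scipy.stats import spearmanr

        rho, _ = spearmanr(x, fit.params["beta_x0"])
        assert rho > 0.9

    def test_hat_trace_in_range(self):
        x, y, d = self._sim(80, 3)
        rng = np.random.default_rng(3)
        resp = d + rng.normal(0, 0.5, 80)
        fit = fit_gwr(x, y, resp, d[:, None], bandwidth=2_000.0)
        assert 0 < fit.tr_s <= fit.n

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_gwr([0, 1], [0, 1], [1.0, 2.0], np.array([[1.0], [2.0]]))


class TestCoefficientMaps:
    def test_constant_fit_constant_raster(self):
        r = _raster_with_water((20, 20), [(3, 3)])
        g = build_grid(r, 500.0)
        d = distance_to_class(r, g, "water")
        x, y = g.centers()
        resp = 3.0 * d["d_water_km"].to_numpy()
        fit = fit_gwr(x, y, resp, d.drop(columns="cell_id"), bandwidth=1e9)
        maps = coefficient_maps(fit, g)
        np.testing.assert_allclose(maps["water"], 3.0, atol=1e-6)

    def test_raster_values_match_stored_coefficients(self):
        r = _raster_with_water((20, 20), [(3, 3), (15, 12)])
        g = build_grid(r, 500.0)
        d = distance_to_class(r, g, "water")
        x, y = g.centers()
        rng = np.random.default_rng(0)
        resp = d["d_water_km"].to_numpy() + rng.normal(0, 0.1, g.n_cells)
        fit = fit_gwr(x, y, resp, d.drop(columns="cell_id"), bandwidth=3_000.0)
        maps = coefficient_maps(fit, g)
        rows = g.cells["row"].to_numpy()
        cols = g.cells["col"].to_numpy()
        np.testing.assert_allclose(
            maps["water"][rows, cols], fit.params["beta_water"].to_numpy()
        )
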