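import numpy as np
import pandas as pd
import pytest

import auditkrige as ak
from auditkrige.synthetic import (
    SyntheticError,
    assign_raters,
    nearest_neighbor_distances,
)
from auditkrige.variogram import NestedVariogramModel, VariogramStructure


class TestGenerateLocations:
    def test_zero_budget_gives_empty_set(self):
        region = ak.RegionSpec(n_target=0, seed=0)
        pts = ak.generate_locations(region)
        assert len(pts) == 0

    def test_points_inside_extent(self, small_points):
        assert (small_points["x_m"] >= 0).all() and (small_points["x_m"] <= 10_000).all()
        assert (small_points["y_m"] >= 0).all() and (small_points["y_m"] <= 7_000).all()

    def test_minimum_separation_holds_brute_force(self, small_points):
        # all-pairs scan against the hard-core distance the sampler used
        xy = small_points[["x_m", "y_m"]].to_numpy()
        d = small_points.attrs["min_separation_m"]
        diff = xy[:, None, :] - xy[None, :, :]
        dist = np.sqrt((diff**2).sum(-1))
        np.fill_diagonal(dist, np.inf)
        assert dist.min() >= d - 1e-9

    def test_spacing_convergence_band(self, small_points):
        mean_nn = small_points.attrs["mean_nn_m"]
        sd_nn = small_points.attrs["sd_nn_m"]
        assert abs(mean_nn - 150.0) <= sd_nn

    def test_reproducible_under_seed(self):
        region = ak.RegionSpec(extent=(0, 0, 4000, 3000), n_target=200, seed=9)
        a = ak.generate_locations(region)
        b = ak.generate_locations(region)
        pd.testing.assert_frame_equal(a, b)

    def test_invalid_region_rejected(self):
        with pytest.raises(SyntheticError):
            ak.RegionSpec(extent=(0, 0, -10, 5), n_target=10)
        with pytest.raises(SyntheticError):
            ak.RegionSpec(target_spacing=0.0)


class TestLatentField:
    def test_zero_variance_model_gives_zero_field(self, small_points):
        model = NestedVariogramModel(0.0, ())
        f = ak.simulate_latent_field(small_points[["x_m", "y_m"]].to_numpy(),
                                     model, seed=0)
        assert np.all(f == 0)

    def test_pure_nugget_moments_monte_carlo(self):
        # replicate draws at 2 fixed points: variances ~ nugget, covariance ~ 0
        nugget = 0.7
        model = NestedVariogramModel(nugget, ())
        coords = np.array([[0.0, 0.0], [500.0, 0.0]])
        n_rep = 8000
        draws = np.array([ak.simulate_latent_field(coords, model, seed=k)
                          for k in range(n_rep)])
        var = draws.var(axis=0, ddof=1)
        cov = np.cov(draws[:, 0], draws[:, 1])[0, 1]
        se_var = nugget * np.sqrt(2.0 / n_rep)
        se_cov = nugget / np.sqrt(n_rep)
        assert np.all(np.abs(var - nugget) < 3 * se_var)
        assert abs(cov) < 3 * se_cov

    def test_estimator_tracks_generative_model(self, small_points):
        # spherical draw -> empirical semivariogram close to the model curve
        model = NestedVariogramModel(
            0.0, (VariogramStructure("spherical", 1.0, 2.0),))
        xy = small_points[["x_m", "y_m"]].to_numpy()
        f = ak.simulate_latent_field(xy, model, seed=5)
        emp = ak.empirical_semivariogram(xy, f, n_bins=15, max_lag_km=3.0)
        lag, gam, n = emp.nonempty()
        expected = model.semivariance(lag)
        good = n > 500
        rel = np.abs(gam[good] - expected[good]) / np.maximum(expected[good], 0.05)
        assert np.mean(rel) < 0.35

    def test_size_cap_enforced(self):
        model = NestedVariogramModel(1.0, ())
        coords = np.zeros((6000, 2))
        with pytest.raises(SyntheticError, match="cap"):
            ak.simulate_latent_field(coords, model)

    def test_invalid_family_rejected(self, small_points):
        model = NestedVariogramModel(
            0.1, (VariogramStructure("sine_hole", 1.0, 2.0),))
        with pytest.raises(SyntheticError, match="positive definite"):
            ak.simulate_latent_field(small_points[["x_m", "y_m"]].to_numpy(),
                                     model, seed=0)


class TestSimulateResponses:
    @pytest.mark.parametrize("prevalence", [0.5, 0.412])
    def test_empirical_prevalence_matches_intercept(self, small_points, prevalence):
        spec = ak.SimulationSpec(rater_effects=(0.0,) * 4,
                                 prevalence_target=prevalence, seed=11)
        f = np.zeros(len(small_points))
        ds = ak.simulate_responses(small_points, f, spec)
        p_hat = (ds.frame["item_item"] == 1).mean()
        se = np.sqrt(prevalence * (1 - prevalence) / len(small_points))
        assert abs(p_hat - prevalence) < 4 * se

    def test_saturated_intercept_gives_all_no(self, small_points):
        spec = ak.SimulationSpec(trend_coefficients=(-20.0,) + (0.0,) * 7,
                                 rater_effects=(0.0,) * 4, seed=1)
        ds = ak.simulate_responses(small_points, np.zeros(len(small_points)), spec)
        assert (ds.frame["item_item"] == 2).all()

    def test_nan_field_rejected(self, small_points):
        spec = ak.SimulationSpec(seed=0)
        f = np.zeros(len(small_points))
        f[0] = np.nan
        with pytest.raises(SyntheticError, match="NaN"):
            ak.simulate_responses(small_points, f, spec)

    def test_coding_is_survey_1_2(self, small_points):
        spec = ak.SimulationSpec(seed=2)
        f = np.zeros(len(small_points))
        ds = ak.simulate_responses(small_points, f, spec)
        assert set(ds.frame["item_item"].unique()) <= {1, 2}

    def test_rater_assignment_partition(self):
        rng = np.random.default_rng(0)
        labels = assign_raters(1001, 4, rng)
        counts = np.bincount(labels)[1:]
        assert counts.sum() == 1001
        assert counts.max() - counts.min() <= 1

    def test_round_trip_through_audit_io(self, small_points, tmp_path):
        spec = ak.SimulationSpec(seed=3)
        ds = ak.simulate_responses(small_points, np.zeros(len(small_points)), spec)
        path = tmp_path / "sim.csv"
        ak.write_audit_csv(ds, path)
        back = ak.read_audit_csv(path)
        pd.testing.assert_frame_equal(
            back.frame, ds.frame, check_dtype=False)


class TestBlockGroups:
    def test_default_unit_count_gives_6710_prediction_points(self):
        region = ak.RegionSpec(n_target=0, seed=0)
        layer = ak.generate_block_groups(region, n_units=671, seed=4)
        pts = ak.sample_prediction_points(layer, k=10, seed=5)
        assert layer.n_units == 671
        assert len(pts) == 6710

    def test_zero_latent_correlation_independent(self, small_points):
        model = NestedVariogramModel(
            0.0, (VariogramStructure("exponential", 1.0, 2.0),))
        region = ak.RegionSpec(extent=(0, 0, 10_000, 7_000), n_target=0, seed=0)
        f = ak.simulate_latent_field(small_points[["x_m", "y_m"]].to_numpy(),
                                     model, seed=6)
        layer = ak.generate_block_groups(
            region, n_units=671, covariate_spec=(("cov", 0.0, 1.0, 0.0),),
            latent_points=small_points, latent_values=f, seed=7)
        # recompute unit-mean field independently via the polygons
        from shapely.geometry import Point

        unit_mean = []
        for poly in layer.polygons:
            mask = [poly.intersects(Point(x, y))
                    for x, y in small_points[["x_m", "y_m"]].to_numpy()]
            unit_mean.append(f[np.asarray(mask)].mean() if any(mask) else np.nan)
        unit_mean = np.asarray(unit_mean)
        ok = ~np.isnan(unit_mean)
        r = np.corrcoef(unit_mean[ok], layer.table["cov"].to_numpy()[ok])[0, 1]
        assert abs(r) < 0.1

    def test_high_latent_correlation_recovered(self, small_points):
        model = NestedVariogramModel(
            0.0, (VariogramStructure("exponential", 1.0, 2.0),))
        region = ak.RegionSpec(extent=(0, 0, 10_000, 7_000), n_target=0, seed=0)
        f = ak.simulate_latent_field(small_points[["x_m", "y_m"]].to_numpy(),
                                     model, seed=8)
        layer = ak.generate_block_groups(
            region, n_units=200, covariate_spec=(("cov", 10.0, 2.0, 0.9),),
            latent_points=small_points, latent_values=f, seed=9)
        table = layer.table
        # units holding at least one audit point carry the signal
        from shapely.geometry import Point

        unit_mean = []
        for poly in layer.polygons:
            mask = [poly.intersects(Point(x, y))
                    for x, y in small_points[["x_m", "y_m"]].to_numpy()]
            unit_mean.append(f[np.asarray(mask)].mean() if any(mask) else np.nan)
        unit_mean = np.asarray(unit_mean)
        ok = ~np.isnan(unit_mean)
        r = np.corrcoef(unit_mean[ok], table["cov"].to_numpy()[ok])[0, 1]
        assert abs(r - 0.9) < 0.12

    def test_units_tile_extent_without_overlap(self):
        region = ak.RegionSpec(extent=(0, 0, 5000, 3000), n_target=0, seed=0)
        layer = ak.generate_block_groups(region, n_units=37, seed=0)
        total = sum(p.area for p in layer.polygons)
        assert total == pytest.approx(5000 * 3000, rel=1e-9)
        for i in range(len(layer.polygons)):
            for j in range(i + 1, len(layer.polygons)):
                inter = layer.polygons[i].intersection(layer.polygons[j]).area
                assert inter == pytest.approx(0.0, abs=1e-6)
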