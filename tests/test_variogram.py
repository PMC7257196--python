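import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import auditkrige as ak
from auditkrige.variogram import (
    MONOTONE_FAMILIES,
    NestedVariogramModel,
    VariogramError,
    VariogramStructure,
    directional_semivariograms,
    model_from_fixture_row,
    weighted_sse,
)


def brute_force_semivariogram(coords_m, values, edges_km):
    """O(n^2) loop re-implementation of the binned Matheron estimator."""
    n = len(coords_m)
    sums = np.zeros(len(edges_km) - 1)
    counts = np.zeros(len(edges_km) - 1, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            h = np.hypot(*(coords_m[i] - coords_m[j])) / 1000.0
            last = len(edges_km) - 2
            for b in range(len(edges_km) - 1):
                lo, hi = edges_km[b], edges_km[b + 1]
                if h >= lo and (h < hi or (b == last and h <= hi)):
                    sums[b] += (values[i] - values[j]) ** 2
                    counts[b] += 1
                    break
    with np.errstate(invalid="ignore", divide="ignore"):
        return sums / (2 * counts), counts


class TestEmpiricalEstimator:
    def test_two_point_hand_value(self):
        coords = np.array([[0.0, 0.0], [1000.0, 0.0]])
        emp = ak.empirical_semivariogram(coords, np.array([0.0, 2.0]),
                                         n_bins=1, max_lag_km=1.5)
        lag, gam, n = emp.nonempty()
        assert n[0] == 1
        assert gam[0] == pytest.approx(2.0)  # (1/2) * (2)^2

    def test_constant_field_is_zero(self, small_points):
        xy = small_points[["x_m", "y_m"]].to_numpy()
        emp = ak.empirical_semivariogram(xy, np.full(len(xy), 3.7), n_bins=10)
        _, gam, _ = emp.nonempty()
        np.testing.assert_allclose(gam, 0.0, atol=1e-20)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        coords = rng.uniform(0, 3000, size=(60, 2))
        values = rng.normal(size=60)
        emp = ak.empirical_semivariogram(coords, values, n_bins=6, max_lag_km=3.0)
        edges = np.linspace(0, 3.0, 7)
        gam_bf, n_bf = brute_force_semivariogram(coords, values, edges)
        np.testing.assert_array_equal(emp.n_pairs, n_bf)
        ok = n_bf > 0
        np.testing.assert_allclose(emp.gamma[ok], gam_bf[ok], rtol=1e-10)

    def test_iid_field_is_flat_at_unit_variance(self, small_points):
        rng = np.random.default_rng(22)
        xy = small_points[["x_m", "y_m"]].to_numpy()
        values = rng.standard_normal(len(xy))
        emp = ak.empirical_semivariogram(xy, values, n_bins=12)
        lag, gam, n = emp.nonempty()
        # 3-SE band per bin; gamma-hat variance roughly 2*gamma^2 / N(h)
        se = np.sqrt(2.0 / n)
        good = n > 200
        assert np.all(np.abs(gam[good] - 1.0) < 3 * se[good] + 0.05)

    def test_order_reversal_symmetry(self):
        rng = np.random.default_rng(23)
        coords = rng.uniform(0, 2000, size=(40, 2))
        values = rng.normal(size=40)
        a = ak.empirical_semivariogram(coords, values, n_bins=5, max_lag_km=2.0)
        b = ak.empirical_semivariogram(coords[::-1], values[::-1], n_bins=5,
                                       max_lag_km=2.0)
        np.testing.assert_allclose(a.gamma, b.gamma, equal_nan=True)

    def test_empty_bins_retained_not_fitted(self):
        coords = np.array([[0.0, 0.0], [100.0, 0.0], [5000.0, 0.0]])
        values = np.array([0.0, 1.0, 2.0])
        emp = ak.empirical_semivariogram(coords, values, n_bins=10, max_lag_km=5.0)
        assert (emp.n_pairs == 0).any()
        assert np.isnan(emp.gamma[emp.n_pairs == 0]).all()

    def test_directional_partition_is_exhaustive(self):
        rng = np.random.default_rng(24)
        coords = rng.uniform(0, 3000, size=(80, 2))
        values = rng.normal(size=80)
        omni = ak.empirical_semivariogram(coords, values, n_bins=5, max_lag_km=2.0)
        dirs = directional_semivariograms(coords, values, n_bins=5, max_lag_km=2.0)
        assert sorted(dirs) == [0.0, 22.5, 45.0, 67.5, 90.0, 112.5, 135.0, 157.5]
        total = sum(d.n_pairs.sum() for d in dirs.values())
        assert total == omni.n_pairs.sum()


class TestModelSemivariance:
    def test_spherical_reaches_sill_exactly_at_range(self):
        m = NestedVariogramModel(0.2, (VariogramStructure("spherical", 1.0, 2.0),))
        assert m.semivariance(2.0) == pytest.approx(1.2)
        assert m.semivariance(5.0) == pytest.approx(1.2)

    @pytest.mark.parametrize("family", ["spherical", "exponential", "gaussian",
                                        "matern", "cubic", "sine_hole"])
    def test_zero_at_origin_nugget_just_above(self, family):
        m = NestedVariogramModel(0.3, (VariogramStructure(family, 1.0, 2.0),))
        assert m.semivariance(0.0) == 0.0
        assert m.semivariance(1e-9) == pytest.approx(0.3, abs=1e-6)

    def test_garbage_nested_sill_worked_example(self, fixture_tables):
        t2 = fixture_tables[2]
        row = t2[(t2["item"] == "Garbage")
                 & (t2["detrending"] == "3rd order spatial")].iloc[0]
        model = model_from_fixture_row(row)
        assert model.total_sill == pytest.approx(1.128, abs=1e-9)

    def test_negative_lag_rejected(self):
        m = NestedVariogramModel(0.0, (VariogramStructure("spherical", 1.0, 1.0),))
        with pytest.raises(VariogramError):
            m.semivariance(-0.1)

    @pytest.mark.parametrize("family", MONOTONE_FAMILIES)
    def test_monotone_families_nondecreasing(self, family):
        kwargs = {"partial_sill": 1.3, "range_km": 1.7}
        if family == "power":
            kwargs = {"partial_sill": 0.5, "range_km": 1.4}  # b, p
        m = NestedVariogramModel(0.1, (VariogramStructure(family, **kwargs),))
        h = np.linspace(0, 10, 2000)
        g = m.semivariance(h)
        assert np.all(np.diff(g) >= -1e-12)

    def test_sine_hole_form(self):
        c, a = 0.8, 2.0
        s = VariogramStructure("sine_hole", c, a)
        h = np.array([0.5, 1.0, 3.0])
        expected = c * (1 - np.sin(np.pi * h / a) / (np.pi * h / a))
        np.testing.assert_allclose(s.semivariance(h), expected)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        family=st.sampled_from(["spherical", "exponential", "gaussian",
                                "matern", "cubic", "sine_hole"]),
        nugget=st.floats(0.0, 2.0),
        sill=st.floats(0.0, 5.0),
        rng_km=st.floats(0.05, 20.0),
        h=st.floats(0.0, 50.0),
    )
    def test_semivariance_bounded_by_definitional_limits(self, family, nugget,
                                                         sill, rng_km, h):
        """gamma(0) = 0 and 0 <= gamma(h) <= nugget + 2*sill everywhere
        (the sine-hole overshoot never exceeds twice its partial sill)."""
        m = NestedVariogramModel(
            nugget, (VariogramStructure(family, sill, rng_km),))
        assert m.semivariance(0.0) == 0.0
        g = float(m.semivariance(h))
        assert 0.0 <= g <= nugget + 2.0 * sill + 1e-9

    def test_power_form_and_bounds(self):
        s = VariogramStructure("power", 0.4, 1.5)
        assert s.semivariance(2.0) == pytest.approx(0.4 * 2.0**1.5)
        with pytest.raises(VariogramError):
            VariogramStructure("power", 0.4, 2.5)


class TestNestedWLS:
    def exact_bins(self, model, n_bins=20, max_lag=6.0):
        lag = np.linspace(max_lag / n_bins, max_lag, n_bins) - max_lag / (2 * n_bins)
        return ak.EmpiricalVariogram(lag, model.semivariance(lag),
                                     np.full(n_bins, 500), max_lag)

    def test_noise_free_self_consistency(self):
        truth = NestedVariogramModel(0.2, (VariogramStructure("spherical", 1.0, 2.0),))
        emp = self.exact_bins(truth)
        fit = ak.fit_nested_wls(emp, candidates=[("spherical",)], n_starts=6, seed=0)
        assert fit.nugget == pytest.approx(0.2, abs=1e-3)
        assert fit.structures[0].partial_sill == pytest.approx(1.0, abs=1e-3)
        assert fit.structures[0].range_km == pytest.approx(2.0, abs=1e-3)
        assert fit.weighted_sse < 1e-6

    def test_grf_parameter_recovery_single_seed(self):
        truth = NestedVariogramModel(0.3, (VariogramStructure("exponential", 1.0, 1.5),))
        region = ak.RegionSpec(extent=(0, 0, 16_000, 10_000), n_target=2000,
                               target_spacing=150, seed=1)
        pts = ak.generate_locations(region)
        xy = pts[["x_m", "y_m"]].to_numpy()
        f = ak.simulate_latent_field(xy, truth, seed=501)
        emp = ak.empirical_semivariogram(xy, f, n_bins=25, max_lag_km=5.0)
        fit = ak.fit_nested_wls(emp, candidates=[("exponential",)], n_starts=4, seed=1)
        s = fit.structures[0]
        assert fit.total_sill == pytest.approx(truth.total_sill, rel=0.35)
        assert s.range_km == pytest.approx(1.5, rel=0.6)

    def test_nested_truth_beats_single_families(self):
        truth = NestedVariogramModel(
            0.1,
            (VariogramStructure("matern", 0.6, 0.3, smoothness=0.5),
             VariogramStructure("spherical", 0.8, 4.0)),
        )
        emp = self.exact_bins(truth, n_bins=25, max_lag=8.0)
        best, ledger = ak.fit_nested_wls(
            emp,
            candidates=[("spherical",), ("exponential",), ("gaussian",),
                        ("matern",), ("matern", "spherical")],
            n_starts=6, seed=2, return_ledger=True)
        assert len(best.structures) == 2
        singles = [m for m in ledger if len(m.structures) == 1]
        assert best.weighted_sse < min(m.weighted_sse for m in singles)

    def test_reported_sse_matches_independent_recomputation(self):
        truth = NestedVariogramModel(0.25, (VariogramStructure("gaussian", 0.9, 1.8),))
        emp = self.exact_bins(truth)
        # perturb to make the fit imperfect
        emp.gamma = emp.gamma + 0.01 * np.sin(np.arange(len(emp.gamma)))
        fit = ak.fit_nested_wls(emp, candidates=[("gaussian",)], n_starts=4, seed=3)
        lag, gam, n = emp.nonempty()
        mod = np.maximum(fit.semivariance(lag), 1e-12)
        sse = float(np.sum(n * (gam - mod) ** 2 / mod**2))
        assert fit.weighted_sse == pytest.approx(sse, abs=1e-9)
        assert fit.weighted_sse == pytest.approx(weighted_sse(emp, fit), abs=1e-12)

    def test_too_few_bins_rejected(self):
        emp = ak.EmpiricalVariogram(np.array([0.5, 1.0]), np.array([1.0, 1.1]),
                                    np.array([10, 10]), 1.0)
        with pytest.raises(VariogramError, match="5"):
            ak.fit_nested_wls(emp)


class TestAnisotropy:
    def test_identical_models_classified_none(self):
        m = NestedVariogramModel(0.2, (VariogramStructure("exponential", 1.0, 2.0),))
        dirs = {a: m for a in (0, 22.5, 45, 67.5, 90, 112.5, 135, 157.5)}
        assert ak.classify_anisotropy(dirs, m) == "None"

    def test_isotropic_field_classified_none(self):
        truth = NestedVariogramModel(0.05, (VariogramStructure("exponential", 1.0, 1.5),))
        region = ak.RegionSpec(extent=(0, 0, 14_000, 9_000), n_target=1500,
                               target_spacing=150, seed=31)
        pts = ak.generate_locations(region)
        xy = pts[["x_m", "y_m"]].to_numpy()
        f = ak.simulate_latent_field(xy, truth, seed=32)
        omni = ak.fit_nested_wls(
            ak.empirical_semivariogram(xy, f, n_bins=20, max_lag_km=5.0),
            candidates=[("exponential",)], n_starts=4, seed=33)
        dirs = directional_semivariograms(xy, f, n_bins=20, max_lag_km=5.0)
        fits = {a: ak.fit_nested_wls(d, candidates=[("exponential",)],
                                     n_starts=4, seed=33)
                for a, d in dirs.items()}
        assert ak.classify_anisotropy(fits, omni, rel_tol=0.5) == "None"

    def test_strong_geometric_anisotropy_detected(self):
        # 3:1 range ratio injected by stretching y before simulating
        truth = NestedVariogramModel(0.02, (VariogramStructure("exponential", 1.0, 1.5),))
        region = ak.RegionSpec(extent=(0, 0, 14_000, 9_000), n_target=1500,
                               target_spacing=150, seed=34)
        pts = ak.generate_locations(region)
        xy = pts[["x_m", "y_m"]].to_numpy()
        stretched = xy.copy()
        stretched[:, 1] *= 3.0
        f = ak.simulate_latent_field(stretched, truth, seed=35)
        omni = ak.fit_nested_wls(
            ak.empirical_semivariogram(xy, f, n_bins=20, max_lag_km=5.0),
            candidates=[("exponential",)], n_starts=4, seed=36)
        dirs = directional_semivariograms(xy, f, n_bins=20, max_lag_km=5.0)
        fits = {a: ak.fit_nested_wls(d, candidates=[("exponential",)],
                                     n_starts=4, seed=36)
                for a, d in dirs.items()}
        label = ak.classify_anisotropy(fits, omni, rel_tol=0.2)
        assert label.startswith("Yes")

    def test_too_few_directions_is_na(self):
        m = NestedVariogramModel(0.2, (VariogramStructure("exponential", 1.0, 2.0),))
        assert ak.classify_anisotropy({0: m, 45: m}, m) == "NA"
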