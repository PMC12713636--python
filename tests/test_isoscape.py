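"""Species standardization, grid extraction/regridding, and the
tree-ensemble isoscape estimator."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr
from sklearn.base import clone

from trisoscape import (
    ClimateGrid,
    DataError,
    DomainError,
    IsoscapeRegressor,
    SiteRecord,
    build_feature_table,
    extract_at_sites,
    fit_isoscape,
    predict_isoscape,
    regrid_to,
    standardize_species,
)
from trisoscape.isoscape import climate_class


def _field(values, lat, lon):
    return xr.DataArray(
        np.asarray(values, float), dims=("lat", "lon"), coords={"lat": lat, "lon": lon}
    )


class TestStandardizeSpecies:
    def test_broadleaf_record_shifts_by_the_offset(self):
        s = SiteRecord("a", 100.0, 30.0, 1200.0, "broadleaf", 25.0)
        out = standardize_species(s)
        assert out.d18o_tr_std == pytest.approx(26.9)
        assert out.standardized

    def test_conifer_record_unchanged(self):
        s = SiteRecord("b", 100.0, 30.0, 1200.0, "conifer", 25.0)
        assert standardize_species(s).d18o_tr_std == 25.0

    def test_double_application_raises(self):
        s = standardize_species(SiteRecord("c", 100.0, 30.0, 0.0, "conifer", 25.0))
        with pytest.raises(DomainError):
            standardize_species(s)

    def test_dataframe_form_shifts_only_broadleaf(self):
        df = pd.DataFrame(
            {
                "species_class": ["conifer", "broadleaf", "Broadleaf"],
                "d18o_tr_permil": [25.0, 25.0, 30.0],
            }
        )
        out = standardize_species(df)
        assert list(out["d18o_tr_std"]) == [25.0, 26.9, 31.9]
        with pytest.raises(DomainError):
            standardize_species(out)

    def test_site_record_validation(self):
        with pytest.raises(DomainError):
            SiteRecord("x", 100.0, 95.0, 0.0, "conifer", 25.0)  # latitude
        with pytest.raises(DomainError):
            SiteRecord("x", 100.0, 30.0, 0.0, "shrub", 25.0)  # species
        with pytest.raises(DomainError):
            SiteRecord("x", 100.0, 30.0, 0.0, "conifer", 50.0)  # sanity window


class TestExtractAtSites:
    lat = np.array([10.0, 11.0, 12.0])
    lon = np.array([100.0, 101.0])

    def test_cell_center_returns_cell_value_for_both_methods(self):
        f = _field([[1, 2], [3, 4], [5, 6]], self.lat, self.lon)
        sites = pd.DataFrame({"lon": [101.0], "lat": [11.0]})
        assert extract_at_sites(f, sites, "nearest")[0] == 4.0
        assert extract_at_sites(f, sites, "bilinear")[0] == 4.0

    def test_bilinear_midpoint_averages_neighbours(self):
        f = _field([[4, 4], [8, 8], [0, 0]], self.lat, self.lon)
        sites = pd.DataFrame({"lon": [100.5], "lat": [10.5]})
        assert extract_at_sites(f, sites, "bilinear")[0] == pytest.approx(6.0)

    def test_constant_grid_extracts_the_constant(self):
        f = _field(np.full((3, 2), 7.5), self.lat, self.lon)
        sites = pd.DataFrame({"lon": [100.2, 100.9], "lat": [10.1, 11.7]})
        for method in ("nearest", "bilinear"):
            assert np.allclose(extract_at_sites(f, sites, method), 7.5)

    def test_sites_outside_grid_are_missing(self):
        f = _field([[1, 2], [3, 4], [5, 6]], self.lat, self.lon)
        sites = pd.DataFrame({"lon": [101.0, 140.0], "lat": [11.0, 50.0]})
        out = extract_at_sites(f, sites, "nearest")
        assert out[0] == 4.0 and np.isnan(out[1])

    def test_all_sites_outside_raises(self):
        f = _field([[1, 2], [3, 4], [5, 6]], self.lat, self.lon)
        sites = pd.DataFrame({"lon": [150.0], "lat": [80.0]})
        with pytest.raises(DataError):
            extract_at_sites(f, sites, "nearest")


class TestRegrid:
    def _grid(self, values):
        return ClimateGrid.from_arrays(
            np.arange(10.0, 20.0), np.arange(100.0, 110.0), f=(values, "u")
        )

    def test_constant_field_preserved_exactly(self):
        g = self._grid(np.full((10, 10), 3.25))
        out = regrid_to(g, np.arange(10.25, 19.0, 0.5), np.arange(100.25, 109.0, 0.5))
        assert np.allclose(out.var("f").values, 3.25)

    def test_linear_in_latitude_field_is_bilinear_exact(self):
        lat = np.arange(10.0, 20.0)
        vals = np.tile(2.0 * lat[:, None], (1, 10))
        out = regrid_to(self._grid(vals), np.arange(10.5, 18.6, 0.5), np.arange(100.5, 108.6))
        expect = 2.0 * out.lat[:, None]
        assert np.allclose(out.var("f").values, np.broadcast_to(expect, out.var("f").shape))

    def test_identity_lattice_returns_identical_values(self):
        g = self._grid(np.random.default_rng(0).normal(size=(10, 10)))
        out = regrid_to(g, g.lat, g.lon)
        assert np.allclose(out.var("f").values, g.var("f").values)

    def test_disjoint_domains_raise(self):
        g = self._grid(np.zeros((10, 10)))
        with pytest.raises(DomainError):
            regrid_to(g, np.arange(50.0, 60.0), np.arange(0.0, 10.0))


class TestIsoscapeRegressor:
    def _xy(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(
            {"a": rng.normal(size=n), "b": rng.normal(size=n), "c": rng.normal(size=n)}
        )
        y = 3 * X["a"] - X["b"] + 0.1 * rng.normal(size=n)
        return X, y.to_numpy()

    @pytest.mark.parametrize("learner", ["xgboost", "random_forest"])
    def test_constant_target_predicts_the_constant(self, learner):
        X, _ = self._xy()
        y = np.full(len(X), 21.5)
        est = IsoscapeRegressor(learner=learner, n_estimators=50, cv=5).fit(X, y)
        assert np.allclose(est.predict(X), 21.5, atol=1e-6)
        assert est.cv_rmse_ < 1e-6

    def test_permuted_targets_give_near_zero_cv_skill(self):
        X, y = self._xy()
        y_perm = np.random.default_rng(1).permutation(y)
        est = IsoscapeRegressor(n_estimators=100, cv=5).fit(X, y_perm)
        assert est.cv_r2_ < 0.1

    def test_cv_metrics_are_held_out_even_when_the_model_memorizes(self):
        # pure-noise target: in-sample fit is strong, honest out-of-fold skill is none
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(150, 3)), columns=list("abc"))
        y = rng.normal(size=150)
        est = IsoscapeRegressor(n_estimators=300, cv=5).fit(X, y)
        train_r2 = 1 - np.sum((est.predict(X) - y) ** 2) / np.sum((y - y.mean()) ** 2)
        assert train_r2 > 0.8  # memorization happened
        assert est.cv_r2_ < 0.1  # but never leaked into the CV metric

    def test_same_seed_is_deterministic(self):
        X, y = self._xy()
        p1 = IsoscapeRegressor(cv=None, random_state=5).fit(X, y).predict(X)
        p2 = IsoscapeRegressor(cv=None, random_state=5).fit(X, y).predict(X)
        assert np.array_equal(p1, p2)

    def test_missing_predictor_columns_error_names_them(self):
        X, y = self._xy()
        est = IsoscapeRegressor(n_estimators=20, cv=None).fit(X, y)
        with pytest.raises(DataError, match=r"\['b'\]"):
            est.predict(X.drop(columns=["b"]))

    def test_sklearn_clone_compatible(self):
        est = IsoscapeRegressor(learner="random_forest", n_estimators=10)
        c = clone(est)
        assert c.get_params() == est.get_params()

    def test_unknown_learner_raises(self):
        X, y = self._xy(n=30)
        with pytest.raises(DomainError):
            IsoscapeRegressor(learner="svm", cv=None).fit(X, y)


class TestClimateClass:
    def test_threshold_partition(self):
        t = np.array([25.0, 25.0, 5.0, 15.0])
        rh = np.array([40.0, 70.0, 70.0, 70.0])
        assert list(climate_class(t, rh)) == ["arid", "tropical", "boreal", "temperate"]


class TestIsoscapeEndToEnd:
    def test_fit_requires_minimum_sites(self, default_grid):
        sites = pd.DataFrame(
            {
                "lon": [100.0] * 5,
                "lat": [30.0] * 5,
                "elevation_m": [0.0] * 5,
                "d18o_tr_std": [25.0] * 5,
            }
        )
        feats = pd.DataFrame({"lon": [100.0] * 5})
        with pytest.raises(DomainError):
            fit_isoscape(sites, feats)

    def test_predict_requires_fitted_model(self, default_grid):
        from trisoscape.isoscape import Isoscape

        blank = Isoscape("xgboost", IsoscapeRegressor(), [], None, np.nan, np.nan, 0, 0)
        with pytest.raises(DomainError):
            predict_isoscape(blank, default_grid)

    def test_raster_matches_fitted_values_at_training_cells(self, default_sites, default_grid):
        feats = build_feature_table(default_sites, default_grid)
        iso = fit_isoscape(default_sites, feats, cv=None, seed=0)
        iso = predict_isoscape(iso, default_grid)
        at_sites = extract_at_sites(iso.raster, default_sites, "nearest")
        fitted = iso.model.predict(feats)
        # nearest-cell raster lookup reproduces the model at snapped coordinates
        assert np.corrcoef(at_sites, fitted)[0, 1] > 0.99

    def test_same_seed_gives_identical_raster(self, default_sites, default_grid):
        feats = build_feature_table(default_sites, default_grid)
        r1 = predict_isoscape(fit_isoscape(default_sites, feats, cv=None, seed=3), default_grid).raster
        r2 = predict_isoscape(fit_isoscape(default_sites, feats, cv=None, seed=3), default_grid).raster
        assert r1.identical(r2)

    def test_predictions_track_the_generating_field(self, default_cfg, default_sites, default_grid):
        feats = build_feature_table(default_sites, default_grid)
        iso = fit_isoscape(default_sites, feats, cv=None, seed=0)
        pred = iso.model.predict(feats)
        r = np.corrcoef(pred, default_sites["d18o_tr_true"])[0, 1]
        assert r > 0.7
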