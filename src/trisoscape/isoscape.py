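"""Tree-ring delta18O isoscape construction.

Species standardization, grid-to-site extraction, regridding, and spatial
prediction of cellulose delta18O on a regular 0.5-degree lattice with tree
ensembles (gradient-boosted trees or random forest), scikit-learn style:
:class:`IsoscapeRegressor` is a ``BaseEstimator``/``RegressorMixin`` that
composes with pipelines and model selection; :func:`fit_isoscape` and
:func:`predict_isoscape` are thin wrappers returning the :class:`Isoscape`
bundle (fitted model + prediction raster + cross-validation metrics).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted
from xgboost import XGBRegressor

from .errors import DataError, DomainError
from .grids import ClimateGrid

__all__ = [
    "SiteRecord",
    "standardize_species",
    "extract_at_sites",
    "regrid_to",
    "climate_class",
    "build_feature_table",
    "IsoscapeRegressor",
    "Isoscape",
    "fit_isoscape",
    "predict_isoscape",
]

#: Offset (permil) added to broadleaf records to standardize against conifers.
BROADLEAF_OFFSET = 1.9

#: Sanity window for raw cellulose delta18O (permil VSMOW).
D18O_TR_WINDOW = (10.0, 45.0)

SPECIES_CLASSES = ("conifer", "broadleaf")

#: Fixed category order of the coarse climate classification (one-hot).
CLIMATE_CLASSES = ("arid", "boreal", "temperate", "tropical")


@dataclass
class SiteRecord:
    """One tree-ring sampling site."""

    id: str
    lon: float
    lat: float
    elevation: float
    species_class: str
    d18o_tr_raw: float
    d18o_tr_std: float | None = None
    region: str | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        if not -180 <= self.lon <= 180:
            raise DomainError(f"site {self.id}: lon {self.lon} outside [-180, 180]")
        if not -90 <= self.lat <= 90:
            raise DomainError(f"site {self.id}: lat {self.lat} outside [-90, 90]")
        sp = str(self.species_class).strip().lower()
        if sp not in SPECIES_CLASSES:
            raise DomainError(f"site {self.id}: unknown species class '{self.species_class}'")
        self.species_class = sp
        lo, hi = D18O_TR_WINDOW
        if not lo <= self.d18o_tr_raw <= hi:
            raise DomainError(
                f"site {self.id}: d18O_TR {self.d18o_tr_raw} outside sanity window [{lo}, {hi}]"
            )


def standardize_species(site, offset: float = BROADLEAF_OFFSET):
    """Standardize species differences: broadleaf values shift by ``offset``
    (default +1.9 permil), conifer values are unchanged.

    Accepts a single :class:`SiteRecord` or a site DataFrame (columns
    ``species_class`` and ``d18o_tr_permil``; adds ``d18o_tr_std``).
    Re-application is an error: the operation is tracked by a flag.
    """
    if isinstance(site, pd.DataFrame):
        if "d18o_tr_std" in site.columns:
            raise DomainError("sites already standardized (d18o_tr_std present)")
        out = site.copy()
        is_bl = out["species_class"].str.strip().str.lower() == "broadleaf"
        out["d18o_tr_std"] = out["d18o_tr_permil"] + offset * is_bl
        return out
    if site.standardized:
        raise DomainError(f"site {site.id} already standardized")
    std = site.d18o_tr_raw + (offset if site.species_class == "broadleaf" else 0.0)
    return replace(site, d18o_tr_std=std, standardized=True)


def extract_at_sites(
    field: xr.DataArray, sites: pd.DataFrame, method: str = "nearest"
) -> np.ndarray:
    """Sample a 2-D lat/lon field at site locations.

    ``method`` is ``nearest`` (default: nearest cell center) or ``bilinear``.
    Sites outside the grid yield NaN; if every site is outside, that is an
    error. ``sites`` needs ``lon`` and ``lat`` columns.
    """
    if method not in ("nearest", "bilinear"):
        raise DomainError(f"unknown extraction method '{method}'")
    lon = np.asarray(sites["lon"], float)
    lat = np.asarray(sites["lat"], float)
    glat, glon = field["lat"].values, field["lon"].values
    dlat, dlon = glat[1] - glat[0], glon[1] - glon[0]

    if method == "nearest":
        inside = (
            (lat >= glat[0] - dlat / 2) & (lat <= glat[-1] + dlat / 2)
            & (lon >= glon[0] - dlon / 2) & (lon <= glon[-1] + dlon / 2)
        )
        out = np.full(lat.shape, np.nan)
        if inside.any():
            sel = field.sel(
                lat=xr.DataArray(lat[inside], dims="site"),
                lon=xr.DataArray(lon[inside], dims="site"),
                method="nearest",
            )
            out[inside] = sel.values
    else:
        out = field.interp(
            lat=xr.DataArray(lat, dims="site"), lon=xr.DataArray(lon, dims="site")
        ).values
    if np.all(np.isnan(out)):
        raise DataError("all sites fall outside the grid")
    return out


def regrid_to(grid: ClimateGrid, target_lat, target_lon) -> ClimateGrid:
    """Bilinear resampling of every field onto a target lattice.

    Constant and lat/lon-linear fields are preserved exactly (bilinear
    exactness). Target cells outside the source domain become NaN; fully
    disjoint domains are an error.
    """
    target_lat = np.asarray(target_lat, float)
    target_lon = np.asarray(target_lon, float)
    if (
        target_lat.max() < grid.lat.min() or target_lat.min() > grid.lat.max()
        or target_lon.max() < grid.lon.min() or target_lon.min() > grid.lon.max()
    ):
        raise DomainError("target lattice is disjoint from the source grid")
    ds = grid.ds.interp(lat=target_lat, lon=target_lon, method="linear")
    for v in ds.data_vars:  # interp drops attrs on some xarray versions
        ds[v].attrs.setdefault("units", grid.ds[v].attrs.get("units", ""))
    return ClimateGrid(ds)


def climate_class(tmean, rh) -> np.ndarray:
    """Coarse climate classification from growing-season temperature (degC)
    and relative humidity (%): arid (RH < 50), else tropical (T > 22),
    boreal (T < 8), temperate otherwise.
    """
    tmean = np.asarray(tmean, float)
    rh = np.asarray(rh, float)
    out = np.where(rh < 50.0, "arid", np.where(tmean > 22.0, "tropical",
                   np.where(tmean < 8.0, "boreal", "temperate")))
    return out


def _one_hot_climate(labels) -> pd.DataFrame:
    cat = pd.Categorical(labels, categories=list(CLIMATE_CLASSES))
    return pd.get_dummies(cat, prefix="climate", dtype=float)


def build_feature_table(
    sites: pd.DataFrame, grid: ClimateGrid, method: str = "nearest",
    extra_fields: dict | None = None,
) -> pd.DataFrame:
    """Predictor table for isoscape fitting: longitude, latitude, elevation,
    May-September mean temperature and RH extracted at the sites, a one-hot
    coarse climate class, plus any named extra 2-D fields."""
    tmean = extract_at_sites(grid.seasonal_mean("tmean"), sites, method)
    rh = extract_at_sites(grid.seasonal_mean("rh"), sites, method)
    feats = pd.DataFrame(
        {
            "lon": np.asarray(sites["lon"], float),
            "lat": np.asarray(sites["lat"], float),
            "elevation_m": np.asarray(sites["elevation_m"], float),
            "tmean_ms": tmean,
            "rh_ms": rh,
        }
    )
    feats = pd.concat([feats, _one_hot_climate(climate_class(tmean, rh))], axis=1)
    if extra_fields:
        for name, fld in extra_fields.items():
            feats[name] = extract_at_sites(fld, sites, method)
    return feats


class IsoscapeRegressor(RegressorMixin, BaseEstimator):
    """Tree-ensemble spatial regressor for isoscape construction.

    Parameters
    ----------
    learner : {"xgboost", "random_forest"}
        Ensemble family. Both are first-class; defaults pin 500 trees and,
        for boosting, a 0.05 learning rate, for determinism and
        documentation rather than for any tuned optimum.
    n_estimators, learning_rate, max_depth :
        Ensemble hyperparameters (``learning_rate``/``max_depth`` apply to
        boosting only; the forest uses unlimited depth).
    cv : int or None
        Number of seeded K-folds for held-out metrics computed during
        ``fit`` (default 10); ``None`` skips cross-validation.
    random_state : int
        Seed for the ensemble and the fold assignment.

    Attributes
    ----------
    model_ : fitted underlying ensemble
    cv_rmse_, cv_r2_ : float
        Pooled out-of-fold RMSE (permil) and R-squared (NaN if ``cv=None``).
    feature_names_in_, n_features_in_ : fitted input schema.
    """

    def __init__(
        self,
        learner: str = "xgboost",
        n_estimators: int = 500,
        learning_rate: float = 0.05,
        max_depth: int = 4,
        cv: int | None = 10,
        random_state: int = 0,
    ):
        self.learner = learner
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.max_depth = max_depth
        self.cv = cv
        self.random_state = random_state

    def _make_model(self):
        if self.learner == "xgboost":
            return XGBRegressor(
                n_estimators=self.n_estimators,
                learning_rate=self.learning_rate,
                max_depth=self.max_depth,
                tree_method="hist",
                n_jobs=1,
                random_state=self.random_state,
                verbosity=0,
            )
        if self.learner == "random_forest":
            return RandomForestRegressor(
                n_estimators=self.n_estimators,
                n_jobs=1,
                random_state=self.random_state,
            )
        raise DomainError(f"unknown learner '{self.learner}'")

    def _coerce(self, X, fitting: bool):
        if isinstance(X, pd.DataFrame):
            if fitting:
                self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            else:
                missing = [c for c in getattr(self, "feature_names_in_", []) if c not in X.columns]
                if missing:
                    raise DataError(f"missing predictor column(s): {missing}")
                X = X[list(self.feature_names_in_)]
            X = X.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            if not fitting and hasattr(self, "feature_names_in_") and X.shape[1] != len(self.feature_names_in_):
                raise DataError("feature count mismatch with fitted schema")
        if X.ndim != 2:
            raise DomainError("X must be 2-D (n_samples, n_features)")
        return X

    def fit(self, X, y):
        Xa = self._coerce(X, fitting=True)
        y = np.asarray(y, dtype=float).ravel()
        if len(y) != len(Xa):
            raise DomainError("X and y length mismatch")
        if not np.all(np.isfinite(Xa)) or not np.all(np.isfinite(y)):
            raise DataError("non-finite values in training data")
        self.n_features_in_ = Xa.shape[1]

        if self.cv:
            if len(y) < self.cv:
                raise DomainError(f"cv={self.cv} folds need at least that many samples")
            oof = np.empty_like(y)
            for tr, te in KFold(self.cv, shuffle=True, random_state=self.random_state).split(Xa):
                m = self._make_model()
                m.fit(Xa[tr], y[tr])
                oof[te] = m.predict(Xa[te])
            self.cv_rmse_ = float(np.sqrt(np.mean((oof - y) ** 2)))
            sst = float(np.sum((y - y.mean()) ** 2))
            self.cv_r2_ = 1.0 - float(np.sum((oof - y) ** 2)) / sst if sst > 0 else float("nan")
            self.oof_prediction_ = oof
        else:
            self.cv_rmse_ = float("nan")
            self.cv_r2_ = float("nan")

        self.model_ = self._make_model()
        self.model_.fit(Xa, y)
        return self

    def predict(self, X):
        check_is_fitted(self, "model_")
        return np.asarray(self.model_.predict(self._coerce(X, fitting=False)), dtype=float)


@dataclass
class Isoscape:
    """A fitted isoscape: model handle, predictors, raster and CV metrics."""

    learner: str
    model: IsoscapeRegressor
    predictors: list[str]
    raster: xr.DataArray | None
    cv_rmse: float
    cv_r2: float
    n_sites: int
    seed: int


def fit_isoscape(
    sites: pd.DataFrame,
    features: pd.DataFrame,
    *,
    learner: str = "xgboost",
    target_col: str = "d18o_tr_std",
    cv: int | None = 10,
    seed: int = 0,
    **hyper,
) -> Isoscape:
    """Fit a tree-ensemble isoscape from standardized site values and a
    predictor table (see :func:`build_feature_table`). Requires >= 20 sites.
    """
    if target_col not in sites.columns:
        raise DataError(f"sites table lacks target column '{target_col}'")
    if len(sites) < 20:
        raise DomainError(f"need >= 20 sites to fit an isoscape, got {len(sites)}")
    if len(features) != len(sites):
        raise DomainError("features and sites must align row-wise")
    est = IsoscapeRegressor(learner=learner, cv=cv, random_state=seed, **hyper)
    est.fit(features, np.asarray(sites[target_col], float))
    return Isoscape(
        learner=learner,
        model=est,
        predictors=list(features.columns),
        raster=None,
        cv_rmse=est.cv_rmse_,
        cv_r2=est.cv_r2_,
        n_sites=len(sites),
        seed=seed,
    )


def grid_feature_table(grid: ClimateGrid, extra_fields: dict | None = None) -> pd.DataFrame:
    """Predictor table for every grid cell, matching
    :func:`build_feature_table` column-for-column."""
    lat2, lon2 = np.meshgrid(grid.lat, grid.lon, indexing="ij")
    tmean = grid.seasonal_mean("tmean").values.ravel()
    rh = grid.seasonal_mean("rh").values.ravel()
    feats = pd.DataFrame(
        {
            "lon": lon2.ravel(),
            "lat": lat2.ravel(),
            "elevation_m": grid.var("elevation").values.ravel(),
            "tmean_ms": tmean,
            "rh_ms": rh,
        }
    )
    feats = pd.concat([feats, _one_hot_climate(climate_class(tmean, rh))], axis=1)
    if extra_fields:
        for name, fld in extra_fields.items():
            feats[name] = np.asarray(fld.values, float).ravel()
    return feats


def predict_isoscape(iso: Isoscape, grid: ClimateGrid, extra_fields: dict | None = None) -> Isoscape:
    """Predict the full-domain raster (including cells without nearby
    training sites) and return the isoscape with its raster attached."""
    if iso.model is None or not hasattr(iso.model, "model_"):
        raise DomainError("isoscape model is not fitted")
    feats = grid_feature_table(grid, extra_fields)
    pred = iso.model.predict(feats).reshape(len(grid.lat), len(grid.lon))
    raster = xr.DataArray(
        pred,
        dims=("lat", "lon"),
        coords={"lat": grid.lat, "lon": grid.lon},
        name=f"d18o_tr_{iso.learner}",
        attrs={"units": "permil"},
    )
    return replace_raster(iso, raster)


def replace_raster(iso: Isoscape, raster: xr.DataArray) -> Isoscape:
    return Isoscape(
        learner=iso.learner, model=iso.model, predictors=iso.predictors,
        raster=raster, cv_rmse=iso.cv_rmse, cv_r2=iso.cv_r2,
        n_sites=iso.n_sites, seed=iso.seed,
    )
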