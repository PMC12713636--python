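"""File formats, configuration and the pipeline driver.

Formats are deliberately plain: UTF-8 comma-separated CSV with a header and
"." decimals for site/station tables, NetCDF (classic format via the scipy
backend) with CF-style ``lat``/``lon`` coordinate variables and a ``units``
attribute for rasters, GeoJSON for region polygons, YAML for pipeline
configuration. Every artifact written by :func:`run_pipeline` embeds the
SHA-256 hash of the fully-resolved configuration so a provenance audit can
reconstruct the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .cellulose import CelluloseParams, invert_cellulose
from .errors import ConfigError, DataError
from .grids import ClimateGrid
from . import isoscape as iso_mod
from . import regional as reg_mod
from .drivers import commonality_two, pearson
from .simulate import SyntheticConfig, gen_climate_grid, gen_d18op_field, gen_sites, gen_stations

logger = logging.getLogger(__name__)

SITE_COLUMNS = ["id", "lon", "lat", "elevation_m", "species_class", "d18o_tr_permil"]

_NETCDF_ENGINE = "scipy"


# ---------------------------------------------------------------------------
# site tables

def read_sites(path) -> pd.DataFrame:
    """Read and validate a site CSV.

    Required header: ``id, lon, lat, elevation_m, species_class,
    d18o_tr_permil``. Species classes are normalized case-insensitively to
    conifer/broadleaf. Malformed rows are rejected with their (1-based,
    header-inclusive) row numbers.
    """
    try:
        df = pd.read_csv(path, comment="#")
    except FileNotFoundError as e:
        raise ConfigError(f"site file not found: {path}") from e
    except Exception as e:
        raise DataError(f"{path}: cannot parse CSV: {e}") from e

    missing = [c for c in SITE_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"{path}: missing required column(s): {missing}")

    problems = []
    for col in ("lon", "lat", "elevation_m", "d18o_tr_permil"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        problems += [f"row {i + 2}: non-numeric {col} '{df.at[i, col]}'" for i in bad]
        df[col] = coerced

    species = df["species_class"].astype(str).str.strip().str.lower()
    bad_sp = df.index[~species.isin(iso_mod.SPECIES_CLASSES)]
    problems += [f"row {i + 2}: unknown species_class '{df.at[i, 'species_class']}'" for i in bad_sp]
    df["species_class"] = species

    lo, hi = iso_mod.D18O_TR_WINDOW
    checks = [
        (~df["lon"].between(-180, 180), "lon outside [-180, 180]"),
        (~df["lat"].between(-90, 90), "lat outside [-90, 90]"),
        (~df["d18o_tr_permil"].between(lo, hi), f"d18o_tr_permil outside sanity window [{lo}, {hi}]"),
    ]
    for mask, msg in checks:
        problems += [f"row {i + 2}: {msg}" for i in df.index[mask.fillna(False)]]

    if problems:
        raise DataError(f"{path}: " + "; ".join(problems[:20]))
    return df


def write_sites(df: pd.DataFrame, path, *, meta: dict | None = None) -> None:
    """Write a site table; provenance metadata goes into ``#`` header lines."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------------------
# rasters

def read_grid(path, varname: str | None = None) -> ClimateGrid:
    """Read a NetCDF raster into a :class:`ClimateGrid` (descending-latitude
    files are normalized to ascending). With ``varname``, verify the
    variable exists, erroring with the available names otherwise."""
    try:
        ds = xr.open_dataset(path, engine=_NETCDF_ENGINE).load()
    except FileNotFoundError as e:
        raise ConfigError(f"grid file not found: {path}") from e
    grid = ClimateGrid.from_dataset(ds)
    if varname is not None:
        grid.var(varname)  # raises DataError listing alternatives
    return grid


def write_grid(grid: ClimateGrid, path, *, meta: dict | None = None) -> None:
    """Write a grid (or a bare DataArray via ``grid_from_da``) to NetCDF;
    round-trips values bit-exactly (float64, classic format)."""
    ds = grid.ds.copy()
    ds.attrs.update(meta or {})
    ds.to_netcdf(path, engine=_NETCDF_ENGINE)


def grid_from_da(da: xr.DataArray, name: str | None = None) -> ClimateGrid:
    return ClimateGrid(da.to_dataset(name=name or da.name or "field"))


# ---------------------------------------------------------------------------
# pipeline configuration

@dataclass
class PipelineConfig:
    """Fully-resolved pipeline settings.

    With ``synthetic=True`` the input networks and grids are generated from
    ``synthetic`` settings; otherwise ``site_csv`` and ``grid_nc`` (holding
    tmean/vap-or-rh/elevation/d18op variables) must point at files.
    """

    outdir: str = "trisoscape_out"
    seed: int = 0
    synthetic: bool = True
    synthetic_cfg: dict = field(default_factory=dict)
    site_csv: str | None = None
    grid_nc: str | None = None
    region_file: str | None = None
    cellulose: dict = field(default_factory=dict)
    broadleaf_offset: float = iso_mod.BROADLEAF_OFFSET
    season: tuple[int, int] = (5, 9)
    learners: tuple[str, ...] = ("xgboost", "random_forest")
    cv_folds: int = 10
    hyper: dict = field(default_factory=dict)

    def params(self) -> CelluloseParams:
        return CelluloseParams(**self.cellulose)

    def to_dict(self) -> dict:
        d = {
            **{k: getattr(self, k) for k in (
                "outdir", "seed", "synthetic", "synthetic_cfg", "site_csv", "grid_nc",
                "region_file", "cellulose", "broadleaf_offset", "cv_folds", "hyper",
            )},
            "season": list(self.season),
            "learners": list(self.learners),
        }
        return d

    def hash(self) -> str:
        # provenance hash covers the analysis settings, not the output path
        d = {k: v for k, v in self.to_dict().items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    """Load and validate a YAML pipeline configuration."""
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except FileNotFoundError as e:
        raise ConfigError(f"config file not found: {path}") from e
    except yaml.YAMLError as e:
        raise ConfigError(f"{path}: invalid YAML: {e}") from e
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown key(s): {sorted(unknown)}; known: {sorted(known)}")
    if "season" in raw:
        raw["season"] = tuple(raw["season"])
    if "learners" in raw:
        raw["learners"] = tuple(raw["learners"])
    cfg = PipelineConfig(**raw)
    _preflight(cfg)
    return cfg


def _preflight(cfg: PipelineConfig) -> None:
    if not cfg.synthetic:
        for label, p in (("site_csv", cfg.site_csv), ("grid_nc", cfg.grid_nc)):
            if not p:
                raise ConfigError(f"non-synthetic run requires '{label}'")
            if not Path(p).exists():
                raise ConfigError(f"{label} path does not exist: {p}")
    if cfg.region_file and not Path(cfg.region_file).exists():
        raise ConfigError(f"region_file path does not exist: {cfg.region_file}")
    cfg.params()  # validates cellulose constants
    for lr in cfg.learners:
        if lr not in ("xgboost", "random_forest"):
            raise ConfigError(f"unknown learner '{lr}'")


# ---------------------------------------------------------------------------
# orchestration

def _stage(name):
    logger.info("pipeline stage: %s", name)
    return time.time()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full analysis and write the artifact bundle.

    Stages: inputs -> species standardization -> grid-to-site extraction ->
    isoscape fit/predict (both learners + difference map) -> inverse-model
    reconstruction of precipitation delta18O -> continental driver report ->
    regional report + elevation gradients -> manifest. Identical
    configuration yields an identical bundle. Any stage failure removes the
    partially-written bundle and re-raises with the stage name.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": cfg.hash(), "seed": str(cfg.seed)}
    written: list[Path] = []
    artifacts: dict = {"outdir": str(outdir), "config_hash": cfg.hash()}

    def emit_csv(name, df):
        p = outdir / name
        write_sites(df, p, meta=meta)
        written.append(p)
        artifacts[name] = str(p)

    def emit_nc(name, grid):
        p = outdir / name
        write_grid(grid, p, meta=meta)
        written.append(p)
        artifacts[name] = str(p)

    stage = "inputs"
    try:
        t0 = _stage(stage)
        if cfg.synthetic:
            scfg = SyntheticConfig(**{"seed": cfg.seed, **cfg.synthetic_cfg})
            grid = gen_d18op_field(scfg, gen_climate_grid(scfg))
            sites = gen_sites(scfg, grid)
            stations = gen_stations(scfg, grid)
            emit_csv("stations.csv", stations)
        else:
            sites = read_sites(cfg.site_csv)
            grid = read_grid(cfg.grid_nc)

        stage = "standardize"
        _stage(stage)
        sites = iso_mod.standardize_species(sites, cfg.broadleaf_offset)

        stage = "extract"
        _stage(stage)
        rh_ms = grid.seasonal_mean("rh", cfg.season)
        p_ms = grid.seasonal_mean("d18op", cfg.season)
        sites["rh_ms"] = iso_mod.extract_at_sites(rh_ms, sites)
        sites["d18op_ms"] = iso_mod.extract_at_sites(p_ms, sites)
        regions = reg_mod.load_regions(cfg.region_file) if cfg.region_file else None
        sites = reg_mod.assign_region(sites, regions)
        emit_csv("sites_processed.csv", sites)

        stage = "isoscape"
        _stage(stage)
        feats = iso_mod.build_feature_table(sites, grid)
        rasters = {}
        for lr in cfg.learners:
            iso = iso_mod.fit_isoscape(
                sites, feats, learner=lr, cv=cfg.cv_folds, seed=cfg.seed, **cfg.hyper
            )
            iso = iso_mod.predict_isoscape(iso, grid)
            rasters[lr] = iso
            emit_nc(f"isoscape_{lr}.nc", grid_from_da(iso.raster))
            artifacts[f"cv_{lr}"] = {"rmse": iso.cv_rmse, "r2": iso.cv_r2}
        if len(rasters) == 2:
            a, b = (rasters[lr].raster for lr in cfg.learners)
            diff = (a - b).rename("isoscape_difference").assign_attrs(units="permil")
            emit_nc("isoscape_difference.nc", grid_from_da(diff))

        stage = "reconstruct"
        _stage(stage)
        first = rasters[cfg.learners[0]].raster
        recon = xr.DataArray(
            invert_cellulose(first.values, rh_ms.values, cfg.params()),
            dims=("lat", "lon"), coords={"lat": grid.lat, "lon": grid.lon},
            name="d18o_p_reconstructed", attrs={"units": "permil"},
        )
        emit_nc("reconstructed_d18op.nc", grid_from_da(recon))

        stage = "drivers"
        _stage(stage)
        y = np.asarray(sites["d18o_tr_std"], float)
        rows = []
        for name, col in (("rh", "rh_ms"), ("d18o_p", "d18op_ms")):
            res = pearson(np.asarray(sites[col], float), y)
            rows.append({"driver": name, "r": res.r, "p": res.p, "n": res.n})
        emit_csv("drivers_continental.csv", pd.DataFrame(rows))
        comm = commonality_two(y, sites["rh_ms"], sites["d18op_ms"])
        emit_csv("commonality.csv", pd.DataFrame([comm.as_row(model="rh+d18o_p")]))

        stage = "regional"
        _stage(stage)
        corr_df, comm_df = reg_mod.regional_driver_report(
            sites, {"rh": "rh_ms", "d18o_p": "d18op_ms"},
            commonality_pairs=[("rh_ms", "d18op_ms")],
        )
        emit_csv("regional_correlations.csv", corr_df)
        emit_csv("regional_commonality.csv", comm_df)
        elev_rows = []
        for scope, g in [("continental", sites)] + list(sites.groupby("region")):
            if scope == reg_mod.UNASSIGNED or len(g) < 3 or np.ptp(g["elevation_m"]) == 0:
                continue
            ef = reg_mod.elevation_gradient(g)
            elev_rows.append(
                {"scope": scope, "slope_per_100m": ef.slope_per_100m,
                 "r": ef.r, "p": ef.p, "n": ef.n}
            )
        emit_csv("elevation_gradients.csv", pd.DataFrame(elev_rows))

        stage = "manifest"
        _stage(stage)
        manifest = {
            "config": cfg.to_dict(),
            "config_hash": cfg.hash(),
            "seed": cfg.seed,
            "artifacts": sorted(p.name for p in written),
        }
        mp = outdir / "manifest.json"
        mp.write_text(json.dumps(manifest, indent=1, default=str))
        artifacts["manifest"] = str(mp)
        logger.info("pipeline complete (%.1fs)", time.time() - t0)
        return artifacts
    except Exception as e:
        for p in written:  # no partial bundles
            p.unlink(missing_ok=True)
        if isinstance(e, (ConfigError, DataError)):
            raise
        raise DataError(f"pipeline failed in stage '{stage}': {e}") from e
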