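"""Subregion assignment and isotope-elevation gradient analysis.

Sites are mapped onto circulation-regime subregions (Indian Summer Monsoon,
East Asian Summer Monsoon, arid westerlies, high latitudes) by
point-in-polygon; the cellulose-delta18O-elevation lapse rate is an ordinary
least-squares slope reported per 100 m of ascent, with the Pearson r/p of
the underlying relationship.

Default region geometries are editable bounding boxes; faithful polygon
outlines can be supplied as a GeoJSON-style file instead. Polygon edges are
inclusive; a point on a shared edge of two adjacent regions is assigned to
the first region in configuration order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import stats
from shapely.geometry import Polygon, box, shape

from .drivers import CommonalityResult, CorrelationResult, commonality_two, pearson
from .errors import ConfigError, DomainError

__all__ = [
    "RegionSpec",
    "default_regions",
    "load_regions",
    "write_regions",
    "assign_region",
    "ElevationFit",
    "elevation_gradient",
    "regional_driver_report",
]

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"

# (lat_min, lat_max, lon_min, lon_max) defaults; Supplementary-grade polygon
# outlines can replace these via a region file.
_DEFAULT_BOXES = {
    "ISM": (5.0, 33.0, 70.0, 100.0),
    "EASM": (20.0, 45.0, 100.0, 125.0),
    "arid_westerlies": (35.0, 50.0, 55.0, 95.0),
    "high_latitudes": (50.0, 90.0, 55.0, 180.0),
}


@dataclass
class RegionSpec:
    """A named subregion with a lon/lat polygon (inclusive edges)."""

    name: str
    polygon: Polygon

    def __post_init__(self) -> None:
        if not self.polygon.is_valid:
            raise ConfigError(f"region '{self.name}': self-intersecting or invalid polygon")


def default_regions() -> list[RegionSpec]:
    """The four built-in Asian subregion bounding boxes."""
    return [
        RegionSpec(name, box(b[2], b[0], b[3], b[1]))  # box(minx, miny, maxx, maxy)
        for name, b in _DEFAULT_BOXES.items()
    ]


def _validate_disjoint(regions: list[RegionSpec]) -> None:
    for i, a in enumerate(regions):
        for b in regions[i + 1 :]:
            inter = a.polygon.intersection(b.polygon)
            if inter.area > 1e-9:  # shared edges are fine, shared area is not
                raise ConfigError(
                    f"regions '{a.name}' and '{b.name}' overlap with area {inter.area:.3g}"
                )


def load_regions(path) -> list[RegionSpec]:
    """Load regions from a GeoJSON FeatureCollection with a ``name``
    property per feature; validates non-overlap at load time."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise ConfigError(f"{path}: expected a GeoJSON FeatureCollection")
    regions = []
    for i, feat in enumerate(gj.get("features", [])):
        name = feat.get("properties", {}).get("name")
        if not name:
            raise ConfigError(f"{path}: feature {i} lacks a 'name' property")
        geom = shape(feat["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise ConfigError(f"{path}: region '{name}' is not a polygon")
        regions.append(RegionSpec(name, geom))
    _validate_disjoint(regions)
    return regions


def write_regions(regions: list[RegionSpec], path) -> None:
    gj = {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "properties": {"name": r.name},
                "geometry": json.loads(shapely.to_geojson(r.polygon)),
            }
            for r in regions
        ],
    }
    with open(path, "w") as fh:
        json.dump(gj, fh, indent=1)


def assign_region(sites: pd.DataFrame, regions: list[RegionSpec] | None = None) -> pd.DataFrame:
    """Label each site with its subregion (or ``unassigned``).

    Edges are inclusive; among adjacent regions sharing an edge the first
    match in configuration order wins. Unassigned sites are kept: they still
    participate in continental-scale analyses.
    """
    regions = default_regions() if regions is None else regions
    _validate_disjoint(regions)
    lon = np.asarray(sites["lon"], float)
    lat = np.asarray(sites["lat"], float)
    label = np.full(len(sites), UNASSIGNED, dtype=object)
    for r in reversed(regions):  # earlier regions overwrite later ones
        hit = shapely.intersects_xy(r.polygon, lon, lat)
        label[hit] = r.name
    out = sites.copy()
    out["region"] = label
    return out


@dataclass(frozen=True)
class ElevationFit:
    """OLS isotope-elevation gradient: slope in permil per 100 m, with the
    Pearson correlation of the relationship."""

    slope_per_100m: float
    intercept: float
    r: float
    p: float
    n: int


def elevation_gradient(sites: pd.DataFrame, value_col: str = "d18o_tr_std") -> ElevationFit:
    """OLS regression of cellulose delta18O on site elevation (m), the slope
    reported per 100 m. Requires >= 3 sites and non-constant elevation."""
    if value_col not in sites.columns:
        raise DomainError(f"sites table lacks '{value_col}'")
    elev = np.asarray(sites["elevation_m"], float)
    y = np.asarray(sites[value_col], float)
    ok = np.isfinite(elev) & np.isfinite(y)
    elev, y = elev[ok], y[ok]
    if elev.size < 3:
        raise DomainError(f"need >= 3 sites with elevation and isotope values, got {elev.size}")
    if np.ptp(elev) == 0:
        raise DomainError("zero elevation variance")
    if np.ptp(y) == 0:
        # a flat response has slope 0 and no linear association
        return ElevationFit(0.0, float(y[0]), 0.0, 1.0, int(elev.size))
    res = stats.linregress(elev, y)
    return ElevationFit(
        slope_per_100m=float(res.slope) * 100.0,
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p=float(res.pvalue),
        n=int(elev.size),
    )


def regional_driver_report(
    sites: pd.DataFrame,
    driver_cols: dict[str, str],
    commonality_pairs: list[tuple[str, str]] | None = None,
    *,
    value_col: str = "d18o_tr_std",
    min_n: int = 4,
    include_continental: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-region driver attribution tables.

    ``driver_cols`` maps display names to site-table columns holding
    extracted driver values (e.g. ``{"rh": "rh_ms", "d18o_p": "d18op_ms"}``).
    ``commonality_pairs`` lists (rh_col, d18o_p_col) pairs to partition.
    Returns (correlations, commonality) DataFrames; regions with fewer than
    ``min_n`` sites are skipped with a logged warning. Non-significant
    correlations (p > 0.05) are flagged.
    """
    if "region" not in sites.columns:
        raise DomainError("sites must be region-assigned first (see assign_region)")
    groups = [("continental", sites)] if include_continental else []
    groups += [(name, g) for name, g in sites.groupby("region", sort=True) if name != UNASSIGNED]

    corr_rows, comm_rows = [], []
    for name, g in groups:
        if len(g) < min_n:
            logger.warning("region '%s' skipped: only %d site(s)", name, len(g))
            continue
        y = np.asarray(g[value_col], float)
        for disp, col in driver_cols.items():
            res: CorrelationResult = pearson(np.asarray(g[col], float), y)
            corr_rows.append(
                {"region": name, "driver": disp, "r": res.r, "p": res.p,
                 "n": res.n, "significant": res.significant}
            )
        for rh_col, p_col in commonality_pairs or []:
            cres: CommonalityResult = commonality_two(
                y, np.asarray(g[rh_col], float), np.asarray(g[p_col], float)
            )
            comm_rows.append({"region": name, **cres.as_row(model=f"{rh_col}+{p_col}")})
    return pd.DataFrame(corr_rows), pd.DataFrame(comm_rows)
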