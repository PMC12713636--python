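"""Mechanistic cellulose delta18O physics.

Saturation vapor pressure (Magnus form), relative humidity, growing-season
aggregation, and the forward/inverse transfer model linking precipitation
delta18O and relative humidity to tree-ring cellulose delta18O.

The transfer model is the standard Anderson-type simplification of the
Craig-Gordon leaf-water enrichment framework: source water (taken as
growing-season precipitation) is enriched in the leaf by equilibrium and
kinetic fractionation scaled by atmospheric dryness ``(1 - h)``; a damping
factor ``f0`` expresses the fraction of that enrichment signal exchanged
back toward source water during cellulose synthesis; a constant biosynthetic
offset ``eps_wc`` maps water to cellulose:

    d18O_TR = d18O_P + eps_wc + (1 - f0) * (1 - h) * (eps_eq + eps_k)

All isotope values are permil vs VSMOW; humidity enters the public API in
percent and is converted to fraction ``h = RH / 100`` exactly once, here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError

__all__ = [
    "CelluloseParams",
    "MonthlySeries",
    "saturation_vapor_pressure",
    "relative_humidity",
    "growing_season_mean",
    "forward_cellulose",
    "invert_cellulose",
    "MAY_SEP",
]

logger = logging.getLogger(__name__)

#: Default growing-season window: May through September, inclusive.
MAY_SEP = (5, 9)

# Magnus coefficients for saturation vapor pressure over water (hPa, degC).
_MAGNUS_A = 6.108
_MAGNUS_B = 17.27
_MAGNUS_C = 237.3


@dataclass(frozen=True)
class CelluloseParams:
    """Constants of the cellulose delta18O transfer model.

    Parameters
    ----------
    f0 : float
        Damping/exchange factor in [0, 1]: fraction of the leaf-water
        enrichment signal exchanged back toward source water during
        cellulose synthesis. Dimensionless.
    eps_eq : float
        Equilibrium liquid-vapor fractionation (permil), >= 0.
    eps_k : float
        Kinetic (diffusive) fractionation during transpiration (permil), >= 0.
    eps_wc : float
        Net biosynthetic water -> cellulose offset (permil).
    """

    f0: float = 0.42
    eps_eq: float = 9.0
    eps_k: float = 29.0
    eps_wc: float = 27.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.f0 <= 1.0:
            raise DomainError(f"f0 must be in [0, 1], got {self.f0}")
        if self.eps_eq < 0:
            raise DomainError(f"eps_eq must be >= 0, got {self.eps_eq}")
        if self.eps_k < 0:
            raise DomainError(f"eps_k must be >= 0, got {self.eps_k}")


@dataclass
class MonthlySeries:
    """Twelve monthly values with a valid-month mask.

    ``values[i]`` is the value for calendar month ``i + 1``; ``valid[i]``
    is False where the month is missing.
    """

    values: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (12,):
            raise DomainError(
                f"MonthlySeries needs exactly 12 values, got shape {self.values.shape}"
            )
        if self.valid is None:
            self.valid = np.isfinite(self.values)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (12,):
                raise DomainError("valid mask must have 12 slots")


def saturation_vapor_pressure(t_mean):
    """Saturation vapor pressure (hPa) from air temperature (degC), Magnus form.

    ``e_sat = 6.108 * exp(17.27 * T / (T + 237.3))``. Strictly positive and
    strictly increasing in temperature. Accepts scalars or arrays.
    """
    t = np.asarray(t_mean, dtype=float)
    if np.any(t <= -_MAGNUS_C):
        raise DomainError(
            f"temperature at or below the Magnus singularity (-{_MAGNUS_C} degC)"
        )
    if np.any((t < -90.0) | (t > 60.0)):
        raise DomainError("temperature outside physical range (-90, 60) degC")
    out = _MAGNUS_A * np.exp(_MAGNUS_B * t / (t + _MAGNUS_C))
    return float(out) if np.isscalar(t_mean) else out


def relative_humidity(t_mean, vap, *, clamp_log: list | None = None):
    """Relative humidity (%) from temperature (degC) and vapor pressure (hPa).

    ``RH = 100 * VAP / e_sat(T)``. Values above 100% (supersaturation
    artifacts in gridded products) are clamped to 100 and counted; pass
    ``clamp_log`` (a list) to receive the count, otherwise it is logged.
    """
    v = np.asarray(vap, dtype=float)
    if np.any(v < 0):
        raise DomainError("vapor pressure must be >= 0 hPa")
    rh = 100.0 * v / saturation_vapor_pressure(t_mean)
    n_clamped = int(np.sum(rh > 100.0))
    if n_clamped:
        rh = np.minimum(rh, 100.0)
        if clamp_log is not None:
            clamp_log.append(n_clamped)
        else:
            logger.info("relative_humidity: clamped %d value(s) above 100%%", n_clamped)
    return float(rh) if np.isscalar(vap) and np.isscalar(t_mean) else rh


def growing_season_mean(series: MonthlySeries, window=MAY_SEP, *, strict: bool = True):
    """Unweighted mean of a monthly series over a month window (inclusive).

    In strict mode (default) any masked month inside the window yields NaN;
    in lenient mode the mean of the available months is returned.
    """
    lo, hi = int(window[0]), int(window[1])
    if not (1 <= lo <= hi <= 12):
        raise DomainError(f"invalid month window {window}")
    sel = slice(lo - 1, hi)
    vals = series.values[sel]
    ok = series.valid[sel]
    if strict and not ok.all():
        return float("nan")
    if not ok.any():
        return float("nan")
    return float(vals[ok].mean())


def _leaf_enrichment(rh, params: CelluloseParams):
    """Damped leaf-water enrichment term (permil) from RH in percent."""
    rh_arr = np.asarray(rh, dtype=float)
    if np.any((rh_arr < 0) | (rh_arr > 100)):
        raise DomainError("relative humidity must lie in [0, 100] %")
    h = rh_arr / 100.0
    return (1.0 - params.f0) * (1.0 - h) * (params.eps_eq + params.eps_k)


def forward_cellulose(d18o_p, rh, params: CelluloseParams | None = None):
    """Model tree-ring cellulose delta18O (permil) from precipitation
    delta18O (permil) and relative humidity (%).

    Strictly decreasing in RH for ``f0 < 1`` (drier air enriches leaf water
    and hence cellulose); shifts one-to-one with the source-water value.
    """
    params = params or CelluloseParams()
    out = np.asarray(d18o_p, dtype=float) + params.eps_wc + _leaf_enrichment(rh, params)
    return float(out) if out.ndim == 0 else out


def invert_cellulose(d18o_tr, rh, params: CelluloseParams | None = None):
    """Reconstruct precipitation delta18O (permil) from cellulose delta18O
    and relative humidity (%): exact algebraic inverse of
    :func:`forward_cellulose`.
    """
    params = params or CelluloseParams()
    out = np.asarray(d18o_tr, dtype=float) - params.eps_wc - _leaf_enrichment(rh, params)
    return float(out) if out.ndim == 0 else out
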