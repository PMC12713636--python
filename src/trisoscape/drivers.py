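"""Driver attribution: Pearson correlation and two-predictor commonality
analysis.

Commonality analysis decomposes the R-squared of the two-predictor
regression ``y ~ x1 + x2`` into the unique contribution of each predictor
and a shared (joint) component:

    unique_1 = R2_{12} - R2_{2}
    unique_2 = R2_{12} - R2_{1}
    common   = R2_{1} + R2_{2} - R2_{12}
    total    = R2_{12}

All three R-squared values come from ordinary least squares with an
intercept, computed here explicitly from the residual and total sums of
squares so the partition is pinned to a single documented fitting method.
The joint component can legitimately be negative (suppression); the unique
components cannot. Results are expressed in percent of variance.

p-values are descriptive (two-sided t transform, n - 2 df); no
multiple-testing correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError

__all__ = ["CorrelationResult", "CommonalityResult", "pearson", "commonality_two"]


@dataclass(frozen=True)
class CorrelationResult:
    """Sample Pearson correlation with its two-sided p-value and n."""

    r: float
    p: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p <= 0.05


@dataclass(frozen=True)
class CommonalityResult:
    """Two-predictor variance partition, in percent of variance.

    ``total`` is derived from the components when not supplied, so a result
    built from published component values reproduces the published total.
    """

    unique_rh: float
    unique_p: float
    common: float
    total: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.total is None:
            object.__setattr__(self, "total", self.unique_rh + self.unique_p + self.common)

    def as_row(self, model: str = "", ndigits: int = 2) -> dict:
        """Table row at the conventional 2-decimal reporting precision."""
        return {
            "model": model,
            "unique_rh": round(self.unique_rh, ndigits),
            "unique_p": round(self.unique_p, ndigits),
            "joint": round(self.common, ndigits),
            "total": round(self.total, ndigits),
        }


def _clean_pair(x, y, how: str = "complete"):
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise DomainError(f"length mismatch: {x.size} vs {y.size}")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def pearson(x, y) -> CorrelationResult:
    """Sample Pearson correlation between two vectors.

    Missing values are removed pairwise-complete. Requires at least 3
    complete pairs and non-zero variance in both vectors.
    """
    xc, yc = _clean_pair(x, y)
    n = xc.size
    if n < 3:
        raise DomainError(f"need >= 3 complete pairs, got {n}")
    if np.ptp(xc) == 0 or np.ptp(yc) == 0:
        raise DomainError("correlation undefined: zero variance in an input")
    res = stats.pearsonr(xc, yc)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue), n=n)


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    """R-squared of least squares with intercept: 1 - SSE/SST."""
    A = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ beta
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        raise DomainError("response has zero variance")
    return 1.0 - float(np.sum(resid**2)) / float(sst)


def commonality_two(y, x1, x2, *, collinearity_r: float = 0.999) -> CommonalityResult:
    """Two-predictor commonality analysis of ``y ~ x1 + x2``.

    ``x1`` plays the relative-humidity slot and ``x2`` the precipitation-
    isotope slot of the result, but the computation is symmetric: swapping
    the predictors swaps the unique components and preserves the joint and
    total components. Rows with a missing value in any of the three vectors
    are dropped (complete-case).
    """
    y = np.asarray(y, dtype=float).ravel()
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if not (y.size == x1.size == x2.size):
        raise DomainError("y, x1, x2 must have equal length")
    ok = np.isfinite(y) & np.isfinite(x1) & np.isfinite(x2)
    y, x1, x2 = y[ok], x1[ok], x2[ok]
    if y.size < 4:
        raise DomainError(f"need >= 4 complete rows, got {y.size}")
    if np.ptp(x1) == 0 or np.ptp(x2) == 0:
        raise DomainError("degenerate predictor with zero variance")
    r12 = np.corrcoef(x1, x2)[0, 1]
    if abs(r12) > collinearity_r:
        warnings.warn(
            f"predictors nearly collinear (|r|={abs(r12):.4f}); "
            "joint component may absorb nearly the whole total",
            stacklevel=2,
        )

    r2_1 = _ols_r2(y, x1[:, None])
    r2_2 = _ols_r2(y, x2[:, None])
    r2_12 = _ols_r2(y, np.column_stack([x1, x2]))

    unique_1 = max(r2_12 - r2_2, 0.0)  # clip tiny negative round-off
    unique_2 = max(r2_12 - r2_1, 0.0)
    common = r2_12 - unique_1 - unique_2
    return CommonalityResult(
        unique_rh=100.0 * unique_1,
        unique_p=100.0 * unique_2,
        common=100.0 * common,
        total=100.0 * r2_12,
    )
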