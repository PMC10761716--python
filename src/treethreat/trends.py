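"""Robust trend estimation: Siegel repeated medians with a significance gate.

The repeated-medians estimator takes, for each point i, the median of the
pairwise slopes to all other points, and then the median of those per-point
medians. Its 50% breakdown point means up to half the annual values can be
gross outliers (sensor artefacts, single extreme fire years) without moving
the slope — the property that makes it the estimator of choice for short
noisy environmental series.

Significance of a fitted trend is judged by the two-sided Mann-Kendall test
(Kendall's tau of value against year), the standard nonparametric companion
of median-based slope estimators: it is exactly calibrated under an iid
null, which rank tests applied to the mutually correlated per-point median
slopes are not. Non-significant slopes are treated as "no trend"
downstream: the rate of recent change is set to exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class TrendFit:
    slope: float
    intercept: float
    p_value: float | None
    significant: bool | None
    n: int


def _pairwise_median_slopes(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-point medians m_i = median_{j != i} (y_j - y_i) / (x_j - x_i)."""
    dx = x[None, :] - x[:, None]
    dy = y[None, :] - y[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        s = dy / dx
    np.fill_diagonal(s, np.nan)
    return np.nanmedian(s, axis=1)


def siegel_slope(x, y) -> TrendFit:
    """Siegel repeated-medians slope and intercept.

    slope = median_i median_{j != i} (y_j - y_i)/(x_j - x_i);
    intercept = median_i (y_i - slope * x_i). Requires n >= 3 distinct x.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.unique(x).size != x.size:
        raise ValueError("x values must be distinct")
    m = _pairwise_median_slopes(x, y)
    slope = float(np.median(m))
    intercept = float(np.median(y - slope * x))
    return TrendFit(slope, intercept, None, None, int(x.size))


def slope_significance(x, y, alpha: float = DEFAULT_ALPHA) -> TrendFit:
    """Repeated-medians fit plus a Mann-Kendall significance gate.

    Two-sided Kendall rank correlation of the values against time (exact
    null distribution for short untied series, tie-corrected normal
    approximation otherwise). A constant series has no trend by
    construction: p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    fit = siegel_slope(x, y)
    if np.all(y == y[0]):
        return TrendFit(fit.slope, fit.intercept, 1.0, False, fit.n)
    p = float(stats.kendalltau(x, y).pvalue)
    if np.isnan(p):
        p = 1.0
    return TrendFit(fit.slope, fit.intercept, p, bool(p < alpha), fit.n)
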