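"""Seasonal-trend decomposition of the binned R-R series.

The binned R-R series is split into trend + daily seasonal + remainder with
STL (seasonal-trend decomposition using LOESS).  On a 30-min grid the daily
cycle spans 48 bins, so ``period=48`` is the default.  The trend is the
object of all downstream indicator analysis; the seasonal component captures
the feeding/activity rhythm and the remainder the short-term variability.

Two trend extractors are provided:

* :func:`stl_decompose` — canonical STL (the primary path).  The seasonal
  LOESS window may be "periodic", which constrains each cycle-subseries to an
  effectively constant seasonal pattern; the trend window defaults to the
  standard STL formula.  Inside STL the trend LOESS is locally linear.
* :func:`loess_trend` — a plain local weighted polynomial regression with
  tricube weights (span 0.75, degree 2, Gaussian errors by default), offered
  as an alternative single-curve trend estimate.

Both satisfy the reconstruction identity trend + seasonal + remainder =
input at every bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Union

import numpy as np
from statsmodels.tsa.seasonal import STL

from .preprocess import BinnedSeries

__all__ = ["Decomposition", "stl_decompose", "loess_trend"]


@dataclass
class Decomposition:
    """Trend/seasonal/remainder triple on the input bin grid (ms)."""

    bin_start_h: np.ndarray
    observed: np.ndarray
    trend: np.ndarray
    seasonal: np.ndarray
    remainder: np.ndarray
    period: int
    method_params: Dict[str, object] = field(default_factory=dict)

    def reconstruction_error(self) -> float:
        return float(
            np.max(np.abs(self.observed - (self.trend + self.seasonal + self.remainder)))
        )


def _next_odd(x: float) -> int:
    k = int(np.ceil(x))
    return k + 1 if k % 2 == 0 else k


def _default_trend_window(period: int, seasonal: int) -> int:
    # smallest odd integer > 1.5*period / (1 - 1.5/seasonal)
    return _next_odd(1.5 * period / (1.0 - 1.5 / seasonal) + 1e-9)


def stl_decompose(
    binned: BinnedSeries,
    period: int = 48,
    seasonal_window: Union[str, int] = "periodic",
    trend_window: Optional[int] = None,
    robust: bool = False,
) -> Decomposition:
    """Decompose a gap-free binned series into trend, seasonal, remainder.

    ``seasonal_window="periodic"`` fixes the seasonal shape over the whole
    recording (implemented as a degree-0 seasonal LOESS whose window spans
    every cycle); an odd integer gives a slowly evolving seasonal.  The trend
    window defaults to the standard STL choice for the given period and
    seasonal window.  ``robust`` enables iterated robustness weights and is
    off by default (Gaussian error model).
    """
    values = np.asarray(binned.rr_ms, dtype=float)
    if np.isnan(values).any():
        raise ValueError(
            "series contains missing values; run impute() before decomposition"
        )
    if values.size < 2 * period:
        raise ValueError(
            f"series of {values.size} bins is shorter than two periods "
            f"({2 * period} bins)"
        )
    if seasonal_window == "periodic":
        # a seasonal LOESS window far wider than the series with degree 0
        # reduces each cycle-subseries to (weighted) constancy
        seasonal = _next_odd(10 * values.size + 1)
        seasonal_deg = 0
    else:
        seasonal = int(seasonal_window)
        if seasonal < 3 or seasonal % 2 == 0:
            raise ValueError("seasonal_window must be 'periodic' or an odd integer >= 3")
        seasonal_deg = 1
    if trend_window is None:
        trend_window = _default_trend_window(period, seasonal)
    elif trend_window % 2 == 0:
        raise ValueError("trend_window must be odd")
    res = STL(
        values,
        period=period,
        seasonal=seasonal,
        trend=trend_window,
        seasonal_deg=seasonal_deg,
        trend_deg=1,
        robust=robust,
    ).fit(inner_iter=None, outer_iter=None)
    return Decomposition(
        bin_start_h=np.asarray(binned.bin_start_h, dtype=float).copy(),
        observed=values.copy(),
        trend=np.asarray(res.trend),
        seasonal=np.asarray(res.seasonal),
        remainder=np.asarray(res.resid),
        period=period,
        method_params={
            "method": "stl",
            "seasonal_window": seasonal_window,
            "seasonal_loess_window": seasonal,
            "trend_window": trend_window,
            "robust": robust,
        },
    )


def _tricube(u: np.ndarray) -> np.ndarray:
    u = np.clip(np.abs(u), 0.0, 1.0)
    return (1.0 - u ** 3) ** 3


def loess_trend(
    binned: BinnedSeries,
    span: float = 0.75,
    degree: int = 2,
) -> Decomposition:
    """LOESS trend of the binned series (tricube-weighted local polynomial).

    At each grid point the nearest ``ceil(span * n)`` points are fit with a
    weighted polynomial of the given degree (0, 1, or 2) and the fit is
    evaluated at that point.  Returned as a :class:`Decomposition` with a
    zero seasonal component, so the reconstruction identity still holds with
    remainder = observed - trend.
    """
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if degree not in (0, 1, 2):
        raise ValueError("degree must be 0, 1, or 2")
    y = np.asarray(binned.rr_ms, dtype=float)
    x = np.asarray(binned.bin_start_h, dtype=float)
    if np.isnan(y).any():
        raise ValueError(
            "series contains missing values; run impute() before smoothing"
        )
    n = y.size
    q = max(int(np.ceil(span * n)), degree + 1)
    q = min(q, n)
    trend = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        order = np.argsort(d, kind="stable")[:q]
        dmax = d[order[-1]]
        if dmax == 0:
            w = np.ones(order.size)
        else:
            w = _tricube(d[order] / dmax)
        xs = x[order] - x[i]
        ys = y[order]
        X = np.vander(xs, degree + 1, increasing=True)
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], ys * sw, rcond=None)
        trend[i] = beta[0]
    return Decomposition(
        bin_start_h=x.copy(),
        observed=y.copy(),
        trend=trend,
        seasonal=np.zeros(n),
        remainder=y - trend,
        period=0,
        method_params={"method": "loess", "span": span, "degree": degree},
    )
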