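"""Financial technical indicators on the R-R trend series.

Trading indicators are simple causal functionals of a price series designed
to flag changes of trend direction.  Applied to the decomposed R-R trend
``P_t`` on the 30-min grid they serve as calving-alert signals:

* **SMA(n)** — simple moving average, mean of the last n values (n = 12, 6 h).
* **EMA(n)** — exponential moving average, ``EMA_t = a P_t + (1-a) EMA_{t-1}``
  with ``a = 2/(n+1)``, initialised with the SMA of the first n values.
* **MAD(n)** — moving-average deviation rate, the deviation of the current
  value from its SMA; percent form ``100 (P_t - SMA_t)/SMA_t`` by default.
* **MACD(short, long)** — difference between a short (12-bin, 6-h) and a long
  (26-bin, 13-h) EMA; percent form ``100 (EMA_s - EMA_l)/EMA_l`` by default.
* **RSI(n)** — relative strength index over the last n = 14 bin-to-bin
  changes: ``100 * Up / (Up + Down)`` with simple (unweighted) sums of the
  upward changes and of the absolute downward changes; 50 means balance, 100
  pure rise, 0 pure fall.

All indicators carry an explicit warm-up region of undefined (NaN) leading
values.  MAD and MACD default to the percent form because the reported
indicator magnitudes (order 0.1-0.5 against a ~600-750 ms trend) are only
consistent with a ratio; the raw millisecond difference is available via
``mode="difference"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Union

import numpy as np

from .decompose import Decomposition
from .preprocess import BinnedSeries

__all__ = ["IndicatorSeries", "sma", "ema", "mad", "macd", "rsi"]


@dataclass
class IndicatorSeries:
    """One indicator evaluated on the bin grid; NaN during warm-up."""

    name: str
    params: Dict[str, object]
    bin_start_h: np.ndarray
    values: np.ndarray
    warm_up: int

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.bin_start_h = np.asarray(self.bin_start_h, dtype=float)

    def __len__(self) -> int:
        return self.values.size

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)


def _coerce(series) -> tuple:
    """Accept a BinnedSeries, a Decomposition (its trend), an IndicatorSeries,
    or a bare array; return (values, grid)."""
    if isinstance(series, Decomposition):
        return np.asarray(series.trend, float), np.asarray(series.bin_start_h, float)
    if isinstance(series, BinnedSeries):
        return np.asarray(series.rr_ms, float), np.asarray(series.bin_start_h, float)
    if isinstance(series, IndicatorSeries):
        return np.asarray(series.values, float), np.asarray(series.bin_start_h, float)
    values = np.asarray(series, dtype=float)
    return values, np.arange(values.size) * 0.5


def _check_window(n: int, length: int, name: str) -> bool:
    if n < 1:
        raise ValueError(f"{name} window must be >= 1")
    if n > length:
        warnings.warn(
            f"{name} window {n} exceeds series length {length}; "
            "all values undefined",
            stacklevel=3,
        )
        return False
    return True


def sma(series, n: int = 12) -> IndicatorSeries:
    """Simple moving average of the last ``n`` bins (warm-up ``n - 1``)."""
    values, grid = _coerce(series)
    out = np.full(values.size, np.nan)
    if _check_window(n, values.size, "SMA"):
        cs = np.concatenate(([0.0], np.cumsum(values)))
        out[n - 1 :] = (cs[n:] - cs[:-n]) / n
    return IndicatorSeries("SMA", {"n": n}, grid, out, n - 1)


def ema(series, n: int, init: str = "sma") -> IndicatorSeries:
    """Exponential moving average with smoothing ``a = 2/(n+1)``.

    ``init="sma"`` (default) seeds the recursion with the mean of the first
    ``n`` values (warm-up ``n - 1``); ``init="first"`` seeds with the first
    value (no warm-up).
    """
    values, grid = _coerce(series)
    out = np.full(values.size, np.nan)
    alpha = 2.0 / (n + 1.0)
    if init == "sma":
        if _check_window(n, values.size, "EMA"):
            out[n - 1] = values[:n].mean()
            for t in range(n, values.size):
                out[t] = alpha * values[t] + (1 - alpha) * out[t - 1]
        warm = n - 1
    elif init == "first":
        if n < 1:
            raise ValueError("EMA window must be >= 1")
        if values.size:
            out[0] = values[0]
            for t in range(1, values.size):
                out[t] = alpha * values[t] + (1 - alpha) * out[t - 1]
        warm = 0
    else:
        raise ValueError("init must be 'sma' or 'first'")
    return IndicatorSeries("EMA", {"n": n, "init": init}, grid, out, warm)


def mad(series, n: int = 12, mode: str = "percent") -> IndicatorSeries:
    """Moving-average deviation of the current value from its SMA.

    Percent mode (default): ``100 (P_t - SMA_t)/SMA_t``; difference mode:
    ``P_t - SMA_t`` in the series' units.  Bins where the SMA is zero are
    undefined in percent mode.
    """
    if mode not in ("percent", "difference"):
        raise ValueError("mode must be 'percent' or 'difference'")
    values, grid = _coerce(series)
    base = sma(series, n=n).values
    diff = values - base
    if mode == "percent":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(base != 0, 100.0 * diff / base, np.nan)
    else:
        out = diff
    return IndicatorSeries("MAD", {"n": n, "mode": mode}, grid, out, n - 1)


def macd(
    series,
    short: int = 12,
    long: int = 26,
    mode: str = "percent",
    init: str = "sma",
) -> IndicatorSeries:
    """Short EMA minus long EMA (percent of the long EMA by default)."""
    if short >= long:
        raise ValueError(f"short window ({short}) must be < long window ({long})")
    if mode not in ("percent", "difference"):
        raise ValueError("mode must be 'percent' or 'difference'")
    values, grid = _coerce(series)
    e_short = ema(series, n=short, init=init).values
    e_long = ema(series, n=long, init=init).values
    diff = e_short - e_long
    if mode == "percent":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(e_long != 0, 100.0 * diff / e_long, np.nan)
    else:
        out = diff
    warm = long - 1 if init == "sma" else 0
    return IndicatorSeries(
        "MACD", {"short": short, "long": long, "mode": mode}, grid, out, warm
    )


def rsi(series, n: int = 14, smoothing: str = "simple") -> IndicatorSeries:
    """Relative strength index over the last ``n`` bin-to-bin changes.

    ``smoothing="simple"`` (default) uses plain sums of the upward and the
    absolute downward changes in the window; ``smoothing="wilder"`` uses the
    classical exponentially smoothed averages.  A window with no change at
    all yields 50 (balance) rather than 0/0.  Values lie in [0, 100];
    warm-up is ``n`` bins (the first value needs n changes).
    """
    values, grid = _coerce(series)
    out = np.full(values.size, np.nan)
    if values.size >= n + 1:
        d = np.diff(values)
        up = np.where(d > 0, d, 0.0)
        down = np.where(d < 0, -d, 0.0)
        if smoothing == "simple":
            cs_up = np.concatenate(([0.0], np.cumsum(up)))
            cs_dn = np.concatenate(([0.0], np.cumsum(down)))
            u = cs_up[n:] - cs_up[:-n]
            v = cs_dn[n:] - cs_dn[:-n]
        elif smoothing == "wilder":
            u = np.empty(d.size - n + 1)
            v = np.empty(d.size - n + 1)
            au, av = up[:n].mean(), down[:n].mean()
            u[0], v[0] = au, av
            for j, t in enumerate(range(n, d.size), start=1):
                au = (au * (n - 1) + up[t]) / n
                av = (av * (n - 1) + down[t]) / n
                u[j], v[j] = au, av
        else:
            raise ValueError("smoothing must be 'simple' or 'wilder'")
        tot = u + v
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(tot > 0, 100.0 * u / tot, 50.0)
        out[n:] = r
    elif smoothing not in ("simple", "wilder"):
        raise ValueError("smoothing must be 'simple' or 'wilder'")
    else:
        _check_window(n + 1, values.size, "RSI")
    return IndicatorSeries("RSI", {"n": n, "smoothing": smoothing}, grid, out, n)
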