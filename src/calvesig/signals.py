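"""Turning-point detection and remaining-time-to-calving conversion.

The calving alert is the *peak* of an indicator computed on the R-R trend:
the moment the trend switches from rising to falling.  Two detectors are
provided:

* **retrospective** — the global maximum of the indicator over the analysis
  window (ties broken to the earliest bin).  An indicator that never exceeds
  its detection floor (MAD/MACD > 0, RSI > 50; the SMA has no floor) is
  declared to carry *no signal* — the behaviour expected of a momentum
  oscillator on a trend that only ever declines.
* **online** — a streaming rule usable in real time: the first local maximum
  above the floor that is followed by ``k`` consecutive non-increasing bins
  is confirmed as the peak, ``k`` bins after the fact.

A confirmed signal at time ``s`` with calving at time ``c`` implies a
remaining time of ``c - s`` hours; on the default 30-min grid every remaining
time is a multiple of 0.5 h.

A practical refinement combines MAD with RSI: the peak search is restricted
to bins where MAD is positive *and* RSI exceeds 50 simultaneously, trading a
little sensitivity for robustness against spurious early peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .indicators import IndicatorSeries

__all__ = [
    "TurningPointSignal",
    "RemainingTime",
    "NoSignalError",
    "DEFAULT_FLOORS",
    "detect_peak_retrospective",
    "detect_peak_online",
    "combined_mad_rsi_signal",
    "remaining_hours",
    "divergence_flags",
]

# detection floors: an indicator that never strictly exceeds its floor has
# produced no signal.  None = no floor (pure argmax / local max).
DEFAULT_FLOORS = {"MAD": 0.0, "MACD": 0.0, "RSI": 50.0, "SMA": None, "EMA": None}


class NoSignalError(ValueError):
    """Raised when a remaining time is requested from an absent signal."""


@dataclass
class TurningPointSignal:
    indicator: str
    found: bool
    signal_time_h: Optional[float] = None     # on the bin grid
    peak_value: Optional[float] = None
    mode: str = "retrospective"               # or "online"
    confirmation_lag: Optional[int] = None    # bins, online only


@dataclass
class RemainingTime:
    subject_id: str
    indicator: str
    hours: float

    def __post_init__(self) -> None:
        if self.hours < 0:
            raise ValueError("remaining time must be non-negative")


def _floor_for(ind: IndicatorSeries, threshold) -> Optional[float]:
    if threshold == "auto":
        return DEFAULT_FLOORS.get(ind.name)
    return threshold


def detect_peak_retrospective(
    ind: IndicatorSeries,
    window: Optional[tuple] = None,
    threshold="auto",
) -> TurningPointSignal:
    """Global maximum of the defined indicator values (earliest tie wins).

    ``window`` is an optional (start_h, end_h) restriction, end-exclusive.
    ``threshold`` is the detection floor; "auto" uses :data:`DEFAULT_FLOORS`
    for the indicator's name.  When the indicator never strictly exceeds its
    floor the signal is reported as not found.
    """
    values = ind.values
    mask = ~np.isnan(values)
    if window is not None:
        start, end = window
        mask &= (ind.bin_start_h >= start) & (ind.bin_start_h < end)
    if not mask.any():
        raise ValueError("no defined indicator values in the requested window")
    floor = _floor_for(ind, threshold)
    masked = np.where(mask, values, -np.inf)
    i = int(np.argmax(masked))  # argmax returns the first max: earliest tie
    peak = values[i]
    if floor is not None and not peak > floor:
        return TurningPointSignal(ind.name, found=False, mode="retrospective")
    return TurningPointSignal(
        ind.name,
        found=True,
        signal_time_h=float(ind.bin_start_h[i]),
        peak_value=float(peak),
        mode="retrospective",
    )


def detect_peak_online(
    ind: IndicatorSeries,
    k: int = 3,
    threshold="auto",
    eligible: Optional[np.ndarray] = None,
) -> TurningPointSignal:
    """First local maximum above the floor confirmed by *k* non-increasing bins.

    Scanning forward over defined values, a bin is a candidate when its value
    strictly exceeds the floor (if any), is not below its predecessor, and is
    eligible (optional boolean mask).  The candidate is confirmed when the
    next ``k`` bins are non-increasing; the signal time is the candidate's
    bin, available ``k`` bins later.  The first confirmed candidate wins.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = ind.values
    floor = _floor_for(ind, threshold)
    defined = np.nonzero(~np.isnan(values))[0]
    for pos, i in enumerate(defined):
        v = values[i]
        if floor is not None and not v > floor:
            continue
        if eligible is not None and not eligible[i]:
            continue
        if pos > 0 and values[defined[pos - 1]] > v:
            continue  # not a local max: predecessor higher
        if pos + k >= defined.size:
            break  # not enough future bins to confirm
        tail = values[defined[pos : pos + k + 1]]
        if np.all(np.diff(tail) <= 0):
            return TurningPointSignal(
                ind.name,
                found=True,
                signal_time_h=float(ind.bin_start_h[i]),
                peak_value=float(v),
                mode="online",
                confirmation_lag=k,
            )
    return TurningPointSignal(
        ind.name, found=False, mode="online", confirmation_lag=k
    )


def combined_mad_rsi_signal(
    mad_series: IndicatorSeries,
    rsi_series: IndicatorSeries,
    k: int = 3,
) -> TurningPointSignal:
    """Online MAD-peak detection gated on MAD > 0 and RSI > 50 simultaneously."""
    if mad_series.values.size != rsi_series.values.size or not np.array_equal(
        mad_series.bin_start_h, rsi_series.bin_start_h
    ):
        raise ValueError("MAD and RSI series must share the same bin grid")
    with np.errstate(invalid="ignore"):
        eligible = (mad_series.values > 0) & (rsi_series.values > 50)
    sig = detect_peak_online(mad_series, k=k, threshold=0.0, eligible=eligible)
    return TurningPointSignal(
        "MAD+RSI",
        found=sig.found,
        signal_time_h=sig.signal_time_h,
        peak_value=sig.peak_value,
        mode="online",
        confirmation_lag=k,
    )


def remaining_hours(
    signal: TurningPointSignal,
    calving_time: float,
    subject_id: str = "",
) -> RemainingTime:
    """Hours from the signal to calving: ``calving_time - signal_time``."""
    if not signal.found:
        raise NoSignalError(
            f"no {signal.indicator} signal was found; remaining time undefined"
        )
    if calving_time < signal.signal_time_h:
        raise ValueError(
            f"calving at {calving_time} h precedes the signal at "
            f"{signal.signal_time_h} h"
        )
    return RemainingTime(
        subject_id=subject_id,
        indicator=signal.indicator,
        hours=calving_time - signal.signal_time_h,
    )


def divergence_flags(
    ind: IndicatorSeries,
    trend: np.ndarray,
    window: int = 12,
) -> np.ndarray:
    """Flag bins where indicator and trend move in opposite directions.

    The direction of each series over a trailing ``window`` of bins is the
    sign of its net change; a flag marks strict opposition.  Informational
    only — divergence never gates a signal.
    """
    values = ind.values
    n = values.size
    flags = np.zeros(n, dtype=bool)
    trend = np.asarray(trend, dtype=float)
    for t in range(window, n):
        a, b = values[t - window], values[t]
        if np.isnan(a) or np.isnan(b):
            continue
        di = np.sign(b - a)
        dt = np.sign(trend[t] - trend[t - window])
        flags[t] = di * dt < 0
    return flags
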