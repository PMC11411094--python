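"""Beat-level cleaning, 30-min binning, gap imputation, and unit conversion.

Raw R-R tachograms from ambulatory Holter devices carry detection artifacts
(missed or spurious R waves produce intervals far from the physiological
range).  The cleaning rule used here removes any beat whose R-R interval
deviates from the running average by more than a fixed proportion (30% by
default).  "The average" is taken as a causal running mean of the last
``window`` previously *accepted* beats, falling back to the mean of all
previously accepted beats while fewer than ``window`` have been seen; the
first beat is always accepted.  A causal rule works online and tolerates the
slow trend drift the downstream analysis relies on.

Accepted beats are averaged over left-closed, right-open 30-min bins aligned
to the recording start; near-empty bins are declared missing, and interior
gaps up to ``max_gap`` bins are filled by linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np

__all__ = [
    "BeatSeries",
    "BinnedSeries",
    "ImputationError",
    "filter_outliers",
    "bin_series",
    "impute",
    "rr_to_hr",
    "hr_to_rr",
]


@dataclass
class BeatSeries:
    """Irregular beat-level R-R intervals.

    ``time_s`` is seconds from recording start (strictly increasing);
    ``rr_ms`` is the R-R interval in milliseconds (positive).
    """

    time_s: np.ndarray
    rr_ms: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.time_s.shape != self.rr_ms.shape:
            raise ValueError("time_s and rr_ms must have equal length")
        if self.time_s.size:
            if np.any(np.diff(self.time_s) <= 0):
                raise ValueError("beat times must be strictly increasing")
            if np.any(self.rr_ms <= 0):
                raise ValueError("R-R intervals must be positive")

    def __len__(self) -> int:
        return self.time_s.size


@dataclass
class BinnedSeries:
    """Mean R-R per regular bin; NaN marks a missing bin.

    ``bin_start_h`` is a regular grid of bin-start times (hours from
    recording start) with step ``bin_width_h``.
    """

    bin_start_h: np.ndarray
    rr_ms: np.ndarray
    bin_width_h: float = 0.5
    calving_time_h: Optional[float] = None

    def __post_init__(self) -> None:
        self.bin_start_h = np.asarray(self.bin_start_h, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.bin_start_h.shape != self.rr_ms.shape:
            raise ValueError("bin_start_h and rr_ms must have equal length")
        if self.bin_start_h.size > 1:
            steps = np.diff(self.bin_start_h)
            if not np.allclose(steps, self.bin_width_h, rtol=0, atol=1e-9):
                raise ValueError("bin grid must be regular with step bin_width_h")
        present = ~np.isnan(self.rr_ms)
        if np.any(self.rr_ms[present] <= 0):
            raise ValueError("binned R-R values must be positive where present")

    def __len__(self) -> int:
        return self.bin_start_h.size

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.rr_ms).sum())


class ImputationError(ValueError):
    """Raised when a missing-data run is too long to impute."""


def filter_outliers(
    beats: BeatSeries,
    threshold: float = 0.30,
    window: int = 60,
) -> Tuple[BeatSeries, List[int]]:
    """Remove beats deviating from the running average by more than *threshold*.

    A beat is removed iff ``|rr - m| / m > threshold`` where ``m`` is the mean
    of the last ``window`` accepted beats (all accepted beats so far during
    warm-up).  The comparison is a strict inequality: a beat at exactly
    ``(1 + threshold) * m`` is kept.  Removed beats never enter later means,
    which makes the filter idempotent.

    Returns the surviving series and the indices (into the input) of removed
    beats.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(beats)
    if n == 0:
        return BeatSeries(np.empty(0), np.empty(0)), []

    rr = beats.rr_ms
    keep = np.ones(n, dtype=bool)
    removed: List[int] = []
    buf = np.empty(window)            # ring buffer of accepted rr values
    buf[0] = rr[0]
    count = 1                         # accepted beats so far
    win_sum = rr[0]                   # sum over the ring buffer
    total_sum = rr[0]
    head = 1 % window
    for i in range(1, n):
        if count >= window:
            m = win_sum / window
        else:
            m = total_sum / count
        x = rr[i]
        if abs(x - m) / m > threshold:
            keep[i] = False
            removed.append(i)
            continue
        if count >= window:
            win_sum += x - buf[head]
        else:
            win_sum += x
        buf[head] = x
        head = (head + 1) % window
        total_sum += x
        count += 1
    return BeatSeries(beats.time_s[keep], rr[keep]), removed


def bin_series(
    beats: BeatSeries,
    bin_width: float = 0.5,
    min_beats: int = 30,
    duration: Optional[float] = None,
) -> BinnedSeries:
    """Average R-R over left-closed, right-open bins aligned to time zero.

    Bins holding fewer than ``min_beats`` beats are marked missing.  The grid
    spans ``duration`` hours when given, else up to the last beat.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if len(beats) == 0 and duration is None:
        return BinnedSeries(np.empty(0), np.empty(0), bin_width)
    time_h = beats.time_s / 3600.0
    if duration is None:
        n_bins = int(np.floor(time_h[-1] / bin_width)) + 1
    else:
        n_bins = int(round(duration / bin_width))
    idx = np.floor(time_h / bin_width).astype(int)
    in_range = idx < n_bins
    idx = idx[in_range]
    sums = np.bincount(idx, weights=beats.rr_ms[in_range], minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        values = np.where(counts >= max(min_beats, 1), sums / np.maximum(counts, 1), np.nan)
    grid = np.arange(n_bins) * bin_width
    return BinnedSeries(grid, values, bin_width)


def impute(binned: BinnedSeries, max_gap: int = 48) -> BinnedSeries:
    """Fill interior missing runs of <= *max_gap* bins by linear interpolation.

    Leading and trailing missing bins are trimmed (there is nothing to
    interpolate between); an interior run longer than ``max_gap`` raises
    :class:`ImputationError` reporting the run's extent.
    """
    values = binned.rr_ms.copy()
    present = ~np.isnan(values)
    if present.all():
        return BinnedSeries(
            binned.bin_start_h.copy(), values, binned.bin_width_h,
            binned.calving_time_h,
        )
    if not present.any():
        raise ImputationError("series has no present values")
    first, last = np.nonzero(present)[0][[0, -1]]
    values = values[first : last + 1]
    grid = binned.bin_start_h[first : last + 1]
    missing = np.isnan(values)
    if missing.any():
        # locate interior runs and enforce the gap limit
        padded = np.concatenate(([False], missing, [False]))
        starts = np.nonzero(padded[1:] & ~padded[:-1])[0]
        ends = np.nonzero(~padded[1:] & padded[:-1])[0]
        for s, e in zip(starts, ends):
            run = e - s
            if run > max_gap:
                raise ImputationError(
                    f"unimputable gap of {run} bins "
                    f"(bins {s}..{e - 1}, {grid[s]:g}-{grid[e - 1]:g} h) "
                    f"exceeds max_gap={max_gap}"
                )
        values[missing] = np.interp(
            grid[missing], grid[~missing], values[~missing]
        )
    return BinnedSeries(grid, values, binned.bin_width_h, binned.calving_time_h)


def rr_to_hr(rr_ms):
    """Heart rate in beats per minute from an R-R interval in milliseconds."""
    rr_ms = np.asarray(rr_ms, dtype=float)
    if np.any(rr_ms <= 0):
        raise ValueError("R-R interval must be positive")
    out = 60.0 / (rr_ms / 1000.0)
    return float(out) if out.ndim == 0 else out


def hr_to_rr(hr_bpm):
    """Inverse of :func:`rr_to_hr`: R-R in milliseconds from bpm."""
    hr_bpm = np.asarray(hr_bpm, dtype=float)
    if np.any(hr_bpm <= 0):
        raise ValueError("heart rate must be positive")
    out = 60000.0 / hr_bpm
    return float(out) if out.ndim == 0 else out
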