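"""CSV readers and writers for every pipeline stage artifact.

All files are comma-separated UTF-8 with a mandatory header row, period
decimal separator, and missing values encoded as empty fields.  Readers
validate domain constraints (monotone timestamps, positive R-R) and report
the 1-based file line of the first offending record.
"""

from __future__ import annotations

import os
import tempfile
from typing import Dict, Iterable, List, Optional

import numpy as np
import pandas as pd

from .decompose import Decomposition
from .indicators import IndicatorSeries
from .preprocess import BeatSeries, BinnedSeries
from .signals import TurningPointSignal

__all__ = [
    "ParseError",
    "read_beat_csv",
    "write_beat_csv",
    "read_binned_csv",
    "write_binned_csv",
    "read_components_csv",
    "write_components_csv",
    "write_indicators_csv",
    "read_indicators_csv",
    "write_signals_csv",
    "atomic_write",
]


class ParseError(ValueError):
    """Malformed input file; the message cites the offending line."""


def _read_table(path, required: List[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: cannot parse CSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    return df


def _line(idx: int) -> int:
    # data row idx (0-based) sits on file line idx + 2 (header is line 1)
    return idx + 2


def read_beat_csv(path) -> BeatSeries:
    df = _read_table(path, ["time_s", "rr_ms"])
    if df.empty:
        return BeatSeries(np.empty(0), np.empty(0))
    t = df["time_s"].to_numpy(float)
    rr = df["rr_ms"].to_numpy(float)
    bad = np.nonzero(~np.isfinite(t) | ~np.isfinite(rr))[0]
    if bad.size:
        raise ParseError(f"{path}: malformed row at line {_line(bad[0])}")
    neg = np.nonzero(rr <= 0)[0]
    if neg.size:
        raise ParseError(
            f"{path}: non-positive rr_ms at line {_line(neg[0])}"
        )
    nonmono = np.nonzero(np.diff(t) <= 0)[0]
    if nonmono.size:
        raise ParseError(
            f"{path}: non-increasing time_s at line {_line(nonmono[0] + 1)}"
        )
    return BeatSeries(t, rr)


def write_beat_csv(beats: BeatSeries, path) -> None:
    pd.DataFrame({"time_s": beats.time_s, "rr_ms": beats.rr_ms}).to_csv(
        path, index=False
    )


def read_binned_csv(path) -> BinnedSeries:
    df = _read_table(path, ["bin_start_h", "rr_ms"])
    if df.empty:
        return BinnedSeries(np.empty(0), np.empty(0))
    grid = df["bin_start_h"].to_numpy(float)
    bad = np.nonzero(~np.isfinite(grid))[0]
    if bad.size:
        raise ParseError(f"{path}: malformed bin_start_h at line {_line(bad[0])}")
    values = df["rr_ms"].to_numpy(float)  # empty fields become NaN (missing)
    neg = np.nonzero(~np.isnan(values) & (values <= 0))[0]
    if neg.size:
        raise ParseError(f"{path}: non-positive rr_ms at line {_line(neg[0])}")
    width = float(grid[1] - grid[0]) if grid.size > 1 else 0.5
    return BinnedSeries(grid, values, width)


def write_binned_csv(binned: BinnedSeries, path) -> None:
    pd.DataFrame(
        {"bin_start_h": binned.bin_start_h, "rr_ms": binned.rr_ms}
    ).to_csv(path, index=False)


def write_components_csv(dec: Decomposition, path) -> None:
    pd.DataFrame(
        {
            "bin_start_h": dec.bin_start_h,
            "observed_ms": dec.observed,
            "trend_ms": dec.trend,
            "seasonal_ms": dec.seasonal,
            "remainder_ms": dec.remainder,
        }
    ).to_csv(path, index=False)


def read_components_csv(path) -> Decomposition:
    df = _read_table(
        path, ["bin_start_h", "observed_ms", "trend_ms", "seasonal_ms", "remainder_ms"]
    )
    return Decomposition(
        bin_start_h=df["bin_start_h"].to_numpy(float),
        observed=df["observed_ms"].to_numpy(float),
        trend=df["trend_ms"].to_numpy(float),
        seasonal=df["seasonal_ms"].to_numpy(float),
        remainder=df["remainder_ms"].to_numpy(float),
        period=0,
        method_params={"method": "loaded"},
    )


def write_indicators_csv(inds: Iterable[IndicatorSeries], path) -> None:
    inds = list(inds)
    data: Dict[str, np.ndarray] = {"bin_start_h": inds[0].bin_start_h}
    for ind in inds:
        data[ind.name.lower()] = ind.values
    pd.DataFrame(data).to_csv(path, index=False)


def read_indicators_csv(path) -> Dict[str, IndicatorSeries]:
    df = _read_table(path, ["bin_start_h"])
    grid = df["bin_start_h"].to_numpy(float)
    out: Dict[str, IndicatorSeries] = {}
    for col in df.columns:
        if col == "bin_start_h":
            continue
        values = df[col].to_numpy(float)
        warm = int(np.argmax(~np.isnan(values))) if (~np.isnan(values)).any() else len(values)
        out[col.upper()] = IndicatorSeries(col.upper(), {}, grid, values, warm)
    return out


def write_signals_csv(
    rows: Iterable[dict],
    path,
) -> None:
    """Rows: dicts with subject_id, indicator, mode, found, signal_time_h,
    peak_value, remaining_h (the latter three empty when found is False)."""
    cols = [
        "subject_id", "indicator", "mode", "found",
        "signal_time_h", "peak_value", "remaining_h",
    ]
    pd.DataFrame(list(rows), columns=cols).to_csv(path, index=False)


def signal_row(
    signal: TurningPointSignal,
    subject_id: str,
    remaining_h: Optional[float] = None,
) -> dict:
    return {
        "subject_id": subject_id,
        "indicator": signal.indicator,
        "mode": signal.mode,
        "found": signal.found,
        "signal_time_h": signal.signal_time_h,
        "peak_value": signal.peak_value,
        "remaining_h": remaining_h,
    }


def atomic_write(path, text: str) -> None:
    """Write text to *path* atomically (tmp file + rename)."""
    d = os.path.dirname(os.path.abspath(path))
    fd, tmp = tempfile.mkstemp(dir=d, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
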