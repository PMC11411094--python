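"""End-to-end pipeline: beats -> binned -> decomposition -> indicators ->
signals -> remaining times, with a run log and atomic artifact writes.
"""

from __future__ import annotations

import datetime
import io as _io
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from . import decompose, indicators, io, preprocess, signals
from .config import PipelineConfig

__all__ = ["RunLog", "run_pipeline", "compute_indicators", "detect_signals"]


@dataclass
class RunLog:
    """Timestamped record of one pipeline run."""

    entries: List[str] = field(default_factory=list)

    def add(self, message: str) -> None:
        stamp = datetime.datetime.now().isoformat(timespec="seconds")
        self.entries.append(f"[{stamp}] {message}")

    def text(self) -> str:
        return "\n".join(self.entries) + "\n"


def compute_indicators(
    dec: decompose.Decomposition, cfg: PipelineConfig
) -> Dict[str, indicators.IndicatorSeries]:
    """The four standard indicators on the decomposed trend."""
    return {
        "SMA": indicators.sma(dec, n=cfg.sma_n),
        "MAD": indicators.mad(dec, n=cfg.mad_n, mode=cfg.mad_mode),
        "MACD": indicators.macd(
            dec, short=cfg.macd_short, long=cfg.macd_long, mode=cfg.macd_mode
        ),
        "RSI": indicators.rsi(dec, n=cfg.rsi_n, smoothing=cfg.rsi_smoothing),
    }


def detect_signals(
    inds: Dict[str, indicators.IndicatorSeries], cfg: PipelineConfig
) -> Dict[str, signals.TurningPointSignal]:
    out = {}
    for name, ind in inds.items():
        if cfg.detector == "online":
            out[name] = signals.detect_peak_online(ind, k=cfg.online_k)
        else:
            out[name] = signals.detect_peak_retrospective(ind)
    return out


def run_pipeline(cfg: PipelineConfig, beats_path, out_dir) -> Dict[str, str]:
    """Execute the full chain on a beat CSV and write all stage artifacts.

    Writes ``binned.csv``, ``components.csv``, ``indicators.csv``,
    ``signals.csv``, and ``run.log`` under *out_dir* (atomically), and
    returns a dict of artifact paths.  Identical config + input give
    identical outputs.
    """
    cfg.validate()
    os.makedirs(out_dir, exist_ok=True)
    log = RunLog()
    log.add(f"run start: subject={cfg.subject_id} seed={cfg.seed}")
    log.add(f"config: {cfg}")

    try:
        beats = io.read_beat_csv(beats_path)
        log.add(f"read {len(beats)} beats from {beats_path}")
        clean, removed = preprocess.filter_outliers(
            beats, threshold=cfg.outlier_threshold, window=cfg.outlier_window
        )
        log.add(f"outlier filter removed {len(removed)} beats")
        binned = preprocess.bin_series(
            clean, bin_width=cfg.bin_width_h, min_beats=cfg.min_beats
        )
        n_missing = binned.n_missing
        binned = preprocess.impute(binned, max_gap=cfg.max_gap_bins)
        log.add(f"binned to {len(binned)} bins; imputed {n_missing} missing")
    except Exception as exc:
        log.add(f"preprocess stage failed: {exc}")
        _write_log(log, out_dir)
        raise RuntimeError(f"preprocess stage failed: {exc}") from exc

    try:
        if cfg.trend_method == "loess":
            dec = decompose.loess_trend(
                binned, span=cfg.loess_span, degree=cfg.loess_degree
            )
        else:
            dec = decompose.stl_decompose(
                binned,
                period=cfg.period,
                seasonal_window=cfg.seasonal_window,
                trend_window=cfg.trend_window,
                robust=cfg.robust,
            )
        log.add(f"decomposed with {dec.method_params}")
    except Exception as exc:
        log.add(f"decompose stage failed: {exc}")
        _write_log(log, out_dir)
        raise RuntimeError(f"decompose stage failed: {exc}") from exc

    inds = compute_indicators(dec, cfg)
    sigs = detect_signals(inds, cfg)
    n_found = sum(s.found for s in sigs.values())
    log.add(f"signals found for {n_found}/4 indicators")

    rows = []
    for name, sig in sigs.items():
        remaining = None
        if sig.found and cfg.calving_time_h is not None:
            remaining = signals.remaining_hours(
                sig, cfg.calving_time_h, cfg.subject_id
            ).hours
        rows.append(io.signal_row(sig, cfg.subject_id, remaining))

    paths = {
        "binned": os.path.join(out_dir, "binned.csv"),
        "components": os.path.join(out_dir, "components.csv"),
        "indicators": os.path.join(out_dir, "indicators.csv"),
        "signals": os.path.join(out_dir, "signals.csv"),
        "log": os.path.join(out_dir, "run.log"),
    }
    _atomic_csv(io.write_binned_csv, binned, paths["binned"])
    _atomic_csv(io.write_components_csv, dec, paths["components"])
    _atomic_csv(
        lambda obj, p: io.write_indicators_csv(obj, p), list(inds.values()),
        paths["indicators"],
    )
    _atomic_csv(lambda obj, p: io.write_signals_csv(obj, p), rows, paths["signals"])
    log.add("artifacts written")
    _write_log(log, out_dir)
    return paths


def _atomic_csv(writer, obj, path) -> None:
    buf = _io.StringIO()
    writer(obj, buf)
    io.atomic_write(path, buf.getvalue())


def _write_log(log: RunLog, out_dir) -> None:
    io.atomic_write(os.path.join(out_dir, "run.log"), log.text())
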