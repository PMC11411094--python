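"""Turning-point detectors: argmax oracle, tie-breaks, detection floors,
online confirmation, combined MAD+RSI gating, and remaining-time arithmetic."""

import numpy as np
import pytest

from calvesig import (
    BinnedSeries,
    combined_mad_rsi_signal,
    detect_peak_online,
    detect_peak_retrospective,
    generate_components,
    mad,
    remaining_hours,
    rsi,
    stl_decompose,
)
from calvesig.indicators import IndicatorSeries
from calvesig.signals import NoSignalError, divergence_flags
from calvesig.synthetic import SyntheticSpec, bin_grid


def ind(values, name="SMA", warm=0):
    values = np.asarray(values, dtype=float)
    return IndicatorSeries(name, {}, np.arange(values.size) * 0.5, values, warm)


class TestRetrospective:
    def test_triangular_peak_found_at_apex(self):
        v = np.concatenate([np.arange(41.0), np.arange(39.0, 19.0, -1.0)])
        sig = detect_peak_retrospective(ind(v))
        assert sig.found and sig.signal_time_h == 40 * 0.5

    def test_plateau_tie_broken_to_earliest(self):
        v = np.zeros(60)
        v[30:33] = 5.0
        sig = detect_peak_retrospective(ind(v))
        assert sig.signal_time_h == 30 * 0.5

    def test_equals_brute_force_argmax_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            v = rng.normal(0, 1, 100)
            sig = detect_peak_retrospective(ind(v))
            best = max(range(100), key=lambda i: (v[i], -i))
            assert sig.signal_time_h == best * 0.5
            assert sig.peak_value == pytest.approx(v[best])

    def test_rsi_identically_zero_reports_no_signal(self):
        sig = detect_peak_retrospective(ind(np.zeros(50), name="RSI"))
        assert not sig.found and sig.signal_time_h is None

    def test_mad_below_floor_reports_no_signal(self):
        sig = detect_peak_retrospective(ind(-1.0 - np.arange(30.0), name="MAD"))
        assert not sig.found

    def test_all_nan_window_raises(self):
        with pytest.raises(ValueError):
            detect_peak_retrospective(ind(np.full(10, np.nan)))

    def test_window_restriction(self):
        v = np.zeros(100)
        v[10] = 5.0
        v[80] = 3.0
        sig = detect_peak_retrospective(ind(v), window=(20.0, 50.0))
        assert sig.signal_time_h == 40.0  # bin 80


class TestOnline:
    def test_clean_peak_matches_retrospective(self):
        v = np.concatenate([np.arange(41.0), np.arange(39.0, 19.0, -1.0)])
        retro = detect_peak_retrospective(ind(v))
        online = detect_peak_online(ind(v), k=3)
        assert online.found
        assert online.signal_time_h == retro.signal_time_h
        assert online.confirmation_lag == 3

    def test_never_above_threshold_not_found(self):
        sig = detect_peak_online(ind(np.full(50, -2.0), name="MAD"), k=3)
        assert not sig.found

    def test_monotone_rise_without_decline_not_confirmed(self):
        sig = detect_peak_online(ind(np.arange(50.0)), k=3)
        assert not sig.found

    def test_k_validated(self):
        with pytest.raises(ValueError):
            detect_peak_online(ind(np.arange(10.0)), k=0)


class TestCombined:
    def grids(self, mad_v, rsi_v):
        return ind(mad_v, "MAD"), ind(rsi_v, "RSI")

    def test_rsi_never_above_fifty_blocks_signal(self):
        m = np.concatenate([np.arange(20.0), np.arange(18.0, 0.0, -1.0)])
        r = np.full(m.size, 40.0)
        sig = combined_mad_rsi_signal(*self.grids(m, r))
        assert not sig.found

    def test_restriction_without_effect_matches_mad_only(self):
        m = np.concatenate([np.zeros(5), np.arange(15.0), np.arange(13.0, -1.0, -1.0),
                            np.zeros(5)])
        r = np.where(m > 0, 80.0, 20.0)
        only = detect_peak_online(ind(m, "MAD"), k=3)
        both = combined_mad_rsi_signal(*self.grids(m, r))
        assert both.found and both.signal_time_h == only.signal_time_h

    def test_grid_mismatch_rejected(self):
        a = ind(np.arange(10.0), "MAD")
        b = IndicatorSeries("RSI", {}, np.arange(10) * 0.25, np.arange(10.0), 0)
        with pytest.raises(ValueError):
            combined_mad_rsi_signal(a, b)

    def test_agrees_with_mad_only_on_most_default_replicates(self):
        close = 0
        n_rep = 20
        for r in range(n_rep):
            spec = SyntheticSpec(seed=8000 + r)
            trend, seas, rem = generate_components(spec)
            dec = stl_decompose(
                BinnedSeries(bin_grid(spec), trend + seas + rem)
            )
            m, s = mad(dec), rsi(dec)
            a = detect_peak_online(m, k=3)
            b = combined_mad_rsi_signal(m, s, k=3)
            if a.found and b.found and abs(a.signal_time_h - b.signal_time_h) <= 1.0:
                close += 1
        assert close / n_rep >= 0.7


class TestRemainingTime:
    def test_arithmetic(self):
        sig = detect_peak_retrospective(ind(np.concatenate(
            [np.arange(96.0), np.arange(94.0, 50.0, -1.0)])))
        assert sig.signal_time_h == 47.5
        rt = remaining_hours(sig, 100.0, "h000")
        assert rt.hours == pytest.approx(52.5)

    def test_result_on_half_hour_grid(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            sig = detect_peak_retrospective(ind(rng.normal(0, 1, 80)))
            rt = remaining_hours(sig, 60.0)
            assert (rt.hours * 2) == pytest.approx(round(rt.hours * 2))

    def test_signal_at_calving_gives_zero(self):
        v = np.arange(21.0)
        v[-1] = 100.0
        sig = detect_peak_retrospective(ind(v))
        assert remaining_hours(sig, sig.signal_time_h).hours == 0.0

    def test_calving_before_signal_rejected(self):
        sig = detect_peak_retrospective(ind(np.concatenate(
            [np.arange(30.0), [0.0]])))
        with pytest.raises(ValueError):
            remaining_hours(sig, 1.0)

    def test_no_signal_propagates(self):
        sig = detect_peak_retrospective(ind(np.zeros(30), name="RSI"))
        with pytest.raises(NoSignalError):
            remaining_hours(sig, 100.0)


def test_monotone_decline_silences_momentum_indicators():
    """A trend that only declines never crosses its SMA from below: RSI stays
    near zero and threshold-gated online MAD finds nothing."""
    spec = SyntheticSpec(mode="monotone_decline", seed=21)
    trend, seas, rem = generate_components(spec)
    dec = stl_decompose(BinnedSeries(bin_grid(spec), trend + seas + rem))
    assert not detect_peak_retrospective(rsi(dec)).found
    assert not detect_peak_online(mad(dec), k=3).found


def test_divergence_flags_detect_opposition():
    trend = np.linspace(0, 10, 40)             # rising trend
    indicator = ind(np.linspace(5, 0, 40))      # falling indicator
    flags = divergence_flags(indicator, trend, window=5)
    assert flags[10:].all()
    agree = divergence_flags(ind(trend), trend, window=5)
    assert not agree.any()
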