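"""HRV metric computation: time domain, PCHIP resampling, band power."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hrvgaps.metrics import (HF_BAND, LF_BAND, ResampledSignal, band_filter,
                             band_power, censored_median, compute_hrv,
                             resample_pchip, subwindow_ln_variances,
                             time_domain)
from hrvgaps.windows import find_gaps

from conftest import make_window, one_hz_window


def brute_time_domain(ibis):
    xs = sorted(ibis)
    n = len(xs)
    med = xs[n // 2] if n % 2 else (xs[n // 2 - 1] + xs[n // 2]) / 2
    mean = sum(ibis) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in ibis) / (n - 1))
    sq = [(ibis[i + 1] - ibis[i]) ** 2 for i in range(n - 1)]
    return med, sd, math.sqrt(sum(sq) / len(sq))


def test_constant_series():
    med, sd, rms = time_domain(make_window([0, 1, 2], [800, 800, 800]))
    assert (med, sd, rms) == (800.0, 0.0, 0.0)


def test_single_pair():
    med, sd, rms = time_domain(make_window([0, 1], [790, 810]))
    assert med == 800.0 and rms == 20.0


def test_single_sample_invalid():
    assert time_domain(make_window([0], [800])) == (None, None, None)


def test_time_domain_matches_brute_force(rng):
    for _ in range(100):
        n = int(rng.integers(2, 500))
        ibis = rng.uniform(400, 1400, n)
        w = make_window(np.linspace(0, 299, n), ibis)
        got = time_domain(w)
        want = brute_time_domain(list(ibis))
        np.testing.assert_allclose(got, want, rtol=1e-9)


@given(st.floats(min_value=-200, max_value=200),
       st.lists(st.floats(min_value=500, max_value=1200), min_size=3, max_size=40))
def test_shift_invariance(shift, ibis):
    w0 = make_window(np.arange(len(ibis)), ibis)
    w1 = make_window(np.arange(len(ibis)), np.asarray(ibis) + shift)
    m0, s0, r0 = time_domain(w0)
    m1, s1, r1 = time_domain(w1)
    assert s1 == pytest.approx(s0, abs=1e-9)
    assert r1 == pytest.approx(r0, abs=1e-9)
    assert m1 == pytest.approx(m0 + shift, abs=1e-9)


# -- resampling -------------------------------------------------------------

def test_resample_constant_series_is_constant():
    w = one_hz_window(n=300, ibi=800.0)
    sig = resample_pchip(w)
    assert sig is not None and sig.rate == 5.0
    np.testing.assert_allclose(sig.values, 800.0)


def test_resample_reproduces_knots():
    off = np.arange(0, 300, 1.0)
    ibis = 900 + 50 * np.sin(0.05 * off)
    w = make_window(off, ibis)
    sig = resample_pchip(w)
    # grid points at 0.2 s spacing hit every integer second exactly
    knots = sig.values[::5][:off.size]
    np.testing.assert_allclose(knots, ibis[:knots.size], rtol=1e-12)


def test_resample_monotone_input_no_overshoot():
    off = np.arange(0, 300, 2.0)
    ibis = np.linspace(600, 1200, off.size) ** 1.1 / 2  # monotone increasing
    w = make_window(off, ibis)
    sig = resample_pchip(w)
    assert (np.diff(sig.values) >= -1e-9).all()


def test_resample_requires_minimum_segment():
    w = make_window([0, 10, 20, 30], [800, 810, 805, 820])  # 30 s only
    assert resample_pchip(w) is None


def test_resample_uses_usable_segment_only():
    off = np.concatenate([np.arange(0, 50), np.arange(150, 300)])
    w = make_window(off, np.full(off.size, 800.0))
    find_gaps(w)
    sig = resample_pchip(w)
    assert sig.start == 150_000
    assert sig.duration_s == pytest.approx(149.0)


# -- band filtering and power ----------------------------------------------

def tone(freq, amp, duration_s=300.0, rate=5.0):
    t = np.arange(0, duration_s + 1e-9, 1 / rate)
    return ResampledSignal(start=0, rate=rate, values=amp * np.sin(2 * np.pi * freq * t))


@pytest.mark.parametrize("freq,inband,outband", [(0.10, "LF", "HF"),
                                                 (0.25, "HF", "LF")])
def test_band_filter_passes_and_rejects_tones(freq, inband, outband):
    sig = tone(freq, 40.0)
    kept = band_filter(sig, inband).values
    killed = band_filter(sig, outband).values
    # compare steady-state amplitudes away from the edges
    core = slice(200, -200)
    assert np.abs(kept[core]).max() == pytest.approx(40.0, rel=0.05)
    assert np.abs(killed[core]).max() < 4.0


def test_band_filter_zero_in_zero_out():
    sig = ResampledSignal(start=0, rate=5.0, values=np.zeros(1500))
    assert np.allclose(band_filter(sig, "LF").values, 0.0)


def test_subwindow_counts_full_segment():
    sig = tone(0.1, 30.0)  # 300 s inclusive -> 1501 samples
    assert sig.values.size == 1501
    assert len(subwindow_ln_variances(band_filter(sig, "LF"), "LF")) == 5
    assert len(subwindow_ln_variances(band_filter(sig, "HF"), "HF")) == 10


def test_censoring_rule_median():
    assert censored_median([3.0, 4.0, 10.0, 5.0, 2.0]) == 4.0


def test_censoring_all_out_returns_none():
    assert censored_median([1.0, 10.0]) is None


def test_zero_variance_subwindow_censored():
    sig = ResampledSignal(start=0, rate=5.0, values=np.zeros(1501))
    assert band_power(sig, "LF") is None


def test_tone_ln_variance_recovered():
    # amplitude chosen so the in-band variance is e^6 ms^2
    amp = math.sqrt(2 * math.e ** 6)
    sig = tone(0.10, amp)
    lf = band_power(band_filter(sig, "LF"), "LF")
    assert lf == pytest.approx(6.0, abs=0.15)


# -- composition ------------------------------------------------------------

def hf_dominant_window():
    off = np.cumsum(np.full(360, 0.85))
    off = off[off < 300]
    ibis = 850 + 30 * np.sin(2 * np.pi * 0.25 * off) + 6 * np.sin(2 * np.pi * 0.1 * off)
    return make_window(off, ibis)


def test_compute_hrv_hf_dominant():
    m = compute_hrv(hf_dominant_window())
    assert m.time_valid and m.freq_valid
    assert m.hf > m.lf
    assert m.lf_hf < 1.0


def test_compute_hrv_gap_rule_blocks_frequency_only():
    chunks = [np.arange(a, a + 30) for a in (0, 60, 120, 180, 240)]
    w = make_window(np.concatenate(chunks), 800 + np.zeros(150))
    m = compute_hrv(w)
    assert m.time_valid and not m.freq_valid
    assert m.median_ibi == 800.0 and m.lf is None and m.hf is None


def test_compute_hrv_never_raises_on_tiny_window():
    m = compute_hrv(make_window([1.0], [800.0]))
    assert not m.time_valid and not m.freq_valid
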