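"""Per-window HRV metrics.

Six metrics per 5-minute window:

* time domain — median IBI, STDRR (SD of the IBI values) and RMSDRR
  (root-mean-square of successive IBI differences), computed on every beat
  in the window;
* frequency domain — LF power (0.04–0.15 Hz), HF power (0.15–1.0 Hz) and
  their ratio.  The beat series is resampled to a uniform 5 Hz grid with a
  shape-preserving piecewise-cubic Hermite interpolant (PCHIP), band-pass
  filtered (zero-phase order-4 Butterworth), tiled into non-overlapping
  sub-windows of 60 s (LF) or 30 s (HF), and each sub-window scored as
  ``ln(variance)`` of the filtered values (population variance, ms²).
  Sub-window scores below 2.5 or above 9.0 are censored; the window's band
  power is the median of the survivors.

The HF upper bound of 1.0 Hz (rather than the conventional 0.40 Hz) keeps
respiratory-coupled variability in band during physical activity, when
breathing and heart rates both rise.

Frequency-domain metrics are computed on the longest continuous segment of
the window whenever any >15 s gap is present (see :mod:`hrvgaps.windows`);
time-domain metrics always use all beats in the window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import PchipInterpolator

from .windows import DEFAULT_GAP_THRESHOLD_S, Window5, find_gaps

LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 1.0)
RESAMPLE_HZ = 5.0
SUBWINDOW_S = {"LF": 60.0, "HF": 30.0}
CENSOR_BOUNDS = (2.5, 9.0)
#: Minimum usable-segment duration: one full LF sub-window.
MIN_SEGMENT_S = 60.0
MIN_SEGMENT_SAMPLES = 4


@dataclass
class ResampledSignal:
    """A uniformly sampled IBI signal covering one usable segment."""

    start: int          # epoch ms of the first grid point
    rate: float         # Hz
    values: np.ndarray  # ms

    @property
    def duration_s(self) -> float:
        return (self.values.size - 1) / self.rate


@dataclass
class HRVMetrics:
    """The six per-window HRV outputs plus validity flags.

    ``lf``/``hf`` are ln of band-limited variance (variance in ms²);
    ``lf_hf`` is their ratio.  A flag is False when the corresponding
    metrics could not be computed (too few beats, too many gaps, or all
    sub-window scores censored).
    """

    median_ibi: float | None = None
    stdrr: float | None = None
    rmsdrr: float | None = None
    lf: float | None = None
    hf: float | None = None
    lf_hf: float | None = None
    time_valid: bool = False
    freq_valid: bool = False


def time_domain(window: Window5) -> tuple[float | None, float | None, float | None]:
    """Median IBI, STDRR and RMSDRR over all beats in the window.

    Needs at least 2 beats; otherwise all three are None.
    """
    x = window.ibi
    if x.size < 2:
        return None, None, None
    d = np.diff(x)
    return (float(np.median(x)),
            float(np.std(x, ddof=1)),
            float(np.sqrt(np.mean(d * d))))


def resample_pchip(window: Window5, rate: float = RESAMPLE_HZ,
                   gap_threshold: float = DEFAULT_GAP_THRESHOLD_S
                   ) -> ResampledSignal | None:
    """Resample the usable segment of a window onto a uniform grid.

    PCHIP is shape preserving: it reproduces the beat values exactly at the
    beat times and never overshoots between them.  The grid runs from the
    first to the last beat of the usable segment (no extrapolation).
    Returns None when the window is unusable or the segment is shorter than
    60 s or has fewer than 4 beats.
    """
    if window.usable is None:
        find_gaps(window, gap_threshold)
    if not window.usable or window.usable_segment is None:
        return None
    seg_start, seg_end = window.usable_segment
    m = (window.timestamps >= seg_start) & (window.timestamps <= seg_end)
    t, x = window.timestamps[m], window.ibi[m]
    if t.size < MIN_SEGMENT_SAMPLES or (t[-1] - t[0]) < MIN_SEGMENT_S * 1000.0:
        return None
    interp = PchipInterpolator(t.astype(float), x)
    n = int(math.floor((t[-1] - t[0]) / 1000.0 * rate)) + 1
    grid = t[0] + np.arange(n) * (1000.0 / rate)
    return ResampledSignal(start=int(t[0]), rate=rate, values=interp(grid))


def band_filter(sig: ResampledSignal, band: str) -> ResampledSignal:
    """Zero-phase band-pass ("LF" or "HF") of a resampled signal.

    The mean is removed first; an order-4 Butterworth band-pass is applied
    forward and backward (zero phase), so sub-window positions stay aligned
    with the original timeline.  Output has the same length as the input.
    """
    lo, hi = LF_BAND if band == "LF" else HF_BAND
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=sig.rate, output="sos")
    x = sig.values - sig.values.mean()
    y = sps.sosfiltfilt(sos, x)
    return ResampledSignal(start=sig.start, rate=sig.rate, values=y)


def subwindow_ln_variances(filtered: ResampledSignal, band: str) -> list[float]:
    """ln(population variance) per full sub-window (60 s for LF, 30 s for HF).

    The filtered signal is tiled into consecutive non-overlapping
    sub-windows; a trailing partial sub-window is discarded.  A zero-variance
    sub-window scores ``-inf`` (censored downstream in any case).
    """
    n_sub = int(round(SUBWINDOW_S[band] * filtered.rate))
    out = []
    for k in range(filtered.values.size // n_sub):
        chunk = filtered.values[k * n_sub:(k + 1) * n_sub]
        v = float(np.var(chunk))
        out.append(math.log(v) if v > 0 else -math.inf)
    return out


def censored_median(values: list[float],
                    bounds: tuple[float, float] = CENSOR_BOUNDS) -> float | None:
    """Median of the values inside ``[low, high]``; None when none survive."""
    lo, hi = bounds
    kept = [v for v in values if lo <= v <= hi]
    return float(np.median(kept)) if kept else None


def band_power(filtered: ResampledSignal, band: str,
               bounds: tuple[float, float] = CENSOR_BOUNDS) -> float | None:
    """Censored-median ln-variance band power of one window's filtered signal."""
    return censored_median(subwindow_ln_variances(filtered, band), bounds)


def compute_hrv(window: Window5, *,
                gap_threshold: float = DEFAULT_GAP_THRESHOLD_S,
                rate: float = RESAMPLE_HZ,
                censor_bounds: tuple[float, float] = CENSOR_BOUNDS) -> HRVMetrics:
    """All six metrics for one window, with failures reported as flags.

    Never raises on degenerate windows, so cohort runs complete: a window
    failing the gap rule still gets time-domain metrics with
    ``freq_valid=False``.
    """
    out = HRVMetrics()
    med, sd, rms = time_domain(window)
    if med is not None:
        out.median_ibi, out.stdrr, out.rmsdrr = med, sd, rms
        out.time_valid = True
    sig = resample_pchip(window, rate, gap_threshold)
    if sig is not None:
        out.lf = band_power(band_filter(sig, "LF"), "LF", censor_bounds)
        out.hf = band_power(band_filter(sig, "HF"), "HF", censor_bounds)
        if out.lf is not None and out.hf is not None:
            out.freq_valid = True
            if out.hf != 0:
                out.lf_hf = out.lf / out.hf
    return out


METRIC_COLUMNS = ["median_ibi", "stdrr", "rmsdrr", "lf", "hf", "lf_hf"]


def metrics_table(windows: list[Window5], participant_id: str, **kwargs) -> pd.DataFrame:
    """Per-window metric table for one participant/device stream."""
    rows = []
    for w in windows:
        m = compute_hrv(w, **kwargs)
        rows.append({"participant_id": participant_id,
                     "window_start_ms": w.start,
                     "activity": w.activity,
                     "n_points": w.n_points,
                     "median_ibi": m.median_ibi, "stdrr": m.stdrr,
                     "rmsdrr": m.rmsdrr, "lf": m.lf, "hf": m.hf,
                     "lf_hf": m.lf_hf,
                     "freq_valid": m.freq_valid, "time_valid": m.time_valid})
    return pd.DataFrame(rows)
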