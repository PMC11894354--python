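"""Wall-clock 5-minute windowing, wear-compliance QC, gap detection, activity class.

Windows are aligned to real time: each window starts at a 5-minute mark
(12:00, 12:05, ...), i.e. at an epoch-ms multiple of 300,000.  The expected
number of IBI points per window is fixed at 300 (a nominal 60 beats/min), so
the expected-data-fraction QC statistic is ``n_points / 300`` capped at 1 —
faster heart rates can exceed the nominal count.

A *gap* is a between-beat silence longer than a threshold (default 15 s).
Leading and trailing silences (window edge to first/last beat) count too, so
a burst of missing data at the start of a window is detected.  Windows with
more than 3 gaps are unusable for frequency-domain analysis; with 1–3 gaps,
only the longest continuous segment is analysed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import IBISeries, StepSeries, ValidationError

WINDOW_MS = 300_000
EXPECTED_POINTS = 300          # 60 beats/min x 5 min
DEFAULT_GAP_THRESHOLD_S = 15.0
DEFAULT_INCLUSION_PCT = 70.0

REST, LIGHT, HIGH, UNKNOWN = "rest", "light", "high", "unknown"


@dataclass
class Window5:
    """A wall-clock-aligned 5-minute slice of one IBI stream.

    ``start`` is an epoch-ms multiple of 300,000; every sample timestamp
    lies in ``[start, start + 300,000)``.  QC annotations (``gaps``,
    ``usable_segment``, ``usable``, ``activity``) are filled in by
    :func:`find_gaps` and :func:`classify_activity`.
    """

    start: int
    timestamps: np.ndarray
    ibi: np.ndarray
    gaps: list[tuple[int, int]] = field(default_factory=list)
    usable_segment: tuple[int, int] | None = None
    usable: bool | None = None
    activity: str = UNKNOWN
    mean_steps: float | None = None

    @property
    def n_points(self) -> int:
        return int(self.timestamps.size)

    @property
    def expected_fraction(self) -> float:
        """Observed / nominal point count, in [0, 1]."""
        return min(1.0, self.n_points / EXPECTED_POINTS)

    @property
    def end(self) -> int:
        return self.start + WINDOW_MS


@dataclass
class QCReport:
    """Participant-level wear-compliance summary."""

    participant_id: str
    total_windows: int
    usable_windows: int
    participant_expected_fraction: float  # percent
    included: bool


def segment_windows(series: IBISeries) -> list[Window5]:
    """Partition a (filtered) IBI series into wall-clock 5-minute windows.

    Each sample goes to the window ``floor(timestamp / 300,000)``; windows
    with no samples are not emitted, so the partition over samples is
    exhaustive and disjoint.
    """
    if len(series) == 0:
        return []
    slot = series.timestamps // WINDOW_MS
    out: list[Window5] = []
    for s in np.unique(slot):
        m = slot == s
        out.append(Window5(start=int(s) * WINDOW_MS,
                           timestamps=series.timestamps[m],
                           ibi=series.ibi[m]))
    return out


def expected_data_fraction(window: Window5) -> float:
    """Expected-data fraction of one window, as a percentage in [0, 100]."""
    return 100.0 * window.expected_fraction


def participant_inclusion(windows: list[Window5], *,
                          participant_id: str = "",
                          threshold: float = DEFAULT_INCLUSION_PCT) -> QCReport:
    """Decide whether a participant's stream is complete enough to analyse.

    The participant-level expected-data fraction is the total observed point
    count over the monitoring span divided by ``300 x (number of 5-minute
    slots in the span)``, *including slots with no data at all* — non-wear
    lowers the fraction.  Inclusion requires the fraction (as a percent) to
    reach ``threshold`` (default 70).
    """
    if not windows:
        raise ValidationError("participant_inclusion: empty window list")
    starts = np.array([w.start for w in windows])
    n_slots = int((starts.max() - starts.min()) // WINDOW_MS) + 1
    total_points = int(sum(w.n_points for w in windows))
    frac = min(100.0, 100.0 * total_points / (EXPECTED_POINTS * n_slots))
    usable = sum(1 for w in windows if w.usable) if any(
        w.usable is not None for w in windows) else len(windows)
    return QCReport(participant_id=participant_id,
                    total_windows=len(windows),
                    usable_windows=usable,
                    participant_expected_fraction=frac,
                    included=frac >= threshold)


def find_gaps(window: Window5,
              gap_threshold: float = DEFAULT_GAP_THRESHOLD_S
              ) -> tuple[list[tuple[int, int]], tuple[int, int] | None, bool]:
    """Locate >threshold gaps and the longest continuous segment.

    A gap is a silence strictly longer than ``gap_threshold`` seconds,
    either between consecutive beats or between a window edge and the
    first/last beat.  Returns ``(gaps, usable_segment, usable)`` and
    annotates the window in place.  ``usable`` is False when the window has
    fewer than 2 samples or more than 3 gaps.  The usable segment is the
    longest run of beats between gaps (earlier run wins ties); when any gap
    is present, frequency-domain metrics must be computed on it alone.
    """
    thr_ms = gap_threshold * 1000.0
    if window.n_points < 2:
        window.gaps, window.usable_segment, window.usable = [], None, False
        return [], None, False

    t = window.timestamps
    gaps: list[tuple[int, int]] = []
    # boundaries between segments: indices i such that a gap separates i-1 and i
    cut_points: list[int] = []
    if t[0] - window.start > thr_ms:
        gaps.append((window.start, int(t[0])))
    dt = np.diff(t)
    for i in np.nonzero(dt > thr_ms)[0]:
        gaps.append((int(t[i]), int(t[i + 1])))
        cut_points.append(int(i) + 1)
    if window.end - t[-1] > thr_ms:
        gaps.append((int(t[-1]), window.end))

    if len(gaps) > 3:
        window.gaps, window.usable_segment, window.usable = gaps, None, False
        return gaps, None, False

    # longest run of samples between interior gaps, measured first-to-last beat
    bounds = [0, *cut_points, int(t.size)]
    best: tuple[int, int] | None = None
    best_len = -1
    for a, b in zip(bounds[:-1], bounds[1:]):
        span = int(t[b - 1] - t[a])
        if span > best_len:
            best_len, best = span, (int(t[a]), int(t[b - 1]))
    window.gaps, window.usable_segment, window.usable = gaps, best, True
    return gaps, best, True


def classify_activity(window: Window5, steps: StepSeries) -> tuple[str, float | None]:
    """Attach an activity class from the step minutes overlapping the window.

    At least 2 step records with ``minute_start`` inside the window are
    required; otherwise the class is ``unknown``.  The class is ``rest``
    when the mean steps/min is exactly 0, ``light`` when 0 < mean < 100 and
    ``high`` when the mean is >= 100.
    """
    m = (steps.minute_start >= window.start) & (steps.minute_start < window.end)
    if int(m.sum()) < 2:
        window.activity, window.mean_steps = UNKNOWN, None
        return UNKNOWN, None
    mean_steps = float(steps.steps[m].mean())
    if mean_steps == 0:
        cls = REST
    elif mean_steps < 100:
        cls = LIGHT
    else:
        cls = HIGH
    window.activity, window.mean_steps = cls, mean_steps
    return cls, mean_steps
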