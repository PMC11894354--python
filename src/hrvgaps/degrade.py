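"""Semisimulated missing-data injection for 5-minute IBI windows.

Rather than deleting beats at random, degradation reuses missingness
patterns observed in genuinely sparse wearable recordings ("semisimulation"):

* 60 % level — one burst: the first 3.15 min of the window missing
  (non-wear-like);
* 35 % level — one burst: minutes 1.00–2.75 missing;
* 20 % level — 0.80 min missing, scattered through the window in 1–2 s
  dropouts (motion-artifact-like);
* 10 % level — 0.63 min missing, scattered the same way.

Levels are *nominal*: patterns are defined by their removed duration, not
by deleting an exact share of beats (the 60 % burst covers 63 % of the
window).  One pattern instance per level is reused across every window, so
all windows of a degraded dataset share the same missingness geometry;
per-window re-randomised scatter is available as a sensitivity option.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .io import ValidationError
from .windows import WINDOW_MS, Window5

WINDOW_S = WINDOW_MS / 1000.0
LEVELS = (10, 20, 35, 60)
#: Removed duration per nominal level, seconds.
LEVEL_TOTAL_S = {60: 189.0, 35: 105.0, 20: 48.0, 10: 37.8}
BURST_INTERVALS = {60: (0.0, 189.0), 35: (60.0, 165.0)}
SCATTER_GAP_RANGE_S = (1.0, 2.0)


@dataclass
class GapPattern:
    """Within-window missingness: a list of gap intervals at a nominal level.

    Gap offsets are seconds from the window start, non-overlapping, inside
    ``[0, 300]``.  ``kind`` is ``burst`` (one long hole) or ``scatter``
    (many 1–2 s dropouts).
    """

    level: int
    gaps: list[tuple[float, float]]
    kind: str

    @property
    def total_gap_seconds(self) -> float:
        return float(sum(b - a for a, b in self.gaps))

    def to_json(self) -> str:
        return json.dumps({"level": self.level, "kind": self.kind,
                           "gaps": [[a, b] for a, b in self.gaps]})

    @classmethod
    def from_json(cls, s: str) -> "GapPattern":
        d = json.loads(s)
        return cls(level=d["level"], kind=d["kind"],
                   gaps=[(a, b) for a, b in d["gaps"]])


@dataclass
class DegradedWindow:
    """A window after pattern application, with its realised missingness."""

    window: Window5
    source: Window5
    level: int
    achieved_missingness: float  # fraction of source beats removed


def _scatter_lengths(rng: np.random.Generator, total_s: float) -> list[float]:
    """Gap lengths in [1, 2] s summing exactly to ``total_s``.

    Lengths are drawn U[1, 2] until at most 3 s of budget remains; the
    remainder closes as one gap (if <= 2 s) or two equal gaps, keeping
    every length inside [1, 2] and the total exact.
    """
    lo, hi = SCATTER_GAP_RANGE_S
    rem = total_s
    lengths: list[float] = []
    while rem > hi + lo:
        length = float(rng.uniform(lo, hi))
        lengths.append(length)
        rem -= length
    if rem > hi:
        lengths.extend([rem / 2.0, rem / 2.0])
    else:
        lengths.append(rem)
    return lengths


def _place_scatter(rng: np.random.Generator, lengths: list[float]) -> list[tuple[float, float]]:
    """Place gap lengths at uniform random offsets, rejecting overlaps."""
    placed: list[tuple[float, float]] = []
    for length in lengths:
        for _ in range(10_000):
            a = float(rng.uniform(0.0, WINDOW_S - length))
            b = a + length
            if all(b <= s or a >= e for s, e in placed):
                placed.append((a, b))
                break
        else:  # pragma: no cover - cannot trigger at these densities
            raise RuntimeError("could not place scatter gaps without overlap")
    return sorted(placed)


def scatter_pattern(level: int, seed: int) -> GapPattern:
    """A seeded scatter pattern (1–2 s gaps) at a 10 % or 20 % nominal level."""
    if level not in (10, 20):
        raise ValidationError("scatter patterns exist for levels 10 and 20 only")
    rng = np.random.default_rng(np.random.SeedSequence([seed, level]))
    gaps = _place_scatter(rng, _scatter_lengths(rng, LEVEL_TOTAL_S[level]))
    return GapPattern(level=level, gaps=gaps, kind="scatter")


def builtin_patterns(seed: int = 0) -> list[GapPattern]:
    """The four built-in patterns (levels 10, 20, 35, 60).

    Burst levels are fixed intervals; scatter levels are deterministic
    under ``seed``.
    """
    out = [scatter_pattern(10, seed), scatter_pattern(20, seed)]
    for level in (35, 60):
        out.append(GapPattern(level=level, gaps=[BURST_INTERVALS[level]], kind="burst"))
    return out


def pattern_for_level(level: int, seed: int = 0) -> GapPattern:
    if level not in LEVELS:
        raise ValidationError(f"unknown level {level}; valid levels are {LEVELS}")
    for p in builtin_patterns(seed):
        if p.level == level:
            return p
    raise AssertionError  # pragma: no cover


def apply_pattern(window: Window5, pattern: GapPattern) -> DegradedWindow:
    """Remove the beats a gap pattern covers; all others survive unchanged.

    A beat is removed when its offset from the window start falls in
    ``[gap_start, gap_end)``.  Pure filter: surviving timestamps/values are
    bit-identical to the source.
    """
    off = (window.timestamps - window.start) / 1000.0
    keep = np.ones(off.size, dtype=bool)
    for a, b in pattern.gaps:
        keep &= ~((off >= a) & (off < b))
    degraded = Window5(start=window.start,
                       timestamps=window.timestamps[keep],
                       ibi=window.ibi[keep],
                       activity=window.activity,
                       mean_steps=window.mean_steps)
    missing = 1.0 - (int(keep.sum()) / window.n_points) if window.n_points else 0.0
    return DegradedWindow(window=degraded, source=window,
                          level=pattern.level, achieved_missingness=missing)


def degrade_dataset(windows: list[Window5], level: int, seed: int = 0,
                    rerandomize_scatter: bool = False) -> list[DegradedWindow]:
    """Apply one level's pattern to every window.

    By default one pattern instance is shared across all windows (the
    matching procedure of the semisimulation design);
    ``rerandomize_scatter=True`` redraws scatter placement per window for
    sensitivity analyses.
    """
    if level not in LEVELS:
        raise ValidationError(f"unknown level {level}; valid levels are {LEVELS}")
    out = []
    pattern = pattern_for_level(level, seed)
    for i, w in enumerate(windows):
        if rerandomize_scatter and pattern.kind == "scatter":
            pattern_i = scatter_pattern(level, seed + 1 + i)
            out.append(apply_pattern(w, pattern_i))
        else:
            out.append(apply_pattern(w, pattern))
    return out
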