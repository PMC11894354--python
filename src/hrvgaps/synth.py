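"""Synthetic paired wrist-PPG / chest-ECG interbeat-interval cohorts.

The generator emits beat-by-beat IBI streams with known ground truth so
every downstream stage (windowing, HRV metrics, degradation, statistics)
can be tested without access to real wearable data.  The beat process is
iterative: the next beat time is the previous beat time plus the current
instantaneous IBI,

    ibi(t) = base(t) + A_LF sin(2 pi f_LF t) + A_HF sin(2 pi f_HF t) + eps,

with ``base(t)`` switching between a resting and an active mean IBI (30-s
linear ramps at activity-block edges, so the switch itself injects no
spurious high-frequency power), sinusoidal low-frequency (~0.1 Hz,
baroreflex-like) and high-frequency (~0.25 Hz, respiratory-like)
components, and white beat-level noise ``eps``.

Occasional artifact beats (values outside the 300–1500 ms physiologic
band) model detection failures.  The PPG stream shares the ECG beat
process exactly and differs only by additive measurement noise and a fixed
bias, so between-device agreement has a known structure.  Wear-compliance
gaps are imposed by dropping beats outside the configured wear schedule.

Default means (rest 889 ms, light activity 691 ms) sit near levels typical
of free-living adult smartwatch cohorts; amplitudes are set so band-limited
ln-variance lands in the 5–6.5 range seen in such data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .io import IBISeries, StepSeries, ValidationError, write_ibi, write_steps
from .windows import WINDOW_MS, REST, LIGHT, HIGH

MS_PER_DAY = 86_400_000
_DEVICE_CODE = {"beats": 0, "artifact": 1, "ppg": 2, "ecg": 3}
#: Artifact values are drawn uniformly from these two ranges (ms), so both
#: the low and the high artifact-filter bound get exercised.
ARTIFACT_RANGES = ((100.0, 300.0), (1500.0, 3000.0))
TRANSITION_S = 30.0


@dataclass
class SyntheticConfig:
    """Cohort-level generator settings.

    Times in ``wear_schedule`` and ``activity_blocks`` are epoch
    milliseconds; simulation time runs from 0 to ``duration_days`` days.
    An empty ``wear_schedule`` means the device is always worn.
    """

    participant_count: int = 16
    duration_days: float = 14.0
    mean_ibi_rest: float = 889.0
    mean_ibi_active: float = 691.0
    lf_freq: float = 0.10       # Hz
    lf_amp: float = 25.0        # ms
    hf_freq: float = 0.25       # Hz
    hf_amp: float = 20.0        # ms
    beat_noise_sd: float = 10.0  # ms
    artifact_rate: float = 0.005  # probability per beat
    device_noise_sd_ppg: float = 10.0  # ms
    ppg_bias: float = 5.0       # ms
    wear_schedule: list[tuple[int, int]] = field(default_factory=list)
    activity_blocks: list[tuple[int, int, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        scalars = [self.duration_days, self.mean_ibi_rest, self.mean_ibi_active,
                   self.lf_freq, self.lf_amp, self.hf_freq, self.hf_amp,
                   self.beat_noise_sd, self.artifact_rate,
                   self.device_noise_sd_ppg, self.ppg_bias]
        if not all(math.isfinite(v) for v in scalars):
            raise ValidationError("SyntheticConfig: all numeric fields must be finite")
        if self.participant_count < 1:
            raise ValidationError("participant_count must be >= 1")
        if not (0.04 <= self.lf_freq < 0.15):
            raise ValidationError("lf_freq must lie in [0.04, 0.15)")
        if not (0.15 <= self.hf_freq <= 1.0):
            raise ValidationError("hf_freq must lie in [0.15, 1.0]")
        if min(self.lf_amp, self.hf_amp, self.beat_noise_sd,
               self.device_noise_sd_ppg) < 0:
            raise ValidationError("amplitudes and noise SDs must be >= 0")
        if not (0 <= self.artifact_rate <= 1):
            raise ValidationError("artifact_rate must lie in [0, 1]")
        for m in (self.mean_ibi_rest, self.mean_ibi_active):
            if not (300 < m < 1500):
                raise ValidationError("mean IBIs must lie in (300, 1500) ms")

    @property
    def duration_ms(self) -> int:
        return int(round(self.duration_days * MS_PER_DAY))


@dataclass
class GroundTruth:
    """Per-window truth record: what the generator actually put in."""

    window_start: int
    true_mean_ibi: float          # mean of base(t) over the window, ms
    lf_power_proxy: float | None  # ln(A_LF^2 / 2), the tone's ln-variance
    hf_power_proxy: float | None
    activity: str


def _rng(config: SyntheticConfig, participant_index: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([config.seed, participant_index, _DEVICE_CODE[stream]]))


def _base_ibi(config: SyntheticConfig, t_ms: float) -> float:
    """Baseline IBI at time t, with 30-s linear ramps around activity blocks."""
    rest, active = config.mean_ibi_rest, config.mean_ibi_active
    tr = TRANSITION_S * 1000.0
    for start, end, steps in config.activity_blocks:
        if steps <= 0:
            continue
        if start <= t_ms < end:
            lead = min(1.0, (t_ms - start) / tr)
            tail = min(1.0, (end - t_ms) / tr)
            return rest + (active - rest) * min(lead, tail)
    return rest


def _in_intervals(t_ms: float, intervals: list[tuple[int, int]]) -> bool:
    return any(a <= t_ms < b for a, b in intervals)


def generate_ibi_series(config: SyntheticConfig, participant_index: int,
                        device: str) -> IBISeries:
    """One participant's IBI stream for one device.

    Deterministic under ``(config.seed, participant_index, device)``; the
    underlying beat process (times, clean values, artifact positions) is
    shared between the two devices of the same participant, so paired
    streams differ only by PPG measurement noise and bias.
    """
    if device not in ("ppg", "ecg"):
        raise ValidationError(f"device must be 'ppg' or 'ecg', got {device!r}")
    rng_beat = _rng(config, participant_index, "beats")
    rng_art = _rng(config, participant_index, "artifact")
    rng_dev = _rng(config, participant_index, device)

    total = config.duration_ms
    two_pi = 2.0 * math.pi
    times: list[int] = []
    values: list[float] = []
    t = 0.0
    while t < total:
        ts = t / 1000.0
        ibi = (_base_ibi(config, t)
               + config.lf_amp * math.sin(two_pi * config.lf_freq * ts)
               + config.hf_amp * math.sin(two_pi * config.hf_freq * ts))
        if config.beat_noise_sd > 0:
            ibi += rng_beat.normal(0.0, config.beat_noise_sd)
        t_beat = t + ibi
        value = ibi
        # artifact stream is shared between devices: both consume the same
        # seeded draws beat for beat, so artifact positions always pair up
        if rng_art.uniform() < config.artifact_rate:
            lo, hi = ARTIFACT_RANGES[int(rng_art.integers(2))]
            value = rng_art.uniform(lo, hi)
        if device == "ppg":
            value += config.ppg_bias
            if config.device_noise_sd_ppg > 0:
                value += rng_dev.normal(0.0, config.device_noise_sd_ppg)
        if t_beat >= total:
            break
        if not config.wear_schedule or _in_intervals(t_beat, config.wear_schedule):
            times.append(int(round(t_beat)))
            values.append(value)
        t = t_beat
    return IBISeries(participant_id=f"P{participant_index:02d}", device=device,
                     timestamps=np.array(times, dtype=np.int64),
                     ibi=np.array(values, dtype=float))


def generate_steps(config: SyntheticConfig, participant_index: int) -> StepSeries:
    """Per-minute step counts: 0 at rest, the block rate during activity.

    Minutes whose start falls outside the wear schedule are absent.
    """
    minutes = np.arange(0, config.duration_ms, 60_000, dtype=np.int64)
    out_t: list[int] = []
    out_s: list[int] = []
    for m in minutes:
        if config.wear_schedule and not _in_intervals(float(m), config.wear_schedule):
            continue
        steps = 0
        for start, end, rate in config.activity_blocks:
            if start <= m < end:
                steps = int(rate)
                break
        out_t.append(int(m))
        out_s.append(steps)
    return StepSeries(participant_id=f"P{participant_index:02d}",
                      minute_start=np.array(out_t, dtype=np.int64),
                      steps=np.array(out_s, dtype=np.int64))


def _window_truth(config: SyntheticConfig, start: int) -> GroundTruth:
    grid = start + np.arange(0, WINDOW_MS, 1000, dtype=float)
    base = np.array([_base_ibi(config, g) for g in grid])
    steps = [rate for s, e, rate in config.activity_blocks
             for m in range(start, start + WINDOW_MS, 60_000) if s <= m < e]
    mean_steps = float(np.mean(steps)) if steps else 0.0
    if mean_steps == 0:
        act = REST
    elif mean_steps < 100:
        act = LIGHT
    else:
        act = HIGH
    return GroundTruth(
        window_start=start,
        true_mean_ibi=float(base.mean()),
        lf_power_proxy=math.log(config.lf_amp ** 2 / 2) if config.lf_amp > 0 else None,
        hf_power_proxy=math.log(config.hf_amp ** 2 / 2) if config.hf_amp > 0 else None,
        activity=act)


@dataclass
class ParticipantData:
    """Paired streams plus truth for one synthetic participant."""

    participant_id: str
    ppg: IBISeries
    ecg: IBISeries
    steps: StepSeries
    truth: list[GroundTruth]


def generate_cohort(config: SyntheticConfig) -> list[ParticipantData]:
    """Paired PPG/ECG streams, steps and per-window ground truth for a cohort."""
    cohort = []
    for i in range(config.participant_count):
        ppg = generate_ibi_series(config, i, "ppg")
        ecg = generate_ibi_series(config, i, "ecg")
        steps = generate_steps(config, i)
        worn_windows = sorted({int(t // WINDOW_MS) * WINDOW_MS for t in ecg.timestamps})
        truth = [_window_truth(config, s) for s in worn_windows]
        cohort.append(ParticipantData(participant_id=f"P{i:02d}", ppg=ppg,
                                      ecg=ecg, steps=steps, truth=truth))
    return cohort


def write_cohort(cohort: list[ParticipantData], out_dir: str | Path,
                 config: SyntheticConfig | None = None) -> Path:
    """Write per-participant CSVs and a JSON manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"participants": []}
    if config is not None:
        manifest["config"] = asdict(config)
    for p in cohort:
        files = {
            "ppg": f"{p.participant_id}_ppg_ibi.csv",
            "ecg": f"{p.participant_id}_ecg_ibi.csv",
            "steps": f"{p.participant_id}_steps.csv",
        }
        write_ibi(p.ppg, out / files["ppg"])
        write_ibi(p.ecg, out / files["ecg"])
        write_steps(p.steps, out / files["steps"])
        manifest["participants"].append({"id": p.participant_id, **files})
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out
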