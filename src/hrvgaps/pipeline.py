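"""End-to-end pipeline: synthesise -> ingest -> QC -> metrics -> degrade -> analyse.

A :class:`RunConfig` gathers every tunable constant of the analysis (QC
threshold, gap threshold, band edges, censoring bounds, degradation
levels, seeds, bootstrap reps) so sensitivity analyses need no code
edits.  :func:`run_pipeline` writes each stage's output as CSV under a run
directory together with a JSON manifest (config hash, seed, version);
re-running with the same config reproduces identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .degrade import LEVELS, degrade_dataset
from .io import IBISeries, StepSeries, ValidationError, filter_artifacts, read_ibi, read_steps
from .metrics import CENSOR_BOUNDS, METRIC_COLUMNS, metrics_table
from .stats import agreement_summary, align_devices, fit_missingness_contrasts
from .synth import SyntheticConfig, generate_cohort, write_cohort
from .windows import (DEFAULT_GAP_THRESHOLD_S, DEFAULT_INCLUSION_PCT,
                      classify_activity, find_gaps, participant_inclusion,
                      segment_windows)

logger = logging.getLogger("hrvgaps")


@dataclass
class RunConfig:
    """All pipeline constants in one place.

    Defaults are the analysis constants of the method: 70 % inclusion
    threshold, 15-s gap rule, LF 0.04–0.15 Hz / HF 0.15–1.0 Hz bands,
    ln-variance censoring at 2.5/9.0, degradation levels 10/20/35/60 and
    1000 bootstrap replicates.
    """

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    qc_threshold_pct: float = DEFAULT_INCLUSION_PCT
    gap_threshold_s: float = DEFAULT_GAP_THRESHOLD_S
    censor_bounds: tuple[float, float] = CENSOR_BOUNDS
    levels: tuple[int, ...] = LEVELS
    n_boot: int = 1000
    seed: int = 0
    contrast_metrics: tuple[str, ...] = ("median_ibi", "stdrr", "rmsdrr",
                                         "lf", "hf", "lf_hf")

    def __post_init__(self) -> None:
        bad = [l for l in self.levels if l not in LEVELS]
        if bad:
            raise ValidationError(f"unknown degradation level(s) {bad}; valid: {LEVELS}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        synth_raw = raw.pop("synthetic", {})
        for key in ("wear_schedule",):
            if key in synth_raw:
                synth_raw[key] = [tuple(x) for x in synth_raw[key]]
        if "activity_blocks" in synth_raw:
            synth_raw["activity_blocks"] = [tuple(x) for x in synth_raw["activity_blocks"]]
        cfg = cls(synthetic=SyntheticConfig(**synth_raw))
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ValidationError(f"unknown config key {k!r}")
            setattr(cfg, k, tuple(v) if isinstance(v, list) else v)
        cfg.__post_init__()
        return cfg

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def prepare_windows(ibi: IBISeries, steps: StepSeries | None,
                    gap_threshold_s: float = DEFAULT_GAP_THRESHOLD_S):
    """Filter artifacts, window, run gap QC and classify activity."""
    filtered, n_removed = filter_artifacts(ibi)
    windows = segment_windows(filtered)
    for w in windows:
        find_gaps(w, gap_threshold_s)
        if steps is not None:
            classify_activity(w, steps)
    return windows, n_removed


def qc_table(participants: list[tuple[str, list]], threshold: float) -> pd.DataFrame:
    rows = []
    for pid, windows in participants:
        rep = participant_inclusion(windows, participant_id=pid, threshold=threshold)
        rows.append({"participant_id": pid,
                     "total_windows": rep.total_windows,
                     "usable_windows": rep.usable_windows,
                     "expected_fraction_pct": rep.participant_expected_fraction,
                     "included": rep.included})
    return pd.DataFrame(rows)


def long_metric_table(reference: pd.DataFrame,
                      degraded: dict[int, pd.DataFrame],
                      metrics: tuple[str, ...] = tuple(METRIC_COLUMNS)) -> pd.DataFrame:
    """Stack reference + degraded per-window metric tables into long form."""
    frames = []
    for label, df in [("ref", reference)] + [(str(k), v) for k, v in degraded.items()]:
        melted = df.melt(id_vars=["participant_id", "window_start_ms", "activity"],
                         value_vars=[m for m in metrics if m in df.columns],
                         var_name="metric", value_name="value")
        melted["level"] = label
        frames.append(melted)
    out = pd.concat(frames, ignore_index=True)
    return out.rename(columns={"window_start_ms": "window_start"})


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run every stage on a synthetic cohort and write all outputs.

    Stages: cohort synthesis (written to and re-read from CSV, so the file
    round trip is exercised), artifact filtering + windowing + QC, reference
    HRV metrics per device, degradation at each level, missingness
    contrasts at rest and light activity, and PPG-vs-ECG agreement.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config

    logger.info("stage synth: %d participants, %.2f days",
                cfg.synthetic.participant_count, cfg.synthetic.duration_days)
    cohort = generate_cohort(cfg.synthetic)
    synth_dir = write_cohort(cohort, out / "synth", cfg.synthetic)

    per_device_metrics: dict[str, list[pd.DataFrame]] = {"ppg": [], "ecg": []}
    degraded_frames: dict[int, list[pd.DataFrame]] = {l: [] for l in cfg.levels}
    qc_rows = []
    for p in cohort:
        steps = read_steps(synth_dir / f"{p.participant_id}_steps.csv",
                           participant_id=p.participant_id)
        for device in ("ppg", "ecg"):
            series = read_ibi(synth_dir / f"{p.participant_id}_{device}_ibi.csv",
                              participant_id=p.participant_id, device=device)
            windows, _ = prepare_windows(series, steps, cfg.gap_threshold_s)
            per_device_metrics[device].append(
                metrics_table(windows, p.participant_id,
                              gap_threshold=cfg.gap_threshold_s,
                              censor_bounds=cfg.censor_bounds))
            if device == "ppg":
                qc_rows.append((p.participant_id, windows))
                for level in cfg.levels:
                    deg = degrade_dataset(windows, level, cfg.seed)
                    dw = [d.window for d in deg]
                    for w in dw:
                        find_gaps(w, cfg.gap_threshold_s)
                    degraded_frames[level].append(
                        metrics_table(dw, p.participant_id,
                                      gap_threshold=cfg.gap_threshold_s,
                                      censor_bounds=cfg.censor_bounds))

    qc = qc_table(qc_rows, cfg.qc_threshold_pct)
    qc.to_csv(out / "qc.csv", index=False)

    ref_ppg = pd.concat(per_device_metrics["ppg"], ignore_index=True)
    ref_ecg = pd.concat(per_device_metrics["ecg"], ignore_index=True)
    ref_ppg.to_csv(out / "metrics_reference_ppg.csv", index=False)
    ref_ecg.to_csv(out / "metrics_reference_ecg.csv", index=False)
    degraded = {}
    for level in cfg.levels:
        df = pd.concat(degraded_frames[level], ignore_index=True)
        df.to_csv(out / f"metrics_level{level}.csv", index=False)
        degraded[level] = df

    long = long_metric_table(ref_ppg, degraded, cfg.contrast_metrics)
    long.to_csv(out / "long_metrics.csv", index=False)

    contrast_rows = []
    for activity in ("rest", "light"):
        for metric in cfg.contrast_metrics:
            sub = long[(long["metric"] == metric) & (long["activity"] == activity)]
            if sub.empty or sub["value"].dropna().empty:
                continue
            try:
                results = fit_missingness_contrasts(long, metric, activity,
                                                    n_boot=cfg.n_boot, seed=cfg.seed)
            except ValidationError as exc:
                logger.warning("contrasts skipped for %s/%s: %s", metric, activity, exc)
                continue
            for r in results:
                contrast_rows.append({"activity": activity, "metric": r.metric,
                                      "level": r.level, "estimate": r.estimate,
                                      "se": r.se, "ci_low": r.ci_low,
                                      "ci_high": r.ci_high, "p_value": r.p_value,
                                      "df": r.df, "transform": r.transform})
    pd.DataFrame(contrast_rows).to_csv(out / "contrasts.csv", index=False)

    try:
        paired = align_devices(ref_ppg, ref_ecg)
        agreement = agreement_summary(paired, list(cfg.contrast_metrics))
        agreement.to_csv(out / "agreement.csv", index=False)
    except ValidationError as exc:
        logger.warning("agreement stage skipped: %s", exc)

    manifest = {"config": cfg.to_dict(), "config_digest": cfg.digest(),
                "seed": cfg.seed, "hrvgaps_version": __version__}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
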