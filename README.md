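# hrvgaps

Heart-rate-variability (HRV) metrics from wearable interbeat-interval (IBI)
streams, with controlled injection of realistic missing-data patterns and
the statistics to quantify what missingness does to each metric.

## The problem

Consumer wrist devices report an IBI value (ms) with every detected beat.
Free-living recordings are never complete: non-wear produces long bursts of
missing data, motion artifacts produce scattered 1–2 s dropouts.  Before
HRV from such devices can be used in epidemiological models, two questions
need answers:

1. **Stability** — how much does each HRV metric move when a 5-minute
   window loses 10 / 20 / 35 / 60 % of its beats, in the gap geometries
   that real recordings actually show?
2. **Agreement** — how well do wrist-PPG-derived metrics track a chest ECG
   reference measuring the same heart?

`hrvgaps` implements the full pipeline: ingest → artifact filtering →
wall-clock 5-minute windowing with wear-compliance QC → six HRV metrics →
semisimulated degradation → mixed-model contrasts and ICC/Bland–Altman
agreement.  A synthetic-data generator with known ground truth (band-limited
oscillations, beat noise, artifacts, wear gaps, step-coupled heart-rate
changes) makes every stage testable without access to wearable data.

## The metrics

Per 5-minute window aligned to real time (starts at :00, :05, …):

* **median IBI**, **STDRR** (SD of IBI values), **RMSDRR**
  (root-mean-square of successive IBI differences) — time domain, ms;
* **LF**, **HF**, **LF/HF** — frequency domain.  Beats are resampled to
  5 Hz with shape-preserving PCHIP interpolation, band-passed to
  0.04–0.15 Hz (LF) or 0.15–1.0 Hz (HF), tiled into 60-s (LF) / 30-s (HF)
  sub-windows, and each sub-window scored as `ln(variance)`; scores outside
  [2.5, 9.0] are censored and the window value is the survivors' median.

QC: artifact beats (IBI < 300 or > 1500 ms) are removed; a window with a
> 15 s gap is trimmed to its longest continuous segment, and more than 3
such gaps make it unusable for the frequency domain; participants need
≥ 70 % of the nominal 60 beats/min expected data to be included.

Degradation uses four built-in patterns observed in sparse recordings:
bursts of 3.15 min (60 % level, start of window) and 1.00–2.75 min (35 %),
and scattered 1–2 s dropouts totalling 0.80 min (20 %) and 0.63 min (10 %).

Missingness effects are estimated per metric with a participant
random-intercept linear mixed model (REML), Satterthwaite-approximated
p-values and parametric-bootstrap 95 % CIs; device agreement uses
ICC(2,k) (consistency and absolute agreement), Bland–Altman limits of
agreement and RMSE.

## Worked example

```bash
python examples/04_degradation.py
```

```
level 10% scatter 25 gap(s), 0.63 min removed
level 20% scatter 33 gap(s), 0.80 min removed
level 35% burst    1 gap(s), 1.75 min removed
level 60% burst    1 gap(s), 3.15 min removed

72 reference windows; mean change after degradation:
  10%: dHF -0.143 ln-units, d(median IBI)  +0.03 ms
  20%: dHF -0.180 ln-units, d(median IBI)  +0.34 ms
  35%: dHF -0.005 ln-units, d(median IBI)  -0.17 ms
  60%: dHF -0.003 ln-units, d(median IBI)  -0.61 ms
```

Scattered dropouts bias HF power downward (PCHIP interpolation smooths
high-frequency content across each small hole) while median IBI is nearly
unmoved even when the first 3.15 minutes of every window are deleted —
the burst leaves a clean continuous segment, so the surviving beats are
unbiased.  The other examples cover cohort synthesis (`01`), windowing and
QC (`02`), the metric table (`03`), mixed-model contrasts (`05`) and
device agreement (`06`); each prints a short narrative of what its numbers
mean.

A thin CLI mirrors the stages:

```bash
hrvgaps synth --out cohort/ --seed 7
hrvgaps metrics --ibi cohort/P00_ppg_ibi.csv --steps cohort/P00_steps.csv --out m.csv
hrvgaps run-all --out run/ --seed 7
```

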