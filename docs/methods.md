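# Methods

## Pipeline overview

`hrvgaps` processes timestamped interbeat-interval (IBI) streams from
wrist photoplethysmography (PPG) and chest ECG devices into per-window HRV
metrics, quantifies how controlled missing-data patterns perturb those
metrics, and measures between-device agreement.  All stages operate on
epoch-millisecond UTC timestamps so windows can be aligned to the wall
clock.

## Ingest and artifact filtering

IBI samples arrive as `(timestamp_ms, ibi_ms)` pairs (CSV or JSON), step
counts as one integer per minute.  Rows are sorted by timestamp; duplicate
timestamps keep the first occurrence with a logged warning (a
deterministic, auditable choice for a case the data model leaves open).
Beats with IBI above 1500 ms or below 300 ms are physiologically
implausible for this population and removed.  The bounds are treated as
strict inequalities, so beats at exactly 300 or 1500 ms survive; nothing
in the filter depends on neighbouring beats, which makes it idempotent and
order-preserving.

## Windowing and QC

Windows are 5-minute wall-clock slices (`floor(t / 300 000)`); empty slices
are not materialised.  The expected-data fraction uses a fixed nominal
denominator of 300 points per window (60 beats/min) — a deliberate
simplification that keeps the statistic interpretable across participants;
because faster heart rates can exceed 300 beats per window, the fraction is
capped at 100 %.  The participant-level fraction divides total observed
points by `300 × (number of 5-minute slots spanned)`, counting empty slots,
so non-wear lowers it; participants below 70 % are flagged for exclusion.

A *gap* is a silence strictly longer than 15 s.  Leading and trailing
silences (window edge to first/last beat) count as gaps: the dominant
burst pattern in sparse recordings sits at the start of a window and must
be detected.  With 1–3 gaps, frequency-domain metrics use only the longest
continuous segment (first-to-last-beat span; ties take the earlier
segment, for determinism); more than 3 gaps make the window unusable for
the frequency domain.  Time-domain metrics always use every beat in the
window — the gap rule exists to protect the interpolation step, and the
time-domain statistics need no interpolation.

Activity class comes from the step minutes overlapping the window
(≥ 2 records required, else `unknown`): `rest` at exactly 0 steps/min on
average, `light` below 100, `high` at or above 100.  High-activity windows
are carried through but not analysed by default.

## HRV metrics

Time domain: median IBI, STDRR (sample SD of the window's IBI values) and
RMSDRR (root-mean-square of successive IBI differences).

Frequency domain: the usable segment (minimum 60 s and 4 beats — one full
LF sub-window) is interpolated with `scipy`'s PCHIP (shape-preserving
piecewise-cubic Hermite; exact at the beat times, no overshoot between
them) and evaluated on a uniform 5 Hz grid from the first to the last beat
of the segment, never extrapolating.  The demeaned grid signal is filtered
with a zero-phase order-4 Butterworth band-pass (applied forward and
backward via `sosfiltfilt`) to 0.04–0.15 Hz (LF) or 0.15–1.0 Hz (HF).  The
HF ceiling of 1.0 Hz, rather than the conventional 0.40 Hz, keeps
respiratory-coupled power in band when breathing rates rise with activity.
No specific filter realisation is essential to the method; tests assert
the realised frequency response (pass-band gain within 5 %, stop-band
leakage under 10 % amplitude), not filter coefficients.

The filtered signal is tiled into consecutive non-overlapping sub-windows
of 60 s (LF, 300 samples) or 30 s (HF, 150 samples); a trailing partial
sub-window is discarded.  Each sub-window scores `ln` of the *population*
variance (ms²); scores below 2.5 or above 9.0 are censored (the censoring
bounds only make sense on a natural-log ms² scale, which fixes both
choices), and the window's band power is the median of the survivors — or
absent when none survive, including the zero-variance case, whose
`-inf` score is censored like any sub-2.5 value.  LF/HF is the ratio of
the two median ln-powers rather than a median of per-sub-window ratios;
the two bands use different sub-window lengths, so per-sub-window ratios
are not defined, and the ratio of medians matches the magnitudes such
pipelines report (LF ≈ 6.5, HF ≈ 5.5, LF/HF ≈ 1.2).

A note on sub-window counts: the 5 Hz grid over a segment spanning exactly
T seconds has `5T + 1` points, so a full 300-s gap-free segment yields 5 LF
and 10 HF candidate scores.  Windows are half-open (`[start, start+300 s)`),
so in-pipeline segments are a beat short of 300 s and typically yield 4/9.

## Synthetic cohorts

The generator emits beats iteratively — next beat time = previous beat
time + current IBI — with

    ibi(t) = base(t) + A_LF sin(2π f_LF t) + A_HF sin(2π f_HF t) + ε,

`ε ~ N(0, σ_beat)`.  `base(t)` switches from the resting mean IBI to the
active mean inside each activity block with 30-s linear ramps, so the
transition itself injects no spurious HF power.  With probability
`artifact_rate` the *emitted value* (not the beat-time advance) is replaced
by a uniform draw from [100, 300) ∪ (1500, 3000] ms, exercising both
artifact-filter bounds.  The PPG stream shares the ECG beat process and
artifact positions exactly and adds a fixed bias (+5 ms default) plus
white measurement noise (10 ms default) — enough to give imperfect but
positive ICCs, which is what the agreement machinery needs to be tested
against.  Beats outside the wear schedule are dropped; step minutes are 0
at rest and the block rate during activity.

Defaults describe a free-living adult cohort at desk scale: 16
participants × 14 days, resting mean IBI 889 ms and active 691 ms (typical
smartwatch-cohort levels), LF tone 0.10 Hz / 25 ms, HF tone 0.25 Hz /
20 ms, beat noise 10 ms, artifact rate 0.005/beat.  These amplitudes put
band-limited ln-variances in the 5–6.5 range, comfortably inside the
[2.5, 9.0] censoring corridor.  The generator is a statistical emulator,
not a cardiac model: it has no baroreflex feedback, no circadian drift,
no correlated artifact bursts, and its oscillations are fixed-frequency
tones.  Tests passing on it therefore demonstrate that the *pipeline*
recovers known structure and reacts to missingness as designed — not that
any physiological claim holds in real cohorts.

Determinism: every stream derives from
`SeedSequence([seed, participant_index, stream_code])`, so cohorts are
reproducible per participant and device, and the two devices of one
participant consume identical beat/artifact draws.

## Degradation (semisimulation)

Missingness is injected by deleting the beats that fall inside a
pattern's gap intervals — never by simulating new data.  The four built-in
patterns mirror gap geometries observed in sparse 5-minute windows:

| level | kind    | gaps                                    | removed |
|------:|---------|-----------------------------------------|--------:|
| 60 %  | burst   | `[0, 189 s)` (start of window)          | 3.15 min |
| 35 %  | burst   | `[60 s, 165 s)`                         | 1.75 min |
| 20 %  | scatter | 1–2 s gaps, seeded random placement     | 0.80 min |
| 10 %  | scatter | 1–2 s gaps, seeded random placement     | 0.63 min |

Levels are nominal labels; patterns are defined by removed *duration*
(the 60 % burst covers 63 % of the window).  Scatter lengths are drawn
U[1, 2] s until at most 3 s of budget remains, which closes as one gap
(≤ 2 s) or two equal halves — every gap stays in [1, 2] s and the total is
exact.  Placement is uniform with overlap rejection.  Gap membership is
half-open (`[start, end)`), so a beat at exactly the gap end survives.
One pattern instance per level is shared across all windows, matching the
semisimulation design of applying one observed pattern to every reference
window; per-window re-randomised scatter is available for sensitivity
analysis but off by default.

By construction the bursts trigger exactly one >15 s QC gap and the
scatter patterns trigger none, so degraded windows remain usable and the
frequency-domain machinery sees exactly the stress the design intends.

## Statistics

**Missingness contrasts.**  Per metric and activity class, window values
from the reference and degraded datasets enter a linear mixed model with a
participant random intercept and level-of-missingness fixed effects, fit
by REML (`statsmodels.MixedLM`).  Metrics with |sample skewness| > 0.5 are
Box-Cox transformed first (λ by maximum profile likelihood); the skewness
rule is an automated, reproducible stand-in for visual Q-Q inspection, and
can be overridden per metric.  p-values use Satterthwaite-approximated
denominator df computed from the closed-form REML log-likelihood of the
random-intercept model: `df = 2f²/(gᵀAg)` with `f = ℓᵀCov(β̂)ℓ`, `g` its
finite-difference gradient in `(σ²_b, σ²_e)` and `A` the inverse observed
REML information (finite-difference Hessian).  95 % CIs come from a
parametric bootstrap — simulate responses from the fitted model, refit,
take percentile bounds (1000 replicates by default).  Bootstrap refits use
an in-package profile-REML solver for the random-intercept model
(per-group sufficient statistics, 1-D bounded search over
`λ = σ²_b/σ²_e`), which agrees with `MixedLM` to ~1e-4 in tests and is
roughly three orders of magnitude faster; it also serves as a fallback
when the general optimizer collapses onto the `σ²_b = 0` boundary, which
it detects by comparing restricted likelihoods.

**Agreement.**  Windows valid in both devices are paired by
`(participant, window start)`.  ICC(2,k) — two-way random effects, mean of
k = 2 raters — is computed from ANOVA mean squares in both forms:
consistency `(MSR − MSE)/MSR` and absolute agreement
`(MSR − MSE)/(MSR + (MSC − MSE)/n)`, with F-based 95 % CIs (McGraw–Wong;
the agreement interval uses the single-rater bounds with a Satterthwaite
df, stepped up to k raters).  Conventional labels attach to the point
estimates: moderate (> 0.5), good (> 0.75), excellent (> 0.9).
Bland–Altman reports mean difference ± 1.96 sample SD of the differences;
RMSE is the root-mean-square paired difference.  Zero between-subject
variance makes the ICC undefined and is flagged rather than raised.

## Numerical and design choices

* Expected points per window fixed at 300, fraction capped at 100 %.
* Population variance (divide by n) in band power; sample SD (n−1) in
  STDRR and Bland–Altman limits.
* The LF band's lower edge is 0.04 Hz, the standard boundary to the
  very-low-frequency range.
* Windows, gaps and degradation intervals are all half-open; boundary
  beats belong to the later structure.
* Segment-length minimum for the frequency domain: 60 s and 4 beats
  (one full LF sub-window; PCHIP needs ≥ 2 points, 4 gives a stable cubic).
* Filter warm-up: `sosfiltfilt`'s default edge padding on ≥ 301-sample
  segments; shorter segments never reach the filter.
* All randomness flows through `numpy` `SeedSequence`s spawned from a
  single integer seed; identical seeds give byte-identical outputs, which
  the pipeline test enforces at the CSV level.

## Problem sizes in the test suite

Tests run the generator at minutes-to-hours per participant rather than
the 14-day default, sizes chosen so each check has clear statistical
resolution: ≥ 200 windows for directional-stability checks, 16
participants × 25–40 windows × 30–120 replicates for mixed-model bias and
bootstrap-coverage checks (200 bootstrap draws per replicate), 150 random
windows for time-domain oracle equivalence.

## Known limitations

* LF/HF is reported as a ratio of ln-powers, which is scale-dependent;
  comparisons should stay within this pipeline's convention.
* The Satterthwaite machinery is specific to the single-random-intercept
  model; nested or crossed random effects would need the general theory.
* Scatter-gap placement rejects overlaps but allows adjacency, so two
  gaps can fuse into one ≤ 4 s hole; this never approaches the 15-s QC
  threshold.
* The generator's stationary tones cannot probe time-varying spectral
  estimation errors; only band-aggregate behaviour is validated.
* No multiple-testing correction is applied across metrics or levels.
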