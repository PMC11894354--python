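"""Window a stream on the wall clock and run wear-compliance QC.

A participant wears the device for only part of the span, so the
participant-level expected-data fraction falls below 100 %.  Windows
containing a >15 s silence are trimmed to their longest continuous
segment; windows with more than three such gaps are unusable for
frequency-domain analysis.
"""

from hrvgaps import (SyntheticConfig, filter_artifacts, find_gaps,
                     generate_ibi_series, participant_inclusion,
                     segment_windows)

HOUR = 3_600_000
config = SyntheticConfig(
    participant_count=1, duration_days=0.25, seed=7,
    wear_schedule=[(0, 2 * HOUR), (3 * HOUR, 6 * HOUR)])  # 1-hour non-wear hole

series, n_removed = filter_artifacts(generate_ibi_series(config, 0, "ppg"))
windows = segment_windows(series)
print(f"{len(series)} beats after removing {n_removed} artifacts, "
      f"{len(windows)} non-empty 5-minute windows")

n_gappy = 0
for w in windows:
    gaps, segment, usable = find_gaps(w)
    n_gappy += bool(gaps)
print(f"{n_gappy} windows contain at least one >15 s gap")

report = participant_inclusion(windows, participant_id="P00", threshold=70)
print(f"expected data fraction {report.participant_expected_fraction:.1f}% "
      f"over {report.total_windows} windows -> "
      f"{'included' if report.included else 'excluded'} at the 70% threshold")
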