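"""Between-device agreement: wrist PPG vs chest ECG on the same beats.

The synthetic PPG stream equals the ECG stream plus 10 ms measurement
noise and a +5 ms bias.  Median IBI survives this well (high ICC); the
difference-sensitive metrics degrade more.  Consistency ICC ignores the
fixed bias, agreement ICC penalises it.
"""

from hrvgaps import (SyntheticConfig, align_devices, agreement_summary,
                     generate_cohort, prepare_windows)
from hrvgaps.metrics import metrics_table

config = SyntheticConfig(participant_count=4, duration_days=0.2, seed=21)
tables = {"ppg": [], "ecg": []}
for p in generate_cohort(config):
    for device, series in (("ppg", p.ppg), ("ecg", p.ecg)):
        windows, _ = prepare_windows(series, p.steps)
        tables[device].append(metrics_table(windows, p.participant_id))

import pandas as pd
paired = align_devices(pd.concat(tables["ppg"], ignore_index=True),
                       pd.concat(tables["ecg"], ignore_index=True))
summary = agreement_summary(paired, ["median_ibi", "stdrr", "rmsdrr", "hf"])
cols = ["metric", "n_pairs", "icc_agreement", "icc_consistency", "icc_label",
        "bland_altman_mean_diff", "rmse"]
print(summary[cols].round(3).to_string(index=False))
print("\nBland-Altman mean_diff ~ +5 ms for median IBI reflects the "
      "configured PPG bias; consistency > agreement because the bias is fixed")
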