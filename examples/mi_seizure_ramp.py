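"""Inter-channel mutual information rising toward seizure onset.

Simulates two distant channels whose shared-signal fraction ramps from 0 to
0.8 over 300 s (the approach to a seizure), estimates mutual information on
consecutive 30 s windows with the histogram estimator, and tests the trend.
"""

import numpy as np

from ptebio import EEGSimConfig, gen_eeg, mi_trend, windowed_mi

cfg = EEGSimConfig(seed=42, coupling_ramp=(0.0, 0.8), spike_times_s=[])
rec, _ = gen_eeg(cfg)

profile = windowed_mi(rec, "C1", "C5", window_len_s=30.0)
slope, rho, p = mi_trend(profile)

print("MI per 30 s window (bits):", np.round(profile.values, 3))
print(f"trend: slope = {slope:.4f} bits/window, "
      f"Spearman rho = {rho:.2f}, p = {p:.2g}")

# A positive, significant Spearman trend reproduces the seizure-approach
# signature: the two channels share progressively more information as the
# coupling between brain regions tightens.
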