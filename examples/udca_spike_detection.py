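"""Unsupervised epileptiform-window detection with the diffusion embedding.

Simulates a 5-channel, 300 s EEG with ~15 spike-wave complexes at known
times, runs the full pipeline (50%-overlapping 2 s windows, local-Mahalanobis
metric, two-stage normalized kernel, 3-D embedding chosen by spread), and
compares the flagged outlier windows against the injected ground truth.
"""

import numpy as np

from ptebio import EEGSimConfig, UDCAConfig, gen_eeg, outlier_scores, run_udca

rec, truth = gen_eeg(EEGSimConfig(seed=7))
result = run_udca(rec, UDCAConfig(k_e="median"))

window_len_s = result.config.window_size / rec.fs
spike_mask = truth.spike_window_mask(result.window_start_s, window_len_s)

# flag at the rate matched to the true spike-window fraction
_, flags = outlier_scores(result.selected_coords, "quantile",
                          float(spike_mask.mean()))
recall = (flags & spike_mask).sum() / spike_mask.sum()

print(f"windows: {result.segment_set.n_segments}, "
      f"spike-bearing: {spike_mask.sum()}")
print(f"selected eigenvector triple: {result.selected_embedding} "
      f"(spread {result.selected_spread:.3f})")
print(f"kernel scale (median-calibrated): k_e = {result.k_e_used:.4f}")
print(f"recall of spike windows among outliers: {recall:.2f}")
print("first flagged times (s):",
      np.round(result.window_start_s[flags][:8], 1))

# Outlying points in the embedding are windows whose whitened statistics
# depart from the bulk; at these study conditions most of them coincide with
# windows that contain an injected spike-wave complex.
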