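# ptebio

Analysis toolkit for biomarker search in post-traumatic epileptogenesis:
multichannel EEG signal analysis (diffusion-component embedding, windowed
mutual information, STFT spectral quantification) and MRI-derived
perivascular-space (PVS) asymmetry statistics, with ground-truth simulators
so that every stage is testable without clinical data.

## Who this is for

Researchers working on traumatic brain injury (TBI) and post-traumatic
epilepsy (PTE) who need reproducible, scriptable versions of three analysis
families:

1. **Unsupervised epileptiform-window detection (UDCA-style diffusion
   embedding).** A long EEG record is cut into 50%-overlapping windows; each
   window is summarized by its per-channel means and channel covariance. A
   symmetrized local-Mahalanobis quadratic form
   `d(i,j) = Δμᵀ · ½(Σᵢ⁺ + Σⱼ⁺) · Δμ` (SVD pseudo-inverses) feeds a Gaussian
   affinity `A = exp(−d / 4kₑ)`. The kernel is symmetrically normalized by
   its row sums and squared, twice; the eigendecomposition of the resulting
   operator (leading eigenvalue exactly 1) yields point-cloud coordinates.
   All 3-subsets of non-trivial eigenvectors are candidate embeddings; the
   one with the largest spread (mean Euclidean distance to the center of
   mass) is selected, and far-from-center windows are flagged as putative
   epileptiform activity. Out-of-sample windows are embedded by a Nyström
   extension through the same normalization.
2. **Windowed mutual information.** A plug-in joint-histogram MI estimate
   (bits) per consecutive 30 s window for a channel pair, plus an OLS slope
   and Spearman trend test — the signature of interest is MI rising toward
   seizure onset.
3. **PVS hemispheric asymmetry.** Per subject: hemispheric ratios
   `HR_h = PVS_h / PVS_tot`, asymmetry index `AI = HR_major − HR_minor ∈
   [0,1]` (AI ≥ 0.2 = high asymmetry, i.e. one hemisphere holds > 60% of
   PVSs), per-hemisphere mean calibers and `|C_diff|`; per cohort: Student
   t-tests, Pearson correlations (AI vs |C_diff|, age vs total count), and
   high-asymmetry counts.

The simulators (`ptebio.synthetic`) generate EEG with a 1/f background,
focal spike-wave complexes at known times, and a coupling ramp toward a
seizure, and PVS cohorts with controllable group-mean AI and a
caliber-asymmetry slope — all reproducible from a single seed.

## Worked example

```bash
python examples/udca_spike_detection.py
```

```
windows: 299, spike-bearing: 27
selected eigenvector triple: (1, 2, 3) (spread 0.048)
kernel scale (median-calibrated): k_e = 0.0166
recall of spike windows among outliers: 0.89
first flagged times (s): [ 5.  6.  9. 10. 19. 20. 21. 35.]
```

A 300 s, 5-channel simulated recording contains 15 spike-wave complexes
touching 27 of the 299 overlapping 2 s windows. The pipeline selects the
first three non-trivial eigenvectors as the embedding, and — flagging
exactly as many windows as are truly spike-bearing — 89% of the flags land
on windows that contain an injected spike. The other examples
(`examples/mi_seizure_ramp.py`, `examples/pvs_asymmetry_report.py`,
`examples/spectrogram_band_events.py`) print the MI trend toward seizure,
a full cohort asymmetry report, and band-power event extraction.

The same operations are scriptable from the shell:

```bash
ptebio simulate eeg --out rec.edf --truth truth.json
ptebio udca --in rec.edf --ke median --out result.json
ptebio mi --in rec.edf --pair C1 C5 --window 30 --out mi.csv
ptebio pvs --in markers.csv --out report.json
```

Every CLI run writes a `*.manifest.json` next to its outputs with the
effective configuration, input digests, version, and seed.

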