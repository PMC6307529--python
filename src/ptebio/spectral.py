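"""Time-frequency analysis of raw EEG: STFT spectrograms, band power, and
threshold-crossing event extraction.

The spectrogram is a one-sided power spectral density (microvolt^2 per Hz) per
frame, computed on the raw, unfiltered signal. Band power integrates the PSD
over a frequency band with the trapezoid rule, giving a per-frame time series
that can be thresholded to extract events (e.g., sustained high-frequency
activity).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import signal as sps

from .errors import ArgumentError
from .io import EEGRecording


@dataclass
class Spectrogram:
    """One-sided PSD per frame.

    ``power`` has shape (n_freqs, n_frames) in microvolt^2/Hz; ``frame_times``
    are frame centers in seconds, spaced ``window_len_s * (1 - overlap_frac)``.
    """

    power: np.ndarray
    freqs: np.ndarray
    frame_times: np.ndarray
    window_len_s: float
    overlap_frac: float
    channel: str = ""

    @property
    def frame_spacing_s(self) -> float:
        return self.window_len_s * (1.0 - self.overlap_frac)

    def total_power_series(self) -> np.ndarray:
        """Per-frame total power (trapezoidal integral over all frequencies)."""
        return np.trapezoid(self.power, self.freqs, axis=0)


def stft_spectrogram(rec: EEGRecording, channel: str,
                     window_len_s: float = 1.0, overlap_frac: float = 0.5,
                     taper: Literal["hann", "rect"] = "hann") -> Spectrogram:
    """Short-time Fourier transform spectrogram of one channel.

    Parameters
    ----------
    rec : EEGRecording
        Raw recording; no filtering or detrending beyond per-frame mean
        removal is applied.
    channel : str
        Channel label.
    window_len_s : float
        Frame length in seconds; ``window_len_s * fs`` must be >= 2 samples.
    overlap_frac : float
        Fractional overlap between consecutive frames, in [0, 1).
    taper : {"hann", "rect"}
        Analysis window.
    """
    if not (0.0 <= overlap_frac < 1.0):
        raise ArgumentError("overlap_frac must be in [0, 1)")
    nperseg = int(round(window_len_s * rec.fs))
    if nperseg < 2:
        raise ArgumentError("window must span at least 2 samples")
    if nperseg > rec.n_samples:
        raise ArgumentError(
            f"window of {nperseg} samples longer than recording ({rec.n_samples})"
        )
    x = rec.data[rec.channel_index(channel)]
    win = "hann" if taper == "hann" else "boxcar"
    noverlap = int(round(nperseg * overlap_frac))
    freqs, times, pxx = sps.spectrogram(
        x, fs=rec.fs, window=win, nperseg=nperseg, noverlap=noverlap,
        scaling="density", mode="psd", detrend="constant",
    )
    return Spectrogram(power=pxx, freqs=freqs, frame_times=times + rec.t0,
                       window_len_s=nperseg / rec.fs,
                       overlap_frac=noverlap / nperseg, channel=channel)


def band_power_series(spec: Spectrogram, f_lo: float, f_hi: float) -> np.ndarray:
    """Per-frame trapezoidal integral of the PSD over [f_lo, f_hi] Hz."""
    if not (0 <= f_lo < f_hi <= spec.freqs.max() + 1e-12):
        raise ArgumentError(
            f"band must satisfy 0 <= f_lo < f_hi <= {spec.freqs.max():.6g} Hz"
        )
    mask = (spec.freqs >= f_lo) & (spec.freqs <= f_hi)
    if mask.sum() < 2:
        raise ArgumentError(
            f"band [{f_lo}, {f_hi}] Hz covers fewer than two frequency bins"
        )
    return np.trapezoid(spec.power[mask], spec.freqs[mask], axis=0)


def threshold_events(series: np.ndarray, threshold: float,
                     min_duration_s: float = 0.0,
                     frame_spacing_s: float = 1.0,
                     t0: float = 0.0) -> list[tuple[float, float]]:
    """Maximal half-open intervals where ``series > threshold``.

    Each frame stands for ``frame_spacing_s`` seconds starting at its own
    time; an interval covering frames i..j-1 maps to
    ``[t0 + i*spacing, t0 + j*spacing)``. Intervals shorter than
    ``min_duration_s`` are discarded.
    """
    series = np.asarray(series, dtype=float)
    if not np.isfinite(threshold):
        raise ArgumentError("threshold must be finite")
    if min_duration_s < 0:
        raise ArgumentError("min_duration_s must be >= 0")
    above = series > threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(series))
    out = []
    for i, j in zip(starts, ends):
        dur = (j - i) * frame_spacing_s
        if dur >= min_duration_s:
            out.append((t0 + i * frame_spacing_s, t0 + j * frame_spacing_s))
    return out
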