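"""Windowed mutual information between EEG channels.

Mutual information (MI) between two channels is estimated per consecutive,
non-overlapping window (30 s by default) with a plug-in joint-histogram
estimator and reported in bits. Rising MI between distant electrode contacts
toward seizure onset is the phenomenon of interest; the trend over windows is
summarized with an ordinary-least-squares slope and a Spearman rank
correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ArgumentError
from .io import EEGRecording

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 16


@dataclass
class MIProfile:
    """Mutual information per consecutive window for one channel pair."""

    values: np.ndarray            # bits, one per complete window
    window_len_s: float
    window_starts_s: np.ndarray
    channel_pair: tuple[str, str]
    estimator: str = "histogram"
    n_bins: int = DEFAULT_N_BINS


def mutual_information(x: np.ndarray, y: np.ndarray,
                       n_bins: int = DEFAULT_N_BINS) -> float:
    """Plug-in histogram estimate of MI(x, y) in bits.

    The joint distribution is estimated on an ``n_bins`` x ``n_bins`` grid of
    equal-width bins spanning each vector's observed range; MI is
    ``sum p(i,j) log2[p(i,j) / (p(i) p(j))]`` over non-empty cells. A constant
    input has zero entropy, so the estimate is exactly 0.0 in that case.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ArgumentError(f"length mismatch: {x.size} vs {y.size}")
    if n_bins < 2:
        raise ArgumentError("n_bins must be >= 2")
    if x.size < n_bins:
        raise ArgumentError(f"need at least n_bins={n_bins} samples, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    joint, _, _ = np.histogram2d(x, y, bins=n_bins)
    total = joint.sum()
    # marginals from integer counts are exact, and fsum is order-independent,
    # so MI(x, y) == MI(y, x) bit-for-bit
    row_counts = joint.sum(axis=1)
    col_counts = joint.sum(axis=0)
    terms = []
    for i, j in zip(*np.nonzero(joint)):
        pij = joint[i, j] / total
        pi = row_counts[i] / total
        pj = col_counts[j] / total
        terms.append(pij * np.log2(pij / (pi * pj)))
    return math.fsum(terms)


def windowed_mi(rec: EEGRecording, ch_a: str, ch_b: str,
                window_len_s: float = 30.0,
                n_bins: int = DEFAULT_N_BINS) -> MIProfile:
    """MI per consecutive non-overlapping window between two channels.

    The trailing partial window is dropped. Self-pairs are allowed (the value
    is then the windowed self-information, i.e. the histogram entropy) but
    flagged in the log since they carry no cross-channel information.
    """
    if ch_a == ch_b:
        logger.warning("windowed_mi called with identical channels %r: values "
                       "are windowed self-information, not coupling", ch_a)
    ia, ib = rec.channel_index(ch_a), rec.channel_index(ch_b)
    w = int(round(window_len_s * rec.fs))
    if w < 2:
        raise ArgumentError("window_len_s too short for the sampling rate")
    n_win = rec.n_samples // w
    if n_win < 1:
        raise ArgumentError(
            f"recording ({rec.duration_s:.6g} s) shorter than one "
            f"{window_len_s:.6g} s window"
        )
    values = np.empty(n_win)
    for k in range(n_win):
        sl = slice(k * w, (k + 1) * w)
        values[k] = mutual_information(rec.data[ia, sl], rec.data[ib, sl], n_bins)
    starts = rec.t0 + np.arange(n_win) * (w / rec.fs)
    return MIProfile(values=values, window_len_s=w / rec.fs,
                     window_starts_s=starts, channel_pair=(ch_a, ch_b),
                     n_bins=n_bins)


def mi_trend(profile: MIProfile) -> tuple[float, float, float]:
    """Trend of MI across windows.

    Returns ``(slope, rho, p)``: the least-squares slope of MI versus window
    index (bits per window), the Spearman rank correlation, and its two-sided
    p-value.
    """
    v = np.asarray(profile.values, dtype=float)
    if v.size < 3:
        raise ArgumentError("need at least 3 windows to estimate a trend")
    idx = np.arange(v.size)
    slope = float(np.polyfit(idx, v, 1)[0])
    if np.ptp(v) == 0:
        return 0.0, 0.0, 1.0
    rho, p = stats.spearmanr(idx, v)
    return slope, float(rho), float(p)
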