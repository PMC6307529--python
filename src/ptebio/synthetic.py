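"""Synthetic EEG recordings and PVS cohorts with known ground truth.

The EEG generator emulates long-term multichannel recordings: a 1/f-like
stochastic background per channel, epileptiform spike-wave complexes injected
at known times on all channels (small per-channel latency/amplitude jitter),
and a shared latent signal whose mixing fraction ramps up toward seizure
onset so that inter-channel mutual information rises as the seizure
approaches. The spike-wave complex is a sharp transient followed by a
same-polarity slow wave, the classic surface-negative spike-and-wave
morphology, so spike-bearing windows carry both a variance and a baseline
shift signature.

The PVS generator draws per-subject hemispheric asymmetry indices around a
group target, splits a realistic total PVS count accordingly, and offsets the
minor hemisphere's caliber distribution downward in proportion to the
asymmetry — mirroring the observation that smaller PVSs sit on the injured
side — so that AI and |C_diff| are positively related by construction.

All randomness fans out from one integer seed through independent
``numpy.random.SeedSequence`` substreams, so adding a component never
perturbs the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ArgumentError
from .io import CALIBER_MAX_MM, CALIBER_MIN_MM, EEGRecording, PVSMarkerTable


# ---------------------------------------------------------------------------
# EEG simulation
# ---------------------------------------------------------------------------

@dataclass
class EEGSimConfig:
    """Study conditions for the EEG simulator.

    Defaults describe a 5-channel, 200 samples/second, 300 s recording with a
    15 uV-SD 1/f background, ~150 uV spike-wave complexes at 0.05/s, and
    inter-channel coupling ramping from 0.05 to 0.6 of shared-signal variance
    across the record (the seizure-approach regime).
    """

    n_channels: int = 5
    fs: float = 200.0
    duration_s: float = 300.0
    background_exponent: float = 1.0      # spectral slope: power ~ 1/f^exponent
    background_amplitude_uv: float = 15.0  # per-channel SD of the background
    highpass_hz: float = 0.5              # acquisition high-pass corner
    spike_times_s: Sequence[float] | None = None  # explicit times, or...
    spike_rate_per_s: float = 0.05                # ...uniform random at this rate
    spike_amplitude_uv: float = 150.0
    spike_width_ms: float = 70.0
    spike_focus_channel: int | None = None  # topography peak; None = middle
    seizure_onset_s: float | None = None   # ramp endpoint; None = end of record
    coupling_ramp: tuple[float, float] = (0.05, 0.6)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1 or self.fs <= 0 or self.duration_s <= 0:
            raise ArgumentError("need n_channels >= 1, fs > 0, duration_s > 0")
        c0, c1 = self.coupling_ramp
        if not (0 <= c0 <= 1 and 0 <= c1 <= 1 and c0 <= c1):
            raise ArgumentError("coupling fractions must be in [0,1], nondecreasing")
        if self.spike_width_ms / 1000.0 >= self.duration_s:
            raise ArgumentError("spike width must be shorter than the recording")
        if self.spike_times_s is not None:
            bad = [t for t in self.spike_times_s
                   if not (0 <= t < self.duration_s)]
            if bad:
                raise ArgumentError(f"spike times outside [0, duration): {bad}")
        if self.seizure_onset_s is not None and not (
                0 < self.seizure_onset_s <= self.duration_s):
            raise ArgumentError("seizure_onset_s must lie in (0, duration_s]")


@dataclass
class EEGGroundTruth:
    """What the generator actually injected."""

    spike_times_s: list[float]
    seizure_interval_s: tuple[float, float] | None
    coupling_fraction: np.ndarray = field(repr=False)  # per sample

    def spike_window_mask(self, window_starts_s: Sequence[float],
                          window_len_s: float) -> np.ndarray:
        """Boolean mask over windows: does [start, start+len) contain a spike?"""
        starts = np.asarray(window_starts_s, dtype=float)
        mask = np.zeros(starts.size, dtype=bool)
        for t in self.spike_times_s:
            mask |= (starts <= t) & (t < starts + window_len_s)
        return mask


def _one_over_f_noise(rng: np.random.Generator, n_samples: int, fs: float,
                      exponent: float, amplitude: float,
                      highpass_hz: float = 0.0, size: int = 1) -> np.ndarray:
    """Gaussian noise shaped to a 1/f^exponent power spectrum, SD=amplitude.

    ``highpass_hz`` applies a second-order-like high-pass magnitude response
    (f^2 / (f^2 + hp^2)), emulating the acquisition front-end that removes
    sub-hertz drift from clinical EEG.
    """
    white = rng.standard_normal((size, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0  # no DC
    if highpass_hz > 0:
        shape *= freqs ** 2 / (freqs ** 2 + highpass_hz ** 2)
    shaped = np.fft.irfft(spec * shape, n=n_samples, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd * amplitude


def _spike_wave_kernel(fs: float, width_ms: float, amplitude: float
                       ) -> np.ndarray:
    """Sharp spike plus same-polarity after-coming slow wave."""
    sigma_spike = width_ms / 6.0 / 1000.0          # seconds
    sigma_wave = width_ms * 2.2 / 1000.0
    wave_delay = width_ms * 3.5 / 1000.0
    length = int(np.ceil((wave_delay + 4 * sigma_wave) * fs))
    t = np.arange(length) / fs
    spike = amplitude * np.exp(-0.5 * ((t - 3 * sigma_spike) / sigma_spike) ** 2)
    wave = 0.35 * amplitude * np.exp(-0.5 * ((t - wave_delay) / sigma_wave) ** 2)
    return spike + wave


def gen_eeg(cfg: EEGSimConfig) -> tuple[EEGRecording, EEGGroundTruth]:
    """Generate a multichannel EEG recording with known spike/coupling truth."""
    n = int(round(cfg.duration_s * cfg.fs))
    ss = np.random.SeedSequence(cfg.seed)
    rng_bg, rng_shared, rng_times, rng_jitter = (
        np.random.default_rng(s) for s in ss.spawn(4))

    background = _one_over_f_noise(rng_bg, n, cfg.fs, cfg.background_exponent,
                                   cfg.background_amplitude_uv,
                                   cfg.highpass_hz, size=cfg.n_channels)
    shared = _one_over_f_noise(rng_shared, n, cfg.fs, cfg.background_exponent,
                               cfg.background_amplitude_uv, cfg.highpass_hz,
                               size=1)[0]

    onset = cfg.seizure_onset_s if cfg.seizure_onset_s is not None else cfg.duration_s
    onset_idx = max(int(round(onset * cfg.fs)), 1)
    c0, c1 = cfg.coupling_ramp
    coupling = np.empty(n)
    ramp_len = min(onset_idx, n)
    coupling[:ramp_len] = np.linspace(c0, c1, ramp_len)
    coupling[ramp_len:] = c1

    data = (np.sqrt(1.0 - coupling)[None, :] * background
            + np.sqrt(coupling)[None, :] * shared[None, :])

    if cfg.spike_times_s is not None:
        spike_times = sorted(float(t) for t in cfg.spike_times_s)
    else:
        n_spikes = int(round(cfg.spike_rate_per_s * cfg.duration_s))
        spike_times = sorted(rng_times.uniform(0, cfg.duration_s * 0.98,
                                               size=n_spikes).tolist())
    kernel = _spike_wave_kernel(cfg.fs, cfg.spike_width_ms,
                                cfg.spike_amplitude_uv)
    focus = (cfg.spike_focus_channel if cfg.spike_focus_channel is not None
             else cfg.n_channels // 2)
    if not (0 <= focus < cfg.n_channels):
        raise ArgumentError("spike_focus_channel out of range")
    # focal topography: full gain at the focus, exponential fall-off with
    # electrode distance — epileptiform fields are spatially localized
    gains = np.exp(-np.abs(np.arange(cfg.n_channels) - focus) / 2.0)
    max_jitter = int(round(0.010 * cfg.fs))  # +/-10 ms channel latency
    for t in spike_times:
        i0 = int(round(t * cfg.fs))
        for ch in range(cfg.n_channels):
            j = int(rng_jitter.integers(-max_jitter, max_jitter + 1))
            amp = gains[ch] * (1.0 + 0.15 * rng_jitter.standard_normal())
            a = max(i0 + j, 0)
            b = min(a + kernel.size, n)
            if b > a:
                data[ch, a:b] += amp * kernel[:b - a]

    rec = EEGRecording(
        data=data, fs=cfg.fs,
        channel_labels=[f"C{i + 1}" for i in range(cfg.n_channels)], t0=0.0)
    seizure = ((onset, cfg.duration_s)
               if cfg.seizure_onset_s is not None else None)
    truth = EEGGroundTruth(spike_times_s=spike_times,
                           seizure_interval_s=seizure,
                           coupling_fraction=coupling)
    return rec, truth


# ---------------------------------------------------------------------------
# PVS cohort simulation
# ---------------------------------------------------------------------------

@dataclass
class PVSSimConfig:
    """Study conditions for the PVS cohort simulator.

    Group-mean asymmetry targets default to the TBI-like (0.17) and
    control-like (0.04) regimes; totals are drawn around ``count_scale`` and
    the minor hemisphere's caliber mean is lowered by
    ``caliber_asymmetry_slope * AI`` millimetres.
    """

    n_tbi: int = 15
    n_control: int = 6
    target_mean_ai_tbi: float = 0.17
    target_mean_ai_control: float = 0.04
    count_scale: float = 78.0
    count_sd: float = 30.0
    caliber_mean_mm: float = 1.35
    caliber_sd_mm: float = 0.22
    caliber_asymmetry_slope: float = 0.5   # mm of |C_diff| per unit AI
    age_range: tuple[float, float] = (7.0, 68.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for target in (self.target_mean_ai_tbi, self.target_mean_ai_control):
            if not (0 <= target <= 1):
                raise ArgumentError("target mean AI must lie in [0, 1]")
        lo = self.caliber_mean_mm - self.caliber_asymmetry_slope
        if not (CALIBER_MIN_MM < self.caliber_mean_mm < CALIBER_MAX_MM):
            raise ArgumentError("caliber_mean_mm must lie inside [0.5, 3) mm")
        if lo <= CALIBER_MIN_MM:
            raise ArgumentError(
                "caliber_mean_mm - caliber_asymmetry_slope must stay above "
                f"{CALIBER_MIN_MM} mm so simulated calibers remain in range"
            )
        if self.age_range[0] < 0 or self.age_range[0] >= self.age_range[1]:
            raise ArgumentError("age_range must be (min, max) with 0 <= min < max")


def _gen_subject(rng: np.random.Generator, sid: str, group: str,
                 target_ai: float, cfg: PVSSimConfig) -> PVSMarkerTable:
    total = max(int(round(rng.normal(cfg.count_scale, cfg.count_sd))), 10)
    # Gamma(shape 2) keeps the mean exactly on target with realistic skew
    ai = float(rng.gamma(2.0, target_ai / 2.0)) if target_ai > 0 else 0.0
    ai = min(ai, 0.95)
    major = int(round(total * (0.5 + ai / 2.0)))
    minor = total - major
    major_side, minor_side = (("right", "left") if rng.random() < 0.5
                              else ("left", "right"))
    realized_ai = (major - minor) / total

    means = {major_side: cfg.caliber_mean_mm,
             minor_side: cfg.caliber_mean_mm
             - cfg.caliber_asymmetry_slope * realized_ai}
    markers: list[tuple[str, float]] = []
    for side, count in ((major_side, major), (minor_side, minor)):
        cal = rng.normal(means[side], cfg.caliber_sd_mm, size=count)
        cal = np.clip(cal, CALIBER_MIN_MM, CALIBER_MAX_MM - 0.01)
        markers += [(side, float(c)) for c in cal]
    age = float(rng.uniform(*cfg.age_range))
    sex = "M" if rng.random() < 0.6 else "F"
    return PVSMarkerTable(subject_id=sid, group=group, age_years=age,
                          sex=sex, markers=markers)


def gen_pvs_cohort(cfg: PVSSimConfig) -> list[PVSMarkerTable]:
    """Generate a TBI-like plus control-like PVS cohort with known targets."""
    ss = np.random.SeedSequence(cfg.seed)
    rng_tbi, rng_ctl = (np.random.default_rng(s) for s in ss.spawn(2))
    cohort = [
        _gen_subject(rng_tbi, f"T{i + 1:02d}", "TBI",
                     cfg.target_mean_ai_tbi, cfg)
        for i in range(cfg.n_tbi)
    ]
    cohort += [
        _gen_subject(rng_ctl, f"C{i + 1:02d}", "control",
                     cfg.target_mean_ai_control, cfg)
        for i in range(cfg.n_control)
    ]
    return cohort
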