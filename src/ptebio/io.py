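"""Reading and writing EEG recordings and perivascular-space (PVS) marker tables.

Two EEG container formats are supported:

* ``edf`` — 16-bit European Data Format, the canonical container for long-term
  clinical EEG. Reading goes through :mod:`mne`; writing uses the small
  standards-conforming writer in this module (one data record holding the whole
  signal, physical dimension microvolts).
* ``csv_matrix`` — a human-readable fixture dialect: a header line of channel
  labels followed by one line of comma-separated samples per channel, with a
  JSON side-car ``<path>.json`` holding ``{"fs": <Hz>}`` (and optionally
  ``"t0"``).

PVS marker tables are UTF-8 CSV with columns ``subject_id, group, age, sex,
hemisphere, caliber_mm`` — one marked PVS per row. Markers with caliber
outside the reliable measurement range [0.5, 3.0) mm are dropped at load and
counted in a :class:`PVSLoadReport`.
"""

from __future__ import annotations

import json
import logging
import math
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ArgumentError, DataIntegrityError, FormatError

logger = logging.getLogger(__name__)

CALIBER_MIN_MM = 0.5
CALIBER_MAX_MM = 3.0  # exclusive

PVS_COLUMNS = ["subject_id", "group", "age", "sex", "hemisphere", "caliber_mm"]


# ---------------------------------------------------------------------------
# EEG recording model
# ---------------------------------------------------------------------------

@dataclass
class EEGRecording:
    """Multichannel EEG signal matrix.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in samples/second.
    channel_labels : list of str
        Unique channel names, one per row of ``data``.
    t0 : float
        Start time of the first sample in seconds.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ArgumentError("data must be a 2-D (n_channels, n_samples) array")
        n_ch, n_s = self.data.shape
        if n_ch < 1 or n_s < 1:
            raise ArgumentError("recording needs at least one channel and one sample")
        if not self.fs > 0:
            raise ArgumentError("sampling rate must be positive")
        self.channel_labels = [str(c) for c in self.channel_labels]
        if len(self.channel_labels) != n_ch:
            raise ArgumentError(
                f"{len(self.channel_labels)} labels for {n_ch} channels"
            )
        if len(set(self.channel_labels)) != n_ch:
            raise ArgumentError("channel labels must be unique")
        bad = _nonfinite_channels(self.data, self.channel_labels)
        if bad:
            raise DataIntegrityError(
                "non-finite samples in channel(s): " + ", ".join(bad)
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ArgumentError(
                f"unknown channel {label!r}; available: {self.channel_labels}"
            ) from None


def _nonfinite_channels(data: np.ndarray, labels: Sequence[str]) -> list[str]:
    mask = ~np.isfinite(data).all(axis=1)
    return [labels[i] for i in np.flatnonzero(mask)]


# ---------------------------------------------------------------------------
# EDF writing (16-bit, one data record)
# ---------------------------------------------------------------------------

def _edf_field(value: str, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise FormatError(f"EDF header field {s!r} exceeds {width} bytes")
    return s.ljust(width).encode("ascii")


def write_edf(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as a 16-bit EDF file.

    The whole signal is stored in a single data record whose duration is
    ``n_samples / fs``; physical limits are integer microvolt bounds rounded
    outward, so amplitude resolution is (max-min)/65535 microvolts.
    """
    path = Path(path)
    bad = _nonfinite_channels(rec.data, rec.channel_labels)
    if bad:
        raise DataIntegrityError(
            "cannot write non-finite samples; channel(s): " + ", ".join(bad)
        )
    n_ch, n_s = rec.data.shape
    header_bytes = 256 * (1 + n_ch)
    duration = n_s / rec.fs
    dur_str = f"{duration:.8g}"[:8]

    parts = [
        _edf_field("0", 8),
        _edf_field("X X X X", 80),
        _edf_field("Startdate X X X X", 80),
        _edf_field("01.01.01", 8),
        _edf_field("00.00.00", 8),
        _edf_field(str(header_bytes), 8),
        _edf_field("", 44),
        _edf_field("1", 8),
        _edf_field(dur_str, 8),
        _edf_field(str(n_ch), 4),
    ]

    phys_min = np.floor(rec.data.min(axis=1)).astype(int)
    phys_max = np.ceil(rec.data.max(axis=1)).astype(int)
    flat = phys_max == phys_min
    phys_max = np.where(flat, phys_min + 1, phys_max)
    dig_min, dig_max = -32768, 32767

    def per_signal(fn) -> bytes:
        return b"".join(fn(i) for i in range(n_ch))

    parts += [
        per_signal(lambda i: _edf_field(rec.channel_labels[i], 16)),
        per_signal(lambda i: _edf_field("", 80)),
        per_signal(lambda i: _edf_field("uV", 8)),
        per_signal(lambda i: _edf_field(str(phys_min[i]), 8)),
        per_signal(lambda i: _edf_field(str(phys_max[i]), 8)),
        per_signal(lambda i: _edf_field(str(dig_min), 8)),
        per_signal(lambda i: _edf_field(str(dig_max), 8)),
        per_signal(lambda i: _edf_field("", 80)),
        per_signal(lambda i: _edf_field(str(n_s), 8)),
        per_signal(lambda i: _edf_field("", 32)),
    ]

    scale = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.rint(
        (rec.data - phys_min[:, None]) / scale[:, None] + dig_min
    ).astype(np.int16)

    with open(path, "wb") as fh:
        fh.write(b"".join(parts))
        fh.write(digital.astype("<i2").tobytes())


def _read_edf(path: Path) -> EEGRecording:
    import mne

    try:
        raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise FormatError(f"cannot read EDF file {path}: {exc}") from exc
    picks = [
        i for i, ch in enumerate(raw.ch_names) if ch.upper() != "EDF ANNOTATIONS"
    ]
    labels = [raw.ch_names[i] for i in picks]
    data_uv = raw.get_data(picks=picks) * 1e6  # mne holds voltages in volts
    return EEGRecording(data=data_uv, fs=float(raw.info["sfreq"]),
                        channel_labels=labels, t0=0.0)


# ---------------------------------------------------------------------------
# csv_matrix dialect
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_csv_matrix(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording in the csv_matrix fixture dialect with JSON side-car."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(rec.channel_labels) + "\n")
        for row in rec.data:
            fh.write(",".join(f"{v:.10g}" for v in row) + "\n")
    with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
        json.dump({"fs": rec.fs, "t0": rec.t0}, fh)


def _read_csv_matrix(path: Path) -> EEGRecording:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(
            f"csv_matrix side-car {sidecar} not found (must hold the sampling rate)"
        )
    with open(sidecar, encoding="utf-8") as fh:
        meta = json.load(fh)
    if "fs" not in meta:
        raise FormatError(f"side-car {sidecar} lacks required key 'fs'")
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header:
            raise FormatError(f"{path}: empty csv_matrix file")
        labels = [c.strip() for c in header.split(",")]
        rows = []
        for line in fh:
            line = line.strip()
            if line:
                rows.append(np.array(line.split(","), dtype=float))
    if len(rows) != len(labels):
        raise FormatError(
            f"{path}: {len(labels)} labels in header but {len(rows)} channel rows"
        )
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise FormatError(f"{path}: channel rows have unequal lengths {sorted(lengths)}")
    data = np.vstack(rows)
    bad = _nonfinite_channels(data, labels)
    if bad:
        raise DataIntegrityError(
            f"{path}: non-finite samples in channel(s): " + ", ".join(bad)
        )
    return EEGRecording(data=data, fs=float(meta["fs"]), channel_labels=labels,
                        t0=float(meta.get("t0", 0.0)))


# ---------------------------------------------------------------------------
# Recording front door
# ---------------------------------------------------------------------------

def read_recording(path: str | Path,
                   format: Literal["edf", "csv_matrix"] | None = None) -> EEGRecording:
    """Read an EEG recording, dispatching on ``format`` (or the file suffix)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv_matrix"
    if format == "edf":
        return _read_edf(path)
    if format == "csv_matrix":
        return _read_csv_matrix(path)
    raise ArgumentError(f"unknown recording format {format!r}")


def write_recording(rec: EEGRecording, path: str | Path,
                    format: Literal["edf", "csv_matrix"] | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv_matrix"
    if format == "edf":
        write_edf(rec, path)
    elif format == "csv_matrix":
        write_csv_matrix(rec, path)
    else:
        raise ArgumentError(f"unknown recording format {format!r}")


def slice_recording(rec: EEGRecording, t_start_s: float, t_end_s: float,
                    channels: Sequence[str] | None = None) -> EEGRecording:
    """Extract the half-open time interval [t_start_s, t_end_s).

    The result holds ``round((t_end_s - t_start_s) * fs)`` samples and its
    ``t0`` is set to ``t_start_s``. Channel order follows the request.
    """
    t_max = rec.t0 + rec.n_samples / rec.fs
    if not (rec.t0 <= t_start_s < t_end_s <= t_max + 1e-9):
        raise ArgumentError(
            f"need t0 <= t_start < t_end <= {t_max:.6g} s "
            f"(got [{t_start_s}, {t_end_s}), t0={rec.t0})"
        )
    if channels is not None and len(channels) == 0:
        raise ArgumentError("empty channel selection")
    idx = (list(range(rec.n_channels)) if channels is None
           else [rec.channel_index(c) for c in channels])
    i0 = int(round((t_start_s - rec.t0) * rec.fs))
    n = int(round((t_end_s - t_start_s) * rec.fs))
    if n < 1:
        raise ArgumentError("slice shorter than one sample")
    data = rec.data[np.asarray(idx)][:, i0:i0 + n]
    labels = [rec.channel_labels[i] for i in idx]
    return EEGRecording(data=data.copy(), fs=rec.fs, channel_labels=labels,
                        t0=t_start_s)


# ---------------------------------------------------------------------------
# PVS marker tables
# ---------------------------------------------------------------------------

@dataclass
class PVSLoadReport:
    """Bookkeeping from a PVS table load: how many markers survived the
    caliber gate and which subjects lost markers."""

    n_rows: int = 0
    n_retained: int = 0
    n_dropped: int = 0
    dropped_by_subject: dict = field(default_factory=dict)


@dataclass
class PVSMarkerTable:
    """All marked PVSs for one subject.

    ``markers`` holds ``(hemisphere, caliber_mm)`` pairs with hemisphere in
    {"right", "left"} and caliber in the reliable range [0.5, 3.0) mm.
    """

    subject_id: str
    group: str                     # "TBI" or "control"
    age_years: float
    sex: str                       # "M" or "F"
    markers: list[tuple[str, float]] = field(default_factory=list)
    load_report: PVSLoadReport | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.group not in ("TBI", "control"):
            raise ArgumentError(f"group must be 'TBI' or 'control', got {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ArgumentError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.age_years < 0:
            raise ArgumentError("age must be non-negative")
        for hemi, cal in self.markers:
            if hemi not in ("right", "left"):
                raise ArgumentError(f"hemisphere must be right/left, got {hemi!r}")
            if not (CALIBER_MIN_MM <= cal < CALIBER_MAX_MM):
                raise ArgumentError(
                    f"caliber {cal} mm outside [{CALIBER_MIN_MM}, {CALIBER_MAX_MM}) mm"
                )

    def counts(self) -> tuple[int, int]:
        """(right, left) marker counts."""
        r = sum(1 for h, _ in self.markers if h == "right")
        return r, len(self.markers) - r

    def calibers(self, hemisphere: str) -> np.ndarray:
        return np.array([c for h, c in self.markers if h == hemisphere])


def read_pvs_cohort(path: str | Path,
                    permissive: bool = False) -> tuple[list[PVSMarkerTable], PVSLoadReport]:
    """Load a cohort PVS marker CSV into one table per subject.

    Markers with caliber outside [0.5, 3.0) mm are dropped and counted in the
    returned :class:`PVSLoadReport`. In strict mode (default) a subject left
    with zero markers, or an empty file, is a :class:`FormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        if permissive:
            return [], PVSLoadReport()
        raise FormatError(f"{path}: empty PVS table") from None
    missing = [c for c in PVS_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    if len(df) == 0 and not permissive:
        raise FormatError(f"{path}: PVS table has no marker rows")

    hemi = df["hemisphere"].astype(str).str.strip().str.lower()
    bad_rows = df.index[~hemi.isin(["right", "left"])]
    if len(bad_rows):
        r = int(bad_rows[0])
        raise FormatError(
            f"{path}: unknown hemisphere label {df['hemisphere'].iloc[r]!r} "
            f"at data row {r + 1}"
        )
    df = df.assign(hemisphere=hemi)

    report = PVSLoadReport(n_rows=len(df))
    tables: list[PVSMarkerTable] = []
    for sid, sub in df.groupby("subject_id", sort=False):
        meta = sub[["group", "age", "sex"]].drop_duplicates()
        if len(meta) > 1:
            raise FormatError(
                f"{path}: inconsistent group/age/sex metadata for subject {sid!r}"
            )
        cal = sub["caliber_mm"].to_numpy(dtype=float)
        keep = (cal >= CALIBER_MIN_MM) & (cal < CALIBER_MAX_MM)
        n_drop = int((~keep).sum())
        if n_drop:
            report.dropped_by_subject[str(sid)] = n_drop
            logger.warning("subject %s: dropped %d marker(s) with caliber outside "
                           "[%.1f, %.1f) mm", sid, n_drop, CALIBER_MIN_MM, CALIBER_MAX_MM)
        report.n_dropped += n_drop
        report.n_retained += int(keep.sum())
        if keep.sum() == 0 and not permissive:
            raise FormatError(
                f"{path}: subject {sid!r} has no in-range markers "
                "(rerun with permissive=True to keep the subject with zero markers)"
            )
        markers = list(zip(sub["hemisphere"].to_numpy()[keep],
                           cal[keep].tolist()))
        tables.append(PVSMarkerTable(
            subject_id=str(sid),
            group=str(meta["group"].iloc[0]),
            age_years=float(meta["age"].iloc[0]),
            sex=str(meta["sex"].iloc[0]),
            markers=[(str(h), float(c)) for h, c in markers],
            load_report=report,
        ))
    return tables, report


def read_pvs_table(path: str | Path, permissive: bool = False) -> PVSMarkerTable:
    """Load a single-subject PVS marker CSV (see :func:`read_pvs_cohort`)."""
    tables, _report = read_pvs_cohort(path, permissive=permissive)
    if len(tables) != 1:
        raise FormatError(
            f"{path}: expected exactly one subject, found {len(tables)}; "
            "use read_pvs_cohort for cohort files"
        )
    return tables[0]


def write_pvs_cohort(tables: Sequence[PVSMarkerTable], path: str | Path) -> None:
    """Write subject marker tables back to the cohort CSV dialect."""
    rows = []
    for t in tables:
        for hemi, cal in t.markers:
            rows.append((t.subject_id, t.group, t.age_years, t.sex, hemi, cal))
    df = pd.DataFrame(rows, columns=PVS_COLUMNS)
    df.to_csv(path, index=False)
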