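"""Reading and writing multichannel EEG recordings.

The universal in-memory container is :class:`EEGRecording`: a channels x
samples float matrix (microvolts) with a sampling rate and unique channel
labels.  CSV (one column per channel, header row = labels) is the guaranteed
interchange format; EDF is supported as an optional extra — reading goes
through :mod:`mne`, writing through a minimal built-in 16-bit EDF encoder.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EEGRecording", "read_recording", "write_recording"]


@dataclass
class EEGRecording:
    """A multichannel EEG recording.

    Parameters
    ----------
    data : ndarray, shape (m, N)
        Channel signals in microvolts, one row per channel.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Unique channel names, one per row of ``data``.
    meta : dict
        Free-form provenance (subject, session, condition, ...).
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        m, n = self.data.shape
        if m < 2:
            raise ValueError(f"need at least 2 channels, got {m}")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if n <= self.fs:
            raise ValueError(
                f"recording must be longer than 1 s ({n} samples @ {self.fs} Hz)"
            )
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != m:
            raise ValueError(
                f"{len(self.labels)} labels for {m} channels"
            )
        if len(set(self.labels)) != m:
            raise ValueError("channel labels must be unique")
        if not np.isfinite(self.data).all():
            bad = np.argwhere(~np.isfinite(self.data))[0]
            raise ValueError(
                f"non-finite sample at channel {self.labels[bad[0]]}, index {bad[1]}"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.data.shape[1] / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel named {label!r}") from None

    def copy_with(self, data: np.ndarray | None = None, **meta) -> "EEGRecording":
        """Return a copy, optionally replacing the data and extending meta."""
        return EEGRecording(
            data=self.data.copy() if data is None else data,
            fs=self.fs,
            labels=list(self.labels),
            meta={**self.meta, **meta},
        )


def _infer_format(path: Path, format: str | None) -> str:
    if format is not None:
        return format.lower()
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "edf"):
        return suffix
    raise ValueError(f"cannot infer format from {path.name!r}; pass format=")


def read_recording(
    path,
    format: str | None = None,
    fs: float | None = None,
    labels: list[str] | None = None,
    meta: dict | None = None,
) -> EEGRecording:
    """Load a recording from CSV or EDF.

    CSV carries no sampling rate, so ``fs`` is mandatory for it.  On-disk
    orientation is resolved by matching the label count: if the provided (or
    header) labels match the column count, columns are channels; if they match
    the row count, rows are channels.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        if fs is None:
            raise ValueError("fs must be supplied when reading CSV (no rate on disk)")
        frame = pd.read_csv(path)
        values = frame.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            r, c = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value in {path.name} at row {r + 2}, "
                f"column {frame.columns[c]!r}"
            )
        file_labels = [str(c) for c in frame.columns]
        if labels is None:
            data, use_labels = values.T, file_labels
        elif len(labels) == values.shape[1]:
            data, use_labels = values.T, list(labels)
        elif len(labels) == values.shape[0]:
            data, use_labels = values, list(labels)
        else:
            raise ValueError(
                f"{len(labels)} labels match neither {values.shape[1]} columns "
                f"nor {values.shape[0]} rows of {path.name}"
            )
        return EEGRecording(data, fs, use_labels, meta=dict(meta or {}))
    if fmt == "edf":
        return _read_edf(path, meta=dict(meta or {}))
    raise ValueError(f"unsupported format {fmt!r}")


def write_recording(rec: EEGRecording, path, format: str | None = None) -> Path:
    """Write a recording to CSV or EDF; round-trips with :func:`read_recording`."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        pd.DataFrame(rec.data.T, columns=rec.labels).to_csv(path, index=False)
        return path
    if fmt == "edf":
        _write_edf(rec, path)
        return path
    raise ValueError(f"unsupported format {fmt!r}")


# --------------------------------------------------------------------------
# EDF: read via mne (optional extra), write via a minimal 16-bit encoder.
# --------------------------------------------------------------------------

def _read_edf(path: Path, meta: dict) -> EEGRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - env-dependent
        raise ImportError(
            "EDF reading requires mne; install the 'edf' extra"
        ) from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # mne works in volts; container is microvolts
    return EEGRecording(data, float(raw.info["sfreq"]), list(raw.ch_names), meta=meta)


def _pad_field(value: str, width: int) -> bytes:
    b = value.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def _write_edf(rec: EEGRecording, path: Path) -> None:
    """Minimal EDF writer: 1-s records, 16-bit samples, per-channel scaling."""
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    spr = int(round(fs))  # samples per 1-s data record
    m, n = rec.data.shape
    n_records = int(np.ceil(n / spr))
    padded = np.empty((m, n_records * spr))
    padded[:, :n] = rec.data
    padded[:, n:] = rec.data[:, -1:]  # edge-pad the final partial record

    phys_min = padded.min(axis=1)
    phys_max = padded.max(axis=1)
    span = phys_max - phys_min
    phys_max = np.where(span == 0, phys_min + 1.0, phys_max)
    dig_min, dig_max = -32768, 32767

    header = b"".join([
        _pad_field("0", 8),
        _pad_field("X X X X", 80),
        _pad_field("Startdate 01-JAN-2000 X X X", 80),
        _pad_field("01.01.00", 8),
        _pad_field("00.00.00", 8),
        _pad_field(str(256 * (1 + m)), 8),
        _pad_field("", 44),
        _pad_field(str(n_records), 8),
        _pad_field("1", 8),
        _pad_field(str(m), 4),
    ])
    fields = [
        [_pad_field(lbl, 16) for lbl in rec.labels],
        [_pad_field("", 80)] * m,
        [_pad_field("uV", 8)] * m,
        [_pad_field(f"{v:.6g}"[:8], 8) for v in phys_min],
        [_pad_field(f"{v:.6g}"[:8], 8) for v in phys_max],
        [_pad_field(str(dig_min), 8)] * m,
        [_pad_field(str(dig_max), 8)] * m,
        [_pad_field("", 80)] * m,
        [_pad_field(str(spr), 8)] * m,
        [_pad_field("", 32)] * m,
    ]
    header += b"".join(b"".join(block) for block in fields)

    # Physical -> digital mapping per channel.
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip(
        np.rint((padded - phys_min[:, None]) * gain[:, None]) + dig_min,
        dig_min, dig_max,
    ).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            block = digital[:, r * spr:(r + 1) * spr]
            fh.write(block.tobytes())
    # sanity: header length must match the declared byte count
    assert len(header) == 256 * (1 + m), struct.error("EDF header size mismatch")
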