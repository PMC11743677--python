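"""EDF import/export for EEG recordings.

Recordings are exchanged as 16-bit European Data Format (EDF) files, the
lingua franca of clinical EEG.  Reading goes through MNE's EDF reader;
writing uses a minimal EDF encoder (one data record per second, per-channel
physical scaling), since no EDF writer is available in the runtime stack.
Subject ID and group label travel in the EDF patient-identification field.
"""

from __future__ import annotations

import math
import os
from typing import Optional, Sequence

import numpy as np

from .cohort import EEGRecording, GROUPS

__all__ = ["EDFParseError", "write_recording", "read_recording"]

_DIG_MIN, _DIG_MAX = -32768, 32767


class EDFParseError(ValueError):
    """Raised when an EDF header field is malformed; names the field."""


def _ascii(value: str, width: int) -> bytes:
    s = value[:width].ljust(width)
    return s.encode("ascii")


def write_recording(recording: EEGRecording, path: str | os.PathLike) -> None:
    """Write a recording as a 16-bit EDF file.

    Samples are quantized per channel to the symmetric physical range
    ``[-A, A]`` where ``A`` covers the channel's maximum absolute
    amplitude, so the round-trip error is at most one quantization step
    ``2A / (2^16 - 1)``.
    """
    n_ch, n_samples = recording.data.shape
    fs = recording.fs
    # one record per second when possible, else a single long record
    if abs(fs - round(fs)) < 1e-9 and n_samples % int(round(fs)) == 0:
        spr = int(round(fs))  # samples per record per signal
        record_dur = 1.0
    else:
        spr = n_samples
        record_dur = n_samples / fs
    n_records = n_samples // spr

    phys_max = np.maximum(np.ceil(np.abs(recording.data).max(axis=1)), 1.0)
    phys_min = -phys_max
    scale = (phys_max - phys_min) / (_DIG_MAX - _DIG_MIN)
    digital = np.round((recording.data - phys_min[:, None]) / scale[:, None]) + _DIG_MIN
    digital = np.clip(digital, _DIG_MIN, _DIG_MAX).astype("<i2")

    header_bytes = 256 * (n_ch + 1)
    patient = f"{recording.subject_id} {recording.group}"
    dur_str = f"{record_dur:g}"
    if len(dur_str) > 8:
        dur_str = f"{record_dur:.6f}"[:8]

    with open(path, "wb") as f:
        f.write(_ascii("0", 8))
        f.write(_ascii(patient, 80))
        f.write(_ascii("synthetic resting EEG", 80))
        f.write(_ascii("01.01.00", 8))
        f.write(_ascii("00.00.00", 8))
        f.write(_ascii(str(header_bytes), 8))
        f.write(_ascii("", 44))
        f.write(_ascii(str(n_records), 8))
        f.write(_ascii(dur_str, 8))
        f.write(_ascii(str(n_ch), 4))
        for name in recording.channel_names:
            f.write(_ascii(str(name), 16))
        for _ in range(n_ch):
            f.write(_ascii("AgAgCl electrode", 80))
        for _ in range(n_ch):
            f.write(_ascii("uV", 8))
        for v in phys_min:
            f.write(_ascii(f"{v:g}"[:8], 8))
        for v in phys_max:
            f.write(_ascii(f"{v:g}"[:8], 8))
        for _ in range(n_ch):
            f.write(_ascii(str(_DIG_MIN), 8))
        for _ in range(n_ch):
            f.write(_ascii(str(_DIG_MAX), 8))
        for _ in range(n_ch):
            f.write(_ascii("", 80))
        for _ in range(n_ch):
            f.write(_ascii(str(spr), 8))
        for _ in range(n_ch):
            f.write(_ascii("", 32))
        # data records: channel-blocked int16, little endian
        for r in range(n_records):
            block = digital[:, r * spr : (r + 1) * spr]
            f.write(block.tobytes())


def _header_field(raw: bytes, start: int, width: int) -> str:
    return raw[start : start + width].decode("ascii", errors="replace").strip()


def _validate_header(path: str | os.PathLike) -> tuple[str, str]:
    """Light structural validation of the fixed EDF header.

    Returns the patient and recording identification strings.  Raises
    :class:`EDFParseError` naming the first offending header field.
    """
    with open(path, "rb") as f:
        raw = f.read(256)
    if len(raw) < 256:
        raise EDFParseError("header: file shorter than the 256-byte fixed header")
    version = _header_field(raw, 0, 8)
    if version != "0":
        raise EDFParseError(f"version: expected '0', got {version!r}")
    for name, start, width in (
        ("number of bytes in header", 184, 8),
        ("number of data records", 236, 8),
        ("number of signals", 252, 4),
    ):
        text = _header_field(raw, start, width)
        try:
            value = int(text)
        except ValueError:
            raise EDFParseError(f"{name}: not an integer ({text!r})") from None
        if value <= 0 and name != "number of data records":
            raise EDFParseError(f"{name}: must be positive, got {value}")
    ns = int(_header_field(raw, 252, 4))
    declared = int(_header_field(raw, 184, 8))
    if declared != 256 * (ns + 1):
        raise EDFParseError(
            f"number of bytes in header: declared {declared}, "
            f"expected {256 * (ns + 1)} for {ns} signals"
        )
    return _header_field(raw, 8, 80), _header_field(raw, 88, 80)


def read_recording(
    path: str | os.PathLike,
    expected_channels: Optional[Sequence[str]] = None,
) -> EEGRecording:
    """Read an EDF file into an :class:`EEGRecording` (data in µV).

    If ``expected_channels`` is given, a missing channel raises a
    ``ValueError`` listing every absent name.
    """
    import mne

    patient, _ = _validate_header(path)
    raw = mne.io.read_raw_edf(os.fspath(path), preload=True, verbose="error")
    names = list(raw.ch_names)
    if expected_channels is not None:
        missing = [c for c in expected_channels if c not in names]
        if missing:
            raise ValueError(f"EDF file {path} is missing expected channels: {missing}")
    data_uv = raw.get_data() * 1e6  # MNE returns volts

    tokens = patient.split()
    subject_id = tokens[0] if tokens else "unknown"
    group = tokens[1] if len(tokens) > 1 and tokens[1] in GROUPS else "unknown"
    return EEGRecording(
        subject_id=subject_id,
        group=group,
        channel_names=tuple(names),
        fs=float(raw.info["sfreq"]),
        data=data_uv,
    )
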