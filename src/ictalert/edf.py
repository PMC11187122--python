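"""EDF (European Data Format) output and input.

Writing is done by a small self-contained 16-bit EDF writer (one-second
data records, per-channel physical ranges taken from the data).  Reading
goes through :mod:`mne`, which also serves as an independent check that
the files we write are standard-conformant.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .preprocess import Recording

__all__ = ["write_edf", "read_edf", "TEN_TWENTY_19"]

#: standard 10-20 labels for a 19-electrode montage
TEN_TWENTY_19 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz",
    "C4", "T8", "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
]

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, rec: Recording, patient_id: str = "X") -> Path:
    """Write a recording as 16-bit EDF with one-second data records.

    ``rec.fs`` must be a positive integer.  A trailing partial second is
    dropped (with a warning).  Physical min/max per channel are set from
    the data range, so the quantisation step is ``range / 65535``.
    """
    path = Path(path)
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9 or fs <= 0:
        raise ValueError("EDF writer requires an integer sampling rate")
    fs = int(round(fs))
    n_ch = rec.n_channels
    n_records = rec.n_samples // fs
    if n_records * fs != rec.n_samples:
        warnings.warn("signal not a whole number of seconds; trailing samples dropped", stacklevel=2)
    if n_records == 0:
        raise ValueError("recording shorter than one data record")

    sig = np.asarray(rec.signal[:, : n_records * fs], dtype=np.float64)
    pmax = np.abs(sig).max(axis=1)
    pmax = np.where(pmax > 0, pmax, 1.0)
    pmin = -pmax
    scale = (_DIG_MAX - _DIG_MIN) / (pmax - pmin)
    digital = np.clip(
        np.round((sig - pmin[:, None]) * scale[:, None] + _DIG_MIN), _DIG_MIN, _DIG_MAX
    ).astype("<i2")

    header = b"".join(
        [
            _field(0, 8),  # version
            _field(patient_id, 80),
            _field("recording", 80),
            _field("01.01.00", 8),
            _field("00.00.00", 8),
            _field(256 * (1 + n_ch), 8),
            _field("", 44),
            _field(n_records, 8),
            _field(1, 8),  # record duration, seconds
            _field(n_ch, 4),
        ]
    )
    labels = rec.channel_names
    sig_header = b"".join(
        [
            b"".join(_field(f"EEG {labels[c]}", 16) for c in range(n_ch)),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field("uV", 8) for _ in range(n_ch)),
            b"".join(_field(f"{pmin[c]:.6g}"[:8], 8) for c in range(n_ch)),
            b"".join(_field(f"{pmax[c]:.6g}"[:8], 8) for c in range(n_ch)),
            b"".join(_field(_DIG_MIN, 8) for _ in range(n_ch)),
            b"".join(_field(_DIG_MAX, 8) for _ in range(n_ch)),
            b"".join(_field("", 80) for _ in range(n_ch)),
            b"".join(_field(fs, 8) for _ in range(n_ch)),
            b"".join(_field("", 32) for _ in range(n_ch)),
        ]
    )
    # records: for each second, all samples of channel 0, then channel 1, ...
    records = digital.reshape(n_ch, n_records, fs).transpose(1, 0, 2)
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig_header)
        fh.write(np.ascontiguousarray(records).tobytes())
    return path


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file into a :class:`Recording` (µV) via mne."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    signal = raw.get_data() * 1e6  # volts -> µV
    names = [n.removeprefix("EEG ").strip() for n in raw.ch_names]
    return Recording(
        signal=signal.astype(np.float32),
        fs=float(raw.info["sfreq"]),
        channel_names=names,
    )
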