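"""Raw EEG conditioning: resampling, filtering, artifact masking, windowing.

The downstream classifier consumes standardized, non-overlapping 10-s
windows sampled at 256 Hz.  All timestamps are seconds from recording
start and intervals are half-open ``[start, end)``.  Validity is tracked
as a per-sample boolean mask: samples rejected as artifacts (or falling
in acquisition gaps) stay in the signal array but are flagged invalid, and
windows containing too many invalid samples are dropped from analysis —
the alarm layer later treats those dropped windows as gaps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

__all__ = [
    "Recording",
    "WindowSet",
    "NormStats",
    "resample",
    "filter_eeg",
    "reject_artifacts",
    "segment",
    "compute_norm_stats",
    "standardize",
    "SD_FLOOR",
    "WINDOW_SECONDS",
    "TARGET_FS",
]

#: sd floor (µV) applied when standardizing, so flat channels cannot blow up
SD_FLOOR = 1e-6
#: analysis window length in seconds
WINDOW_SECONDS = 10.0
#: working sampling rate of the pipeline
TARGET_FS = 256.0


@dataclass
class Recording:
    """Continuous multichannel EEG.

    ``signal`` is (channels, samples) in µV; ``valid_mask`` is one boolean
    per sample shared across channels.
    """

    signal: np.ndarray
    fs: float
    t0: float = 0.0
    channel_names: list[str] = field(default_factory=list)
    valid_mask: np.ndarray | None = None

    def __post_init__(self):
        self.signal = np.atleast_2d(np.asarray(self.signal))
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.signal.shape[1], dtype=bool)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != (self.signal.shape[1],):
            raise ValueError("valid_mask length must equal number of samples")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.signal.shape[0])]

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class NormStats:
    """Per-channel standardization statistics and their provenance."""

    mean: np.ndarray
    sd: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.sd = np.maximum(np.asarray(self.sd, dtype=np.float64), SD_FLOOR)


@dataclass
class WindowSet:
    """Non-overlapping fixed-length windows cut from one recording.

    ``windows`` has shape (n_windows, channels, window_samples) and may be
    a view into the recording's signal buffer.
    """

    windows: np.ndarray
    start_times: np.ndarray
    valid: np.ndarray
    fs: float = TARGET_FS
    norm_stats: NormStats | None = None

    def __post_init__(self):
        self.start_times = np.asarray(self.start_times, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.start_times) > 1 and not np.all(np.diff(self.start_times) > 0):
            raise ValueError("window start times must be strictly increasing")

    def __len__(self) -> int:
        return self.windows.shape[0]

    @property
    def window_seconds(self) -> float:
        return self.windows.shape[2] / self.fs


def resample(rec: Recording, target_fs: float = TARGET_FS, max_denominator: int = 10000) -> Recording:
    """Polyphase resampling of all channels to ``target_fs``.

    The rational approximation of ``target_fs / fs`` must be exact to one
    part in 1e-9, otherwise the call is rejected.  The validity mask is
    carried over by nearest-neighbour lookup.
    """
    if target_fs <= 0:
        raise ValueError("target_fs must be positive")
    if rec.fs == target_fs:
        return rec
    frac = Fraction(target_fs / rec.fs).limit_denominator(max_denominator)
    if abs(float(frac) - target_fs / rec.fs) > 1e-9:
        raise ValueError(
            f"resampling ratio {target_fs}/{rec.fs} has no rational approximation "
            f"with denominator <= {max_denominator}"
        )
    up, down = frac.numerator, frac.denominator
    out = sps.resample_poly(rec.signal.astype(np.float64), up, down, axis=1).astype(np.float32)
    n_new = out.shape[1]
    src_idx = np.clip(
        np.round(np.arange(n_new) * rec.fs / target_fs).astype(np.int64), 0, rec.n_samples - 1
    )
    return Recording(
        signal=out,
        fs=target_fs,
        t0=rec.t0,
        channel_names=list(rec.channel_names),
        valid_mask=rec.valid_mask[src_idx],
    )


def filter_eeg(
    rec: Recording,
    band: tuple[float, float] = (0.5, 100.0),
    notch: float | None = 50.0,
    order: int = 4,
    notch_q: float = 30.0,
    copy: bool = True,
) -> Recording:
    """Zero-phase band-pass plus optional power-line notch.

    Butterworth band-pass applied with ``sosfiltfilt`` (forward-backward,
    so no phase distortion) followed by an IIR notch.  Length preserved.
    """
    low, high = band
    if not (0 < low < high < rec.fs / 2):
        raise ValueError(f"invalid band {band} for fs={rec.fs}")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    if notch is not None:
        if not (0 < notch < rec.fs / 2):
            raise ValueError(f"invalid notch frequency {notch} for fs={rec.fs}")
        bn, an = sps.iirnotch(notch, notch_q, fs=rec.fs)
    sig = rec.signal.copy() if copy else rec.signal
    for c in range(sig.shape[0]):
        x = sps.sosfiltfilt(sos, sig[c].astype(np.float64))
        if notch is not None:
            x = sps.filtfilt(bn, an, x)
        sig[c] = x.astype(sig.dtype)
    if not copy:
        return rec
    return Recording(
        signal=sig,
        fs=rec.fs,
        t0=rec.t0,
        channel_names=list(rec.channel_names),
        valid_mask=rec.valid_mask.copy(),
    )


def reject_artifacts(rec: Recording, amp_thresh: float = 300.0, pad_s: float = 0.1) -> Recording:
    """Mark high-amplitude samples invalid; signal values are untouched.

    A sample is rejected when any channel exceeds ``amp_thresh`` µV in
    absolute value; the rejection is dilated by ``pad_s`` seconds on each
    side.  The new mask is AND-combined with the existing one.
    """
    if amp_thresh <= 0:
        raise ValueError("amp_thresh must be positive")
    bad = np.any(np.abs(rec.signal) > amp_thresh, axis=0)
    pad = int(round(pad_s * rec.fs))
    if pad > 0 and bad.any():
        kernel = np.ones(2 * pad + 1, dtype=bool)
        bad = np.convolve(bad, kernel, mode="same") > 0
    return Recording(
        signal=rec.signal,
        fs=rec.fs,
        t0=rec.t0,
        channel_names=list(rec.channel_names),
        valid_mask=rec.valid_mask & ~bad,
    )


def segment(
    rec: Recording, window_s: float = WINDOW_SECONDS, min_valid_frac: float = 1.0
) -> WindowSet:
    """Cut a recording into non-overlapping windows.

    A window is valid iff at least ``min_valid_frac`` of its samples are
    valid (default: all of them).  A trailing partial window is dropped.
    Returns an empty WindowSet for recordings shorter than one window.
    """
    wlen = window_s * rec.fs
    if abs(wlen - round(wlen)) > 1e-9:
        raise ValueError(f"window of {window_s}s is not an integer number of samples at fs={rec.fs}")
    wlen = int(round(wlen))
    n = rec.n_samples // wlen
    if n == 0:
        return WindowSet(
            windows=np.empty((0, rec.n_channels, wlen), dtype=rec.signal.dtype),
            start_times=np.empty(0),
            valid=np.empty(0, dtype=bool),
            fs=rec.fs,
        )
    usable = rec.signal[:, : n * wlen]
    windows = usable.reshape(rec.n_channels, n, wlen).transpose(1, 0, 2)
    valid_frac = rec.valid_mask[: n * wlen].reshape(n, wlen).mean(axis=1)
    valid = valid_frac >= min_valid_frac - 1e-12
    start_times = np.arange(n, dtype=np.float64) * window_s
    return WindowSet(windows=windows, start_times=start_times, valid=valid, fs=rec.fs)


def compute_norm_stats(ws: WindowSet, source: str = "") -> NormStats:
    """Per-channel mean and sd over all samples of all valid windows."""
    if not ws.valid.any():
        raise ValueError("cannot compute statistics: no valid windows")
    data = ws.windows[ws.valid]
    mean = data.mean(axis=(0, 2), dtype=np.float64)
    sd = data.std(axis=(0, 2), dtype=np.float64)
    if np.any(sd < SD_FLOOR):
        warnings.warn("near-constant channel: sd floored", stacklevel=2)
    return NormStats(mean=mean, sd=sd, source=source)


def standardize(ws: WindowSet, stats: NormStats) -> WindowSet:
    """Apply (x - mean) / sd per channel; provenance kept in ``norm_stats``."""
    if not (np.all(np.isfinite(stats.mean)) and np.all(np.isfinite(stats.sd))):
        raise ValueError("non-finite standardization statistics")
    if stats.mean.shape[0] != ws.windows.shape[1]:
        raise ValueError(
            f"channel mismatch: stats for {stats.mean.shape[0]} channels, "
            f"windows have {ws.windows.shape[1]}"
        )
    mu = stats.mean.astype(np.float32)[None, :, None]
    sd = stats.sd.astype(np.float32)[None, :, None]
    return WindowSet(
        windows=(ws.windows - mu) / sd,
        start_times=ws.start_times.copy(),
        valid=ws.valid.copy(),
        fs=ws.fs,
        norm_stats=stats,
    )
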