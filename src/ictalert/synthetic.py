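"""Synthetic scalp-EEG generator with a plantable preictal signature.

Real long-term presurgical EEG is not shareable, so every stage of the
pipeline is exercised on simulated recordings that reproduce the
*structural* properties the method depends on: long continuous
multichannel signals at 256 Hz, at least three leading seizures separated
by >= 4.5 h, acquisition gaps, sparse high-amplitude artifacts, and a
statistically detectable preictal change in the 40 min before each onset.

The background model is a sum of four band-limited Gaussian processes
(delta/theta/alpha/beta) whose amplitudes scale as 1/f of the band centre
frequency, giving the characteristic decaying EEG spectrum.  The preictal
signature is a linear ramp of the alpha-band amplitude: over the
``preictal_len`` seconds before each onset the alpha component is scaled
from x1 up to x(1 + strength).  The ramp shape is a simulation choice,
not a claim about real preictal EEG; see docs/methods.md.

All randomness flows from ``SimSpec.seed`` through numpy's PCG64
generator, so identical specs give bit-identical recordings on any
platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .annotate import SeizureAnnotation
from .edf import TEN_TWENTY_19, read_edf, write_edf
from .preprocess import Recording

__all__ = [
    "SimSpec",
    "SyntheticDataset",
    "BANDS",
    "generate_recording",
    "inject_preictal_signature",
    "write_dataset",
    "read_dataset",
]

#: EEG rhythm bands (Hz) mixed into the background, with centre frequencies
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

#: target standard deviation of the background signal, µV
BACKGROUND_STD = 15.0


@dataclass
class SimSpec:
    """Parameters of one simulated patient recording."""

    duration: float  #: seconds
    n_channels: int = 19
    fs: float = 256.0
    seizure_onsets: tuple[float, ...] = ()
    seizure_duration: float = 60.0  #: seconds of (unmodelled) ictal signal
    preictal_len: float = 2400.0  #: seconds of ramp before each onset
    signature_strength: float = 0.0  #: peak fractional alpha-amplitude increase
    signature_band: tuple[float, float] = BANDS["alpha"]
    gap_spec: tuple[tuple[float, float], ...] = ()  #: (start, end) invalid spans, s
    artifact_rate: float = 0.0  #: high-amplitude transients per hour
    seed: int = 0

    def validate(self, leading_only: bool = False, min_lead_gap_s: float = 4.5 * 3600.0) -> None:
        onsets = np.asarray(self.seizure_onsets, dtype=float)
        if len(onsets) > 1 and not np.all(np.diff(onsets) > 0):
            raise ValueError("seizure onsets must be strictly increasing")
        if leading_only and len(onsets) > 1 and np.any(np.diff(onsets) < min_lead_gap_s):
            raise ValueError(f"leading seizures must be >= {min_lead_gap_s} s apart")
        if np.any(onsets < 0) or np.any(onsets > self.duration):
            raise ValueError("seizure onsets must lie within [0, duration]")
        if np.any(onsets < self.preictal_len):
            raise ValueError(
                "each onset must be preceded by at least preictal_len seconds of recording"
            )
        if self.signature_strength < 0:
            raise ValueError("signature_strength must be >= 0")
        gaps = sorted(self.gap_spec)
        for (s0, e0) in gaps:
            if not (0 <= s0 < e0 <= self.duration):
                raise ValueError(f"gap ({s0}, {e0}) outside [0, duration] or empty")
        for (_, e0), (s1, _) in zip(gaps, gaps[1:]):
            if s1 < e0:
                raise ValueError("overlapping gaps")


@dataclass
class SyntheticDataset:
    recording: Recording
    annotations: SeizureAnnotation
    spec: SimSpec
    #: ground-truth injected artifacts as (start_s, duration_s) pairs
    artifact_events: list[tuple[float, float]] = field(default_factory=list)


def _band_filters(fs: float):
    filters = {}
    for name, (lo, hi) in BANDS.items():
        hi = min(hi, 0.45 * fs)
        filters[name] = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return filters


def _band_weights() -> dict[str, float]:
    centres = {name: 0.5 * (lo + hi) for name, (lo, hi) in BANDS.items()}
    w = {name: 1.0 / fc for name, fc in centres.items()}
    norm = np.sqrt(sum(v * v for v in w.values()))
    return {name: BACKGROUND_STD * v / norm for name, v in w.items()}


def generate_recording(spec: SimSpec) -> SyntheticDataset:
    """Simulate one annotated recording according to ``spec``.

    Deterministic given ``spec.seed``.  The validity mask is False inside
    ``gap_spec`` intervals; artifacts are injected into the signal but
    left valid (masking them is the preprocessing stage's job).
    """
    spec.validate()
    fs = spec.fs
    n_samples = int(round(spec.duration * fs))
    rng = np.random.default_rng(spec.seed)
    filters = _band_filters(fs)
    weights = _band_weights()

    signal = np.empty((spec.n_channels, n_samples), dtype=np.float32)
    for c in range(spec.n_channels):
        acc = np.zeros(n_samples)
        for name, sos in filters.items():
            band = sps.sosfiltfilt(sos, rng.standard_normal(n_samples))
            sd = band.std()
            if sd > 0:
                band *= weights[name] / sd
            acc += band
        signal[c] = acc.astype(np.float32)

    # sparse high-amplitude transients (ground truth kept for tests)
    artifact_events: list[tuple[float, float]] = []
    if spec.artifact_rate > 0:
        n_events = rng.poisson(spec.artifact_rate * spec.duration / 3600.0)
        for _ in range(n_events):
            dur = 0.3
            t0 = rng.uniform(0, spec.duration - dur)
            amp = rng.uniform(400.0, 800.0) * rng.choice([-1.0, 1.0])
            ch = rng.integers(spec.n_channels)
            i0 = int(round(t0 * fs))
            n = int(round(dur * fs))
            bump = amp * np.hanning(n)
            signal[ch, i0 : i0 + n] += bump.astype(np.float32)
            artifact_events.append((t0, dur))

    mask = np.ones(n_samples, dtype=bool)
    for (g0, g1) in spec.gap_spec:
        mask[int(round(g0 * fs)) : int(round(g1 * fs))] = False

    names = (
        TEN_TWENTY_19[: spec.n_channels]
        if spec.n_channels <= len(TEN_TWENTY_19)
        else [f"ch{i}" for i in range(spec.n_channels)]
    )
    rec = Recording(signal=signal, fs=fs, channel_names=list(names), valid_mask=mask)
    onsets = np.asarray(spec.seizure_onsets, dtype=float)
    ann = SeizureAnnotation(
        onsets=onsets,
        offsets=np.minimum(onsets + spec.seizure_duration, spec.duration),
        patient_id=f"sim{spec.seed}",
    )
    ds = SyntheticDataset(recording=rec, annotations=ann, spec=spec, artifact_events=artifact_events)
    if spec.signature_strength > 0:
        ds = inject_preictal_signature(ds, spec.signature_strength)
    return ds


def inject_preictal_signature(
    ds: SyntheticDataset, strength: float, band: tuple[float, float] | None = None
) -> SyntheticDataset:
    """Ramp the chosen band's amplitude over each pre-onset span.

    In the ``preictal_len`` seconds before every onset the band component
    (extracted with a zero-phase band-pass) is re-added with a weight that
    grows linearly from 0 at span start to ``strength`` at onset, i.e. the
    band amplitude is multiplied by up to ``1 + strength``.  The signal is
    untouched outside those spans.  ``strength = 0`` returns an identical
    copy.
    """
    if strength < 0:
        raise ValueError("signature strength must be >= 0")
    rec = ds.recording
    out = rec.signal.copy()
    if strength > 0 and len(ds.annotations) > 0:
        fs = rec.fs
        lo, hi = band if band is not None else ds.spec.signature_band
        sos = sps.butter(4, [lo, min(hi, 0.45 * fs)], btype="bandpass", fs=fs, output="sos")
        pad = int(round(5.0 * fs))  # filter context outside the span
        span_len = int(round(ds.spec.preictal_len * fs))
        for onset in ds.annotations.onsets:
            i1 = int(round(onset * fs))
            i0 = i1 - span_len
            if i0 < 0:
                raise ValueError("onset closer than preictal_len to recording start")
            j0, j1 = max(0, i0 - pad), min(rec.n_samples, i1 + pad)
            ramp = (np.arange(i0, i1) - i0) / span_len  # 0 -> 1 across the span
            for c in range(rec.n_channels):
                comp = sps.sosfiltfilt(sos, out[c, j0:j1].astype(np.float64))
                out[c, i0:i1] += (strength * ramp * comp[i0 - j0 : i1 - j0]).astype(np.float32)
    new_rec = Recording(
        signal=out,
        fs=rec.fs,
        t0=rec.t0,
        channel_names=list(rec.channel_names),
        valid_mask=rec.valid_mask.copy(),
    )
    return SyntheticDataset(
        recording=new_rec,
        annotations=ds.annotations,
        spec=replace(ds.spec, signature_strength=strength),
        artifact_events=list(ds.artifact_events),
    )


def write_dataset(ds: SyntheticDataset, path_stem: str | Path) -> dict[str, Path]:
    """Write ``<stem>.edf`` plus annotation (and, if any, gap) CSV tables.

    The annotation CSV has columns ``patient_id,onset_s,offset_s``; the gap
    CSV has ``start_s,end_s``.  Round-tripping the EDF reproduces the
    signal to within one 16-bit quantisation step.
    """
    stem = Path(path_stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    paths = {"edf": write_edf(stem.with_suffix(".edf"), ds.recording, ds.annotations.patient_id)}
    ann = pd.DataFrame(
        {
            "patient_id": ds.annotations.patient_id,
            "onset_s": ds.annotations.onsets,
            "offset_s": ds.annotations.offsets,
        }
    )
    paths["annotations"] = Path(f"{stem}_annotations.csv")
    ann.to_csv(paths["annotations"], index=False)
    if ds.spec.gap_spec:
        gaps = pd.DataFrame(ds.spec.gap_spec, columns=["start_s", "end_s"])
        paths["gaps"] = Path(f"{stem}_gaps.csv")
        gaps.to_csv(paths["gaps"], index=False)
    return paths


def read_dataset(path_stem: str | Path) -> tuple[Recording, SeizureAnnotation]:
    """Read back a dataset written by :func:`write_dataset`."""
    stem = Path(path_stem)
    rec = read_edf(stem.with_suffix(".edf"))
    ann_df = pd.read_csv(f"{stem}_annotations.csv")
    gaps_path = Path(f"{stem}_gaps.csv")
    if gaps_path.exists():
        gaps = pd.read_csv(gaps_path)
        for s, e in zip(gaps["start_s"], gaps["end_s"]):
            rec.valid_mask[int(round(s * rec.fs)) : int(round(e * rec.fs))] = False
    patient = str(ann_df["patient_id"].iloc[0]) if len(ann_df) else "patient"
    return rec, SeizureAnnotation(
        onsets=ann_df["onset_s"].to_numpy(),
        offsets=ann_df["offset_s"].to_numpy(),
        patient_id=patient,
    )
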