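"""Seizure bookkeeping: leading-seizure selection, labelling, splits.

The labelling scheme follows the SOP/SPH convention: an alarm must come
at least SPH (10 min) before the seizure, and the seizure is expected
within the following SOP (30 min).  The preictal period is therefore the
SOP+SPH = 40 min before onset.  For training, only the 4 h before each
onset are used: the first 3 h 20 min as interictal, the next 30 min (the
SOP span) as preictal, and the final SPH discarded.  Data from onset to
30 min after onset is excluded everywhere (ictal + postictal).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import train_test_split

from .preprocess import WindowSet

__all__ = [
    "SeizureAnnotation",
    "HorizonConfig",
    "LabeledWindows",
    "TrainingSelection",
    "SplitPlan",
    "INTERICTAL",
    "PREICTAL",
    "EXCLUDED",
    "select_leading_seizures",
    "label_windows",
    "build_training_selection",
    "chronological_split",
]

INTERICTAL = 0
PREICTAL = 1
EXCLUDED = -1

MIN_LEADING_SEIZURES = 3


@dataclass
class SeizureAnnotation:
    """Ordered seizure onset/offset times (seconds from recording start)."""

    onsets: np.ndarray
    offsets: np.ndarray | None = None
    patient_id: str = "patient"

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=np.float64)
        if self.offsets is None:
            self.offsets = self.onsets.copy()
        self.offsets = np.asarray(self.offsets, dtype=np.float64)
        if len(self.onsets) != len(self.offsets):
            raise ValueError("onsets and offsets must have equal length")
        if len(self.onsets) > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("seizure onsets must be strictly increasing")
        if np.any(self.offsets < self.onsets):
            raise ValueError("offset before onset")

    def __len__(self) -> int:
        return len(self.onsets)


@dataclass
class HorizonConfig:
    """Timing constants of the prediction task (defaults in the units noted)."""

    sop_min: float = 30.0  #: seizure occurrence period, minutes
    sph_min: float = 10.0  #: seizure prediction horizon, minutes
    train_window_h: float = 4.0  #: pre-onset span used for training, hours
    post_ictal_exclusion_min: float = 30.0  #: excluded after each onset, minutes
    min_lead_gap_h: float = 4.5  #: minimum onset-to-onset gap of a leading seizure, hours

    def __post_init__(self):
        for name in (
            "sop_min",
            "sph_min",
            "train_window_h",
            "post_ictal_exclusion_min",
            "min_lead_gap_h",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def sop_s(self) -> float:
        return self.sop_min * 60.0

    @property
    def sph_s(self) -> float:
        return self.sph_min * 60.0

    @property
    def preictal_s(self) -> float:
        """SOP + SPH, the labelled preictal span before each onset."""
        return self.sop_s + self.sph_s

    @property
    def refractory_s(self) -> float:
        """Post-alarm suppression time = SOP + SPH."""
        return self.preictal_s

    @property
    def train_window_s(self) -> float:
        return self.train_window_h * 3600.0

    @property
    def post_ictal_exclusion_s(self) -> float:
        return self.post_ictal_exclusion_min * 60.0

    @property
    def min_lead_gap_s(self) -> float:
        return self.min_lead_gap_h * 3600.0


@dataclass
class LabeledWindows:
    """A WindowSet plus one label per window."""

    windows: WindowSet
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(self.windows):
            raise ValueError("one label per window required")


@dataclass
class TrainingSelection:
    """Window indices and labels chosen for fitting one patient's model."""

    indices: np.ndarray
    labels: np.ndarray
    seizure_of: np.ndarray  # training-seizure index each window was drawn for


@dataclass
class SplitPlan:
    """Chronological seizure-level split with an 80/20 training holdout."""

    train_seizures: np.ndarray
    test_seizures: np.ndarray
    train_idx: np.ndarray
    train_labels: np.ndarray
    val_idx: np.ndarray
    val_labels: np.ndarray
    test_segments: list[tuple[float, float]] = field(default_factory=list)
    seed: int = 0


def select_leading_seizures(ann: SeizureAnnotation, cfg: HorizonConfig) -> SeizureAnnotation:
    """Greedy scan keeping seizures whose onset is >= min_lead_gap after the
    previously kept onset; the first seizure is always kept.

    Warns when fewer than three leading seizures remain (the patient does
    not meet the study's inclusion criterion).
    """
    if len(ann) == 0:
        raise ValueError("no seizures annotated")
    keep = [0]
    for i in range(1, len(ann)):
        if ann.onsets[i] - ann.onsets[keep[-1]] >= cfg.min_lead_gap_s:
            keep.append(i)
    if len(keep) < MIN_LEADING_SEIZURES:
        warnings.warn(
            f"patient {ann.patient_id}: only {len(keep)} leading seizure(s); "
            f"at least {MIN_LEADING_SEIZURES} required for a conformant split",
            stacklevel=2,
        )
    keep = np.asarray(keep)
    return SeizureAnnotation(
        onsets=ann.onsets[keep], offsets=ann.offsets[keep], patient_id=ann.patient_id
    )


def is_conformant(ann: SeizureAnnotation) -> bool:
    return len(ann) >= MIN_LEADING_SEIZURES


def label_windows(ws: WindowSet, ann: SeizureAnnotation, cfg: HorizonConfig) -> LabeledWindows:
    """Label every window interictal / preictal / excluded.

    A window is preictal iff its start lies in ``[onset - (SOP+SPH), onset)``;
    excluded iff it overlaps ``[onset, onset + post-ictal exclusion]``;
    otherwise interictal.  Exclusion wins over preictal when both apply
    (possible only for non-leading seizure pairs).
    """
    starts = ws.start_times
    wlen = ws.window_seconds
    labels = np.full(len(ws), INTERICTAL, dtype=np.int8)
    for onset in ann.onsets:
        pre = (starts >= onset - cfg.preictal_s) & (starts < onset)
        labels[pre] = PREICTAL
    for onset in ann.onsets:
        excl = (starts < onset + cfg.post_ictal_exclusion_s) & (starts + wlen > onset)
        labels[excl] = EXCLUDED
    return LabeledWindows(windows=ws, labels=labels)


def build_training_selection(
    lw: LabeledWindows,
    ann: SeizureAnnotation,
    cfg: HorizonConfig,
    seizure_indices: np.ndarray | None = None,
    max_interictal_per_seizure: int | None = None,
    seed: int = 0,
) -> TrainingSelection:
    """Pick the training windows for the given (training) seizures.

    Per seizure: windows starting in ``[onset - 4 h, onset - (SOP+SPH))``
    become interictal, windows in ``[onset - (SOP+SPH), onset - SPH)``
    become preictal (the SOP span), and the final SPH is dropped.  Only
    valid windows are used.  ``max_interictal_per_seizure`` optionally
    subsamples the interictal class (seeded) for reduced-scale fits.
    """
    if seizure_indices is None:
        seizure_indices = np.arange(len(ann))
    starts = lw.windows.start_times
    valid = lw.windows.valid
    rng = np.random.default_rng(seed)
    idx_parts, label_parts, seiz_parts = [], [], []
    for si in np.asarray(seizure_indices):
        onset = ann.onsets[si]
        inter = np.flatnonzero(
            valid & (starts >= onset - cfg.train_window_s) & (starts < onset - cfg.preictal_s)
        )
        pre = np.flatnonzero(
            valid & (starts >= onset - cfg.preictal_s) & (starts < onset - cfg.sph_s)
        )
        if len(pre) == 0:
            warnings.warn(
                f"seizure {si} at {onset:.0f}s has no valid preictal training windows",
                stacklevel=2,
            )
        if max_interictal_per_seizure is not None and len(inter) > max_interictal_per_seizure:
            inter = np.sort(rng.choice(inter, size=max_interictal_per_seizure, replace=False))
        idx_parts.extend([inter, pre])
        label_parts.extend(
            [np.full(len(inter), INTERICTAL, np.int8), np.full(len(pre), PREICTAL, np.int8)]
        )
        seiz_parts.extend([np.full(len(inter), si), np.full(len(pre), si)])
    indices = np.concatenate(idx_parts) if idx_parts else np.empty(0, dtype=int)
    return TrainingSelection(
        indices=indices,
        labels=np.concatenate(label_parts) if label_parts else np.empty(0, dtype=np.int8),
        seizure_of=np.concatenate(seiz_parts) if seiz_parts else np.empty(0, dtype=int),
    )


def chronological_split(
    ann: SeizureAnnotation,
    lw: LabeledWindows,
    cfg: HorizonConfig,
    train_frac: float = 0.6,
    val_frac: float = 0.2,
    seed: int = 0,
    max_interictal_per_seizure: int | None = None,
) -> SplitPlan:
    """Seizure-level chronological split plus label-stratified 80/20 holdout.

    The first ``ceil(train_frac * n)`` seizures train the model; the rest
    are test seizures.  Each test seizure's segment runs from 30 min after
    the previous onset up to its own onset.  Training windows are split
    80/20 into train/validation, stratified by label and seeded.
    """
    n = len(ann)
    if n < MIN_LEADING_SEIZURES:
        raise ValueError(f"need at least {MIN_LEADING_SEIZURES} leading seizures, got {n}")
    n_train = math.ceil(train_frac * n)
    train_seizures = np.arange(n_train)
    test_seizures = np.arange(n_train, n)
    selection = build_training_selection(
        lw,
        ann,
        cfg,
        seizure_indices=train_seizures,
        max_interictal_per_seizure=max_interictal_per_seizure,
        seed=seed,
    )
    if len(np.unique(selection.labels)) < 2:
        raise ValueError("training selection does not contain both classes")
    tr, va = train_test_split(
        np.arange(len(selection.indices)),
        test_size=val_frac,
        random_state=seed,
        stratify=selection.labels,
    )
    tr.sort()
    va.sort()
    segments = [
        (float(ann.onsets[i - 1] + cfg.post_ictal_exclusion_s), float(ann.onsets[i]))
        for i in test_seizures
    ]
    plan = SplitPlan(
        train_seizures=train_seizures,
        test_seizures=test_seizures,
        train_idx=selection.indices[tr],
        train_labels=selection.labels[tr],
        val_idx=selection.indices[va],
        val_labels=selection.labels[va],
        test_segments=segments,
        seed=seed,
    )
    _assert_no_leakage(plan, lw)
    return plan


def _assert_no_leakage(plan: SplitPlan, lw: LabeledWindows) -> None:
    """No training/validation window may fall inside any test segment."""
    starts = lw.windows.start_times
    used = np.concatenate([plan.train_idx, plan.val_idx])
    for lo, hi in plan.test_segments:
        inside = (starts[used] >= lo) & (starts[used] < hi)
        if inside.any():
            raise AssertionError("temporal leakage: training window inside a test segment")
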