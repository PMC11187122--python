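"""Alarm adjudication, SS / FPR/h metrics, surrogate chance-level test,
and the paired comparison between training approaches.

An alarm at time ``t`` is *true* when some test-seizure onset falls in
``[t + SPH, t + SPH + SOP]`` — the alarm gave at least the minimum
warning time and the seizure arrived within the occurrence period.

Seizure sensitivity:   SS = #predicted test seizures / #test seizures.
False prediction rate: FPR/h = #FA / (interictal_hours - #FA * refractory_hours),
with the interictal duration measured on valid recorded test time only,
excluding the preictal span before each test seizure.

The chance-level (surrogate) test redraws every test-seizure onset
uniformly within its test segment (no closer than SOP+SPH to the segment
start), re-scores the *same* alarms against the shifted onsets, and
reports the Monte-Carlo rank p-value

    p = (1 + #{surrogate SS >= observed SS}) / (n_surrogates + 1).

With the default n_surrogates = 1/alpha - 1 = 19 this is an exact
level-alpha test for continuous statistics under the null that alarm
times carry no information about seizure times.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .alarms import Alarm
from .annotate import HorizonConfig

__all__ = [
    "SurrogateConfig",
    "AdjudicationResult",
    "SurrogateResult",
    "PatientReport",
    "adjudicate_alarms",
    "seizure_sensitivity",
    "interictal_hours",
    "fpr_per_hour",
    "surrogate_analysis",
    "compare_approaches",
    "evaluate_patient",
]


@dataclass
class SurrogateConfig:
    n_surrogates: int = 19  #: 1/alpha - 1 gives an exact level-alpha rank test
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_surrogates < 2:
            raise ValueError("need at least 2 surrogates")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class AdjudicationResult:
    alarms: list[Alarm]
    predicted: np.ndarray  #: one boolean per test seizure

    @property
    def n_true(self) -> int:
        return sum(a.kind == "true" for a in self.alarms)

    @property
    def n_false(self) -> int:
        return sum(a.kind == "false" for a in self.alarms)


def adjudicate_alarms(
    alarms: list[Alarm], onsets: np.ndarray, cfg: HorizonConfig | None = None
) -> AdjudicationResult:
    """Assign true/false to each alarm and mark which seizures are predicted."""
    cfg = cfg or HorizonConfig()
    onsets = np.asarray(onsets, dtype=np.float64)
    predicted = np.zeros(len(onsets), dtype=bool)
    out = []
    for a in alarms:
        hits = (onsets >= a.time + cfg.sph_s) & (onsets <= a.time + cfg.sph_s + cfg.sop_s)
        kind = "true" if hits.any() else "false"
        predicted |= hits
        out.append(Alarm(time=a.time, kind=kind))
    return AdjudicationResult(alarms=out, predicted=predicted)


def seizure_sensitivity(adj: AdjudicationResult) -> float:
    """Fraction of test seizures preceded by a correctly timed alarm."""
    if len(adj.predicted) == 0:
        raise ValueError("seizure sensitivity undefined without test seizures")
    return float(adj.predicted.mean())


def interictal_hours(
    window_starts: np.ndarray,
    window_valid: np.ndarray,
    onsets: np.ndarray,
    cfg: HorizonConfig | None = None,
    window_s: float = 10.0,
) -> float:
    """Valid recorded test time outside the preictal spans, in hours."""
    cfg = cfg or HorizonConfig()
    starts = np.asarray(window_starts, dtype=np.float64)
    keep = np.asarray(window_valid, dtype=bool).copy()
    for onset in np.asarray(onsets, dtype=np.float64):
        keep &= ~((starts >= onset - cfg.preictal_s) & (starts < onset))
    return float(keep.sum() * window_s / 3600.0)


def fpr_per_hour(
    n_false: int, interictal_h: float, cfg: HorizonConfig | None = None
) -> float:
    """False alarms per hour with false-alarm refractory time discounted."""
    cfg = cfg or HorizonConfig()
    denom = interictal_h - n_false * cfg.refractory_s / 3600.0
    if denom <= 0:
        raise ValueError(
            f"non-positive effective interictal duration ({denom:.3f} h) for "
            f"{n_false} false alarms over {interictal_h:.3f} h"
        )
    return n_false / denom


@dataclass
class SurrogateResult:
    observed_ss: float
    surrogate_ss: np.ndarray
    p_value: float
    above_chance: bool


def _mean_ss(alarm_sets: list[list[Alarm]], onsets: np.ndarray, cfg: HorizonConfig) -> float:
    return float(
        np.mean([seizure_sensitivity(adjudicate_alarms(a, onsets, cfg)) for a in alarm_sets])
    )


def surrogate_analysis(
    alarm_sets: list[list[Alarm]] | list[Alarm],
    onsets: np.ndarray,
    test_segments: list[tuple[float, float]],
    cfg: HorizonConfig | None = None,
    scfg: SurrogateConfig | None = None,
) -> SurrogateResult:
    """Monte-Carlo chance-level test on fixed alarms.

    ``alarm_sets`` may be a single alarm list or one list per training
    repeat; the statistic is the mean SS over the sets.  Each surrogate
    redraws every onset uniformly in ``[segment start + SOP + SPH,
    segment end]``; segments too short for that placement are dropped
    with a warning.  The procedure reads only alarm times and segments —
    never the model.
    """
    cfg = cfg or HorizonConfig()
    scfg = scfg or SurrogateConfig()
    if alarm_sets and isinstance(alarm_sets[0], Alarm):
        alarm_sets = [alarm_sets]  # type: ignore[list-item]
    onsets = np.asarray(onsets, dtype=np.float64)
    if len(onsets) != len(test_segments):
        raise ValueError("one test segment per test seizure required")
    if len(onsets) == 0:
        raise ValueError("surrogate analysis requires at least one test seizure")

    usable = []
    for i, (lo, hi) in enumerate(test_segments):
        if lo + cfg.preictal_s > hi:
            warnings.warn(
                f"test segment {i} ({lo:.0f}-{hi:.0f}s) too short to place a "
                "surrogate onset; seizure dropped from the surrogate test",
                stacklevel=2,
            )
        else:
            usable.append(i)
    if not usable:
        raise ValueError("no test segment can hold a surrogate onset")
    onsets_u = onsets[usable]
    segs = [test_segments[i] for i in usable]

    observed = _mean_ss(alarm_sets, onsets_u, cfg)
    rng = np.random.default_rng(scfg.seed)
    surr = np.empty(scfg.n_surrogates)
    for s in range(scfg.n_surrogates):
        shifted = np.array(
            [rng.uniform(lo + cfg.preictal_s, hi) for lo, hi in segs]
        )
        surr[s] = _mean_ss(alarm_sets, shifted, cfg)
    p = (1 + int(np.sum(surr >= observed))) / (scfg.n_surrogates + 1)
    # rank-test convention: with n = 1/alpha - 1 surrogates the smallest
    # achievable p is exactly alpha, and that outcome rejects
    return SurrogateResult(
        observed_ss=observed,
        surrogate_ss=surr,
        p_value=p,
        above_chance=bool(p <= scfg.alpha + 1e-12),
    )


def compare_approaches(
    metric_a: np.ndarray,
    metric_b: np.ndarray,
    alternative: str = "greater",
) -> float:
    """One-tailed Wilcoxon signed-rank p-value on paired per-patient means.

    ``alternative='greater'`` tests whether approach A's values exceed
    approach B's (use 'less' for metrics where lower is better, e.g.
    FPR/h).  All-zero differences return p = 1 with a warning.
    """
    a = np.asarray(metric_a, dtype=np.float64)
    b = np.asarray(metric_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs for the signed-rank comparison")
    if np.all(a == b):
        warnings.warn("all paired differences are zero; returning p = 1", stacklevel=2)
        return 1.0
    res = stats.wilcoxon(a, b, alternative=alternative, zero_method="wilcox")
    return float(res.pvalue)


@dataclass
class PatientReport:
    """Evaluation of one patient: per-repeat metrics plus the chance test."""

    patient_id: str
    mode: str
    ss: list[float] = field(default_factory=list)
    fpr_h: list[float] = field(default_factory=list)
    alarms: list[list[Alarm]] = field(default_factory=list)
    mean_ss: float = float("nan")
    mean_fpr_h: float = float("nan")
    surrogate_p: float = float("nan")
    above_chance: bool = False

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "mode": self.mode,
            "ss_per_repeat": self.ss,
            "fpr_h_per_repeat": self.fpr_h,
            "mean_ss": self.mean_ss,
            "mean_fpr_h": self.mean_fpr_h,
            "surrogate_p": self.surrogate_p,
            "above_chance": self.above_chance,
            "alarm_times": [[a.time for a in rep] for rep in self.alarms],
            "alarm_kinds": [[a.kind for a in rep] for rep in self.alarms],
        }


def evaluate_patient(
    patient_id: str,
    mode: str,
    alarm_sets: list[list[Alarm]],
    onsets: np.ndarray,
    test_segments: list[tuple[float, float]],
    interictal_h: float,
    cfg: HorizonConfig | None = None,
    scfg: SurrogateConfig | None = None,
) -> PatientReport:
    """Adjudicate each repeat's alarms, average SS and FPR/h over repeats,
    and run the surrogate chance test on the pooled alarm sets."""
    cfg = cfg or HorizonConfig()
    report = PatientReport(patient_id=patient_id, mode=mode)
    for alarms in alarm_sets:
        adj = adjudicate_alarms(alarms, onsets, cfg)
        report.alarms.append(adj.alarms)
        report.ss.append(seizure_sensitivity(adj))
        report.fpr_h.append(fpr_per_hour(adj.n_false, interictal_h, cfg))
    report.mean_ss = float(np.mean(report.ss))
    report.mean_fpr_h = float(np.mean(report.fpr_h))
    sres = surrogate_analysis(alarm_sets, onsets, test_segments, cfg, scfg)
    report.surrogate_p = sres.p_value
    report.above_chance = sres.above_chance
    return report
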