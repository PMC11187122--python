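"""Gap-aware firing power and alarm triggering.

The classifier emits one preictal probability ``o[k]`` per 10-s window.
Firing power is the moving average of the last tau outputs, where tau is
the number of windows in one SOP (180 under defaults):

    fp[n] = (1/tau) * sum_{k = n-tau+1}^{n} o[k]

The moving window spans *calendar* time: the series is materialised on
the nominal 10-s grid and any missing or invalid step contributes 0, so
during long acquisition gaps the firing power decays to exactly zero.
An alarm fires when fp crosses the threshold (0.5 by default) from
below, after which alarms are suppressed for one refractory period of
SOP + SPH = 40 min; a new alarm then needs a fresh upward crossing, so a
sustained plateau cannot re-alarm indefinitely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotate import HorizonConfig
from .preprocess import WINDOW_SECONDS

__all__ = [
    "PredictionSeries",
    "FiringPowerSeries",
    "Alarm",
    "firing_power",
    "trigger_alarms",
]


@dataclass
class PredictionSeries:
    """Per-window classifier outputs for one contiguous evaluation span."""

    times: np.ndarray  #: window start times, seconds, strictly increasing
    o: np.ndarray  #: preictal probability per window, in [0, 1]
    valid: np.ndarray | None = None
    window_s: float = WINDOW_SECONDS

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.o = np.asarray(self.o, dtype=np.float64)
        if self.valid is None:
            self.valid = np.ones(len(self.times), dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (len(self.times) == len(self.o) == len(self.valid)):
            raise ValueError("times, o and valid must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.o < 0) | (self.o > 1)):
            raise ValueError("classifier outputs must lie in [0, 1]")


@dataclass
class FiringPowerSeries:
    times: np.ndarray  #: nominal grid times, step = window_s
    fp: np.ndarray  #: firing power in [0, 1]
    tau: int
    warmup: np.ndarray = field(default=None)  #: True while fewer than tau slots seen

    def __post_init__(self):
        if self.warmup is None:
            self.warmup = np.zeros(len(self.times), dtype=bool)


@dataclass
class Alarm:
    time: float
    kind: str | None = None  # "true" / "false", assigned by evaluation


def firing_power(ps: PredictionSeries, cfg: HorizonConfig | None = None) -> FiringPowerSeries:
    """Moving-average firing power on the nominal window grid.

    Steps missing from ``ps.times`` (gaps) and steps flagged invalid
    contribute 0 to the average but still occupy their calendar slot, so
    a gap of >= tau steps drives fp to exactly 0.  The first tau-1 grid
    steps are flagged as warm-up (their average runs over fewer than tau
    real slots); alarm triggering ignores them.
    """
    cfg = cfg or HorizonConfig()
    tau = int(round(cfg.sop_s / ps.window_s))
    if len(ps.times) == 0:
        return FiringPowerSeries(times=np.empty(0), fp=np.empty(0), tau=tau)
    t0 = ps.times[0]
    slots = np.round((ps.times - t0) / ps.window_s).astype(np.int64)
    if len(np.unique(slots)) != len(slots):
        raise ValueError("two windows map to the same 10-s grid slot")
    n_grid = slots[-1] + 1
    o_grid = np.zeros(n_grid)
    o_grid[slots[ps.valid]] = ps.o[ps.valid]
    csum = np.concatenate([[0.0], np.cumsum(o_grid)])
    n = np.arange(n_grid)
    lo = np.maximum(0, n - tau + 1)
    fp = (csum[n + 1] - csum[lo]) / tau
    times = t0 + n * ps.window_s
    return FiringPowerSeries(times=times, fp=fp, tau=tau, warmup=n < tau - 1)


def trigger_alarms(
    fps: FiringPowerSeries, threshold: float = 0.5, cfg: HorizonConfig | None = None
) -> list[Alarm]:
    """Upward-crossing alarm generation with a refractory period.

    The trigger is *armed* at series start and re-armed whenever fp dips
    below ``threshold``; an armed trigger fires at the first non-warm-up
    step with fp >= threshold outside the refractory window and then
    disarms.  A sustained plateau therefore alarms exactly once, and a
    plateau that began during warm-up alarms as soon as warm-up ends.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must lie in (0, 1)")
    cfg = cfg or HorizonConfig()
    refractory = cfg.refractory_s
    alarms: list[Alarm] = []
    armed = True
    last_alarm = -np.inf
    for t, v, warm in zip(fps.times, fps.fp, fps.warmup):
        if v < threshold:
            armed = True
        elif armed and not warm and (t - last_alarm) >= refractory:
            alarms.append(Alarm(time=float(t)))
            last_alarm = t
            armed = False
    return alarms
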