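"""Mechanical sleep-deprivation efficacy and homeostatic rebound metrics.

The protocol emulated here shakes flies awake for the final 6 hours of one
night (the deprivation window ends at lights-on) and quantifies:

* efficacy — sleep minutes remaining inside the deprivation window;
* excess (rebound) sleep — sleep in the first 3 h after lights-on on the
  recovery day minus sleep in the identical clock window following the
  undisturbed baseline night;
* consolidation of rebound sleep — mean duration of sleep bouts initiated
  within the first 2 h of the light phase, recovery versus baseline.

All window sums reuse the per-minute clipping rules of
:mod:`flysomnus.sleep_metrics`; excess sleep is computed per fly and then
averaged (the per-fly form is what group SEMs require).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dam_io import NIGHT, ActivityTrace, Experiment
from .sleep_metrics import (
    SleepBout,
    detect_sleep_bouts,
    phase_windows,
    sleep_indicator,
)


@dataclass(frozen=True)
class DeprivationDesign:
    """Night indices and window lengths of a deprivation experiment.

    ``deprivation_night`` is the cycle whose final ``deprivation_h`` hours
    are mechanically disturbed; ``baseline_night`` is an undisturbed cycle
    used for the clock-matched comparison windows.
    """

    baseline_night: int = 0
    deprivation_night: int = 1
    deprivation_h: float = 6.0
    recovery_h: float = 3.0
    bout_window_min: int = 120

    def __post_init__(self) -> None:
        if self.baseline_night == self.deprivation_night:
            raise ValueError("baseline and deprivation nights must differ")
        if self.deprivation_h <= 0 or self.recovery_h <= 0:
            raise ValueError("window lengths must be positive")


@dataclass
class ReboundResult:
    fly_id: str
    sleep_lost_min: float
    excess_sleep_min: float
    deprivation_sleep_min: float
    baseline_bout_duration_min: float | None
    recovery_bout_duration_min: float | None


def _night_window(trace: ActivityTrace, cycle: int):
    for w in phase_windows(trace):
        if w.phase == NIGHT and w.cycle == cycle:
            return w
    raise ValueError(f"trace {trace.fly_id} has no complete night of cycle {cycle}")


def _windows(trace: ActivityTrace, design: DeprivationDesign):
    """(deprivation, baseline-night-tail, recovery 3h, baseline 3h) windows."""
    dep_night = _night_window(trace, design.deprivation_night)
    base_night = _night_window(trace, design.baseline_night)
    dep_len = int(round(design.deprivation_h * 60))
    rec_len = int(round(design.recovery_h * 60))
    dep_win = (dep_night.stop - dep_len, dep_night.stop)
    base_tail = (base_night.stop - dep_len, base_night.stop)
    rec_win = (dep_night.stop, dep_night.stop + rec_len)
    base_win = (base_night.stop, base_night.stop + rec_len)
    if rec_win[1] > len(trace) or base_win[1] > len(trace):
        raise ValueError(
            f"trace {trace.fly_id} does not span the recovery window"
        )
    return dep_win, base_tail, rec_win, base_win


def _sleep_in(asleep: np.ndarray, window: tuple[int, int]) -> int:
    return int(asleep[window[0]:window[1]].sum())


def _mean_onset_bout_duration(
    bouts: list[SleepBout], start: int, width: int
) -> float | None:
    durs = [b.duration_min for b in bouts if start <= b.onset < start + width]
    return float(np.mean(durs)) if durs else None


def deprivation_efficacy(
    trace: ActivityTrace, design: DeprivationDesign = DeprivationDesign()
) -> float:
    """Sleep minutes inside the deprivation window (0 under forced wake)."""
    dep_win, _, _, _ = _windows(trace, design)
    bouts = detect_sleep_bouts(trace)
    return float(_sleep_in(sleep_indicator(len(trace), bouts), dep_win))


def rebound_excess(
    trace: ActivityTrace, design: DeprivationDesign = DeprivationDesign()
) -> ReboundResult:
    """Per-fly sleep lost to deprivation and excess recovery sleep.

    Windows are clock-aligned between the baseline and recovery days; bouts
    spanning into a window from before it contribute their clipped minutes.
    """
    dep_win, base_tail, rec_win, base_win = _windows(trace, design)
    bouts = detect_sleep_bouts(trace)
    asleep = sleep_indicator(len(trace), bouts)
    dep_sleep = _sleep_in(asleep, dep_win)
    base_mean, rec_mean = recovery_bout_duration(trace, design, bouts=bouts)
    return ReboundResult(
        fly_id=trace.fly_id,
        sleep_lost_min=float(_sleep_in(asleep, base_tail) - dep_sleep),
        excess_sleep_min=float(_sleep_in(asleep, rec_win) - _sleep_in(asleep, base_win)),
        deprivation_sleep_min=float(dep_sleep),
        baseline_bout_duration_min=base_mean,
        recovery_bout_duration_min=rec_mean,
    )


def recovery_bout_duration(
    trace: ActivityTrace,
    design: DeprivationDesign = DeprivationDesign(),
    bouts: list[SleepBout] | None = None,
) -> tuple[float | None, float | None]:
    """Mean duration of sleep bouts initiated in the first 2 h of light.

    Returns ``(baseline_mean, recovery_mean)`` at full unclipped durations;
    a component is absent when no bout onsets in its window.
    """
    _, _, rec_win, base_win = _windows(trace, design)
    if bouts is None:
        bouts = detect_sleep_bouts(trace)
    w = design.bout_window_min
    return (
        _mean_onset_bout_duration(bouts, base_win[0], w),
        _mean_onset_bout_duration(bouts, rec_win[0], w),
    )


def rebound_table(
    experiment: Experiment, design: DeprivationDesign = DeprivationDesign()
) -> pd.DataFrame:
    """Per-fly deprivation/rebound metrics for a whole experiment."""
    rows = []
    for t in experiment.traces:
        r = rebound_excess(t, design)
        rows.append(
            {
                "fly_id": r.fly_id,
                "genotype": t.genotype,
                "sex": t.sex,
                "sleep_lost_min": r.sleep_lost_min,
                "excess_sleep_min": r.excess_sleep_min,
                "deprivation_sleep_min": r.deprivation_sleep_min,
                "baseline_bout_duration_min": r.baseline_bout_duration_min,
                "recovery_bout_duration_min": r.recovery_bout_duration_min,
            }
        )
    return pd.DataFrame(rows)
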