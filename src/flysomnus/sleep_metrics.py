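"""Sleep-architecture metrics from per-minute beam-crossing counts.

A sleep bout is the field-standard fly proxy: a maximal run of at least
5 consecutive minutes with zero beam crossings. From detected bouts this
module derives, per fly and per light phase: total sleep, bout count and
mean bout duration, sleep-onset latency (lights-off to first bout onset),
waking activity per active minute, the short/medium/long bout-duration
composition of night sleep, 30-min sleep profiles, and the dead-fly filter
(under 10 active minutes in a complete light or dark phase).

Bout attribution across the day/night boundary follows two complementary
rules: per-minute clipping for totals and bin fractions (minutes must be
conserved), and onset-phase attribution with unclipped duration for bout
count and mean duration (bout statistics describe episodes, attributed
wholesale to the phase in which they start).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .dam_io import DAY, NIGHT, ActivityTrace, Experiment

SLEEP_THRESHOLD_MIN = 5
#: night-sleep bout-duration classes (clipped minutes): short, medium, long.
#: Detection guarantees unclipped bouts are >= 5 min; the short class is
#: open at the bottom so that phase-clipped fragments still land in a class
#: and the fractions always sum to 1.
BIN_EDGES = (49, 149, 720)
DEAD_ACTIVE_MIN = 10


@dataclass(frozen=True)
class SleepBout:
    """A maximal quiescence run satisfying the sleep rule."""

    onset: int  # 0-based minute index into the trace
    duration_min: int
    onset_phase: str | None = None
    censored_start: bool = False
    censored_end: bool = False

    @property
    def end(self) -> int:  # exclusive
        return self.onset + self.duration_min


class Latency(NamedTuple):
    minutes: float
    no_sleep: bool


@dataclass
class Window:
    """A half-open minute window ``[start, stop)`` of one phase of one cycle."""

    phase: str
    cycle: int
    start: int
    stop: int

    def __len__(self) -> int:
        return self.stop - self.start


@dataclass
class WindowSummary:
    fly_id: str
    phase: str
    cycle: int
    window_min: int
    total_sleep_min: int
    bout_count: int
    mean_bout_duration_min: float | None
    latency_min: float | None
    latency_no_sleep: bool | None
    motion_bout_activity: float | None
    frac_short: float | None
    frac_medium: float | None
    frac_long: float | None
    dead: bool


def detect_sleep_bouts(
    trace: ActivityTrace | Sequence[int],
    threshold_min: int = SLEEP_THRESHOLD_MIN,
) -> list[SleepBout]:
    """Maximal zero-count runs of at least ``threshold_min`` minutes.

    Requires minute-resolution data (rebin coarser traces first — that is
    an error, not a silent reinterpretation). Runs touching either trace
    boundary are included at their observed length and flagged censored.
    """
    if isinstance(trace, ActivityTrace):
        if trace.bin_min != 1:
            raise ValueError(
                f"sleep detection needs 1-min bins, got {trace.bin_min}-min"
            )
        counts = trace.counts
        phases = trace.phase_labels()
    else:
        counts = np.asarray(trace)
        phases = None
    if threshold_min < 1:
        raise ValueError("threshold_min must be >= 1")

    quiet = np.concatenate(([False], counts == 0, [False]))
    edges = np.flatnonzero(np.diff(quiet.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    n = counts.size
    bouts = []
    for a, b in zip(starts, stops):
        if b - a < threshold_min:
            continue
        bouts.append(
            SleepBout(
                onset=int(a),
                duration_min=int(b - a),
                onset_phase=None if phases is None else str(phases[a]),
                censored_start=a == 0,
                censored_end=b == n,
            )
        )
    return bouts


def sleep_indicator(n_minutes: int, bouts: Sequence[SleepBout]) -> np.ndarray:
    """Boolean per-minute asleep mask implied by a bout list."""
    asleep = np.zeros(n_minutes, dtype=bool)
    for b in bouts:
        asleep[b.onset:min(b.end, n_minutes)] = True
    return asleep


def phase_windows(trace: ActivityTrace, phases: tuple[str, ...] = (DAY, NIGHT)) -> list[Window]:
    """Complete (unclipped) phase windows of a minute-resolution trace.

    Cycle numbering counts elapsed 24-h periods from the first lights-on
    at or before the trace start, so a day window and the night that
    follows it share a cycle index.
    """
    if trace.bin_min != 1:
        raise ValueError("phase windows need a 1-min binned trace")
    labels = trace.phase_labels()
    zt0 = trace.schedule.zt_minutes(trace.start)
    photoperiod = trace.schedule.photoperiod_min
    expected = {DAY: photoperiod, NIGHT: 1440 - photoperiod}
    windows = []
    i, n = 0, len(trace)
    while i < n:
        j = i
        while j < n and labels[j] == labels[i]:
            j += 1
        lab = str(labels[i])
        if lab in phases and lab in expected and j - i == expected[lab]:
            windows.append(Window(lab, (zt0 + i) // 1440, i, j))
        i = j
    return windows


def summarize_window(
    trace: ActivityTrace,
    bouts: Sequence[SleepBout],
    window: Window,
    dead: bool = False,
) -> WindowSummary:
    """Per-window sleep metrics under the clipping/attribution rules.

    Totals, bin fractions and waking activity use per-minute clipping to
    the window; bout count and mean duration use bouts whose onset lies in
    the window, at full unclipped duration.
    """
    if len(window) <= 0 or window.start < 0 or window.stop > len(trace):
        raise ValueError(f"window [{window.start}, {window.stop}) invalid for trace")
    asleep = sleep_indicator(len(trace), bouts)[window.start:window.stop]
    total_sleep = int(asleep.sum())

    onset_bouts = [b for b in bouts if window.start <= b.onset < window.stop]
    bout_count = len(onset_bouts)
    mean_dur = (
        float(np.mean([b.duration_min for b in onset_bouts])) if onset_bouts else None
    )

    wake_minutes = len(window) - total_sleep
    if wake_minutes > 0:
        motion = float(trace.counts[window.start:window.stop].sum() / wake_minutes)
    else:
        motion = None

    clipped = [
        min(b.end, window.stop) - max(b.onset, window.start)
        for b in bouts
        if b.onset < window.stop and b.end > window.start
    ]
    fracs = bin_fractions(clipped)

    if window.phase in (NIGHT, "subjective_night"):
        lat = sleep_latency_in(bouts, window)
        latency_min, latency_no_sleep = lat.minutes, lat.no_sleep
    else:
        latency_min = latency_no_sleep = None

    return WindowSummary(
        fly_id=trace.fly_id,
        phase=window.phase,
        cycle=window.cycle,
        window_min=len(window),
        total_sleep_min=total_sleep,
        bout_count=bout_count,
        mean_bout_duration_min=mean_dur,
        latency_min=latency_min,
        latency_no_sleep=latency_no_sleep,
        motion_bout_activity=motion,
        frac_short=fracs[0],
        frac_medium=fracs[1],
        frac_long=fracs[2],
        dead=dead,
    )


def sleep_latency_in(bouts: Sequence[SleepBout], night: Window) -> Latency:
    """Minutes from lights-off to the first sleep-bout onset in the night.

    0 if a bout is ongoing at lights-off; the full window length, flagged,
    if no bout onsets within the night.
    """
    for b in bouts:
        if b.onset < night.start < b.end:
            return Latency(0.0, False)
    onsets = [b.onset for b in bouts if night.start <= b.onset < night.stop]
    if onsets:
        return Latency(float(min(onsets) - night.start), False)
    return Latency(float(len(night)), True)


def sleep_latency(trace: ActivityTrace, night: Window) -> Latency:
    return sleep_latency_in(detect_sleep_bouts(trace), night)


def bin_fractions(
    clipped_durations: Sequence[int],
    edges: tuple[int, int, int] = BIN_EDGES,
) -> tuple[float | None, float | None, float | None]:
    """Fraction of sleep carried by short/medium/long bouts.

    ``clipped_durations`` are window-clipped bout durations; each class
    fraction is (minutes contributed by bouts in the class) / (total
    minutes). All fractions are absent when there is no sleep.
    """
    total = float(sum(clipped_durations))
    if total == 0:
        return (None, None, None)
    short = sum(d for d in clipped_durations if d <= edges[0])
    medium = sum(d for d in clipped_durations if edges[0] < d <= edges[1])
    long_ = sum(d for d in clipped_durations if edges[1] < d <= edges[2])
    return (short / total, medium / total, long_ / total)


def flag_dead(trace: ActivityTrace, min_active_min: int = DEAD_ACTIVE_MIN) -> bool:
    """Dead-fly filter: under 10 active minutes in a complete light or dark phase.

    A minute is active when its count is >= 1. Traces with no complete
    light/dark phase (pure DD) fall back to the whole-trace activity count.
    """
    active = trace.counts >= 1
    windows = phase_windows(trace)
    if not windows:
        return int(active.sum()) < min_active_min
    for w in windows:
        if int(active[w.start:w.stop].sum()) < min_active_min:
            return True
    return False


def summarize_trace(
    trace: ActivityTrace, threshold_min: int = SLEEP_THRESHOLD_MIN
) -> list[WindowSummary]:
    """WindowSummary per complete day/night window of one fly."""
    bouts = detect_sleep_bouts(trace, threshold_min)
    dead = flag_dead(trace)
    return [
        summarize_window(trace, bouts, w, dead=dead) for w in phase_windows(trace)
    ]


def summarize_experiment(
    experiment: Experiment, threshold_min: int = SLEEP_THRESHOLD_MIN
) -> pd.DataFrame:
    """Long-format per-fly, per-phase, per-cycle summary table."""
    rows = []
    for t in experiment.traces:
        for s in summarize_trace(t, threshold_min):
            rows.append(
                {
                    "fly_id": s.fly_id,
                    "genotype": t.genotype,
                    "sex": t.sex,
                    "phase": s.phase,
                    "cycle": s.cycle,
                    "window_min": s.window_min,
                    "total_sleep_min": s.total_sleep_min,
                    "bout_count": s.bout_count,
                    "mean_bout_duration_min": s.mean_bout_duration_min,
                    "latency_min": s.latency_min,
                    "latency_no_sleep": s.latency_no_sleep,
                    "motion_bout_activity": s.motion_bout_activity,
                    "frac_short": s.frac_short,
                    "frac_medium": s.frac_medium,
                    "frac_long": s.frac_long,
                    "dead": s.dead,
                }
            )
    return pd.DataFrame(rows)


def per_fly_metrics(summaries: pd.DataFrame) -> pd.DataFrame:
    """Collapse the summary table to one row per fly (mean across cycles).

    Columns are ``<metric>_<phase>`` plus ``latency_min`` (nights only);
    dead status is carried through for downstream exclusion.
    """
    meta = summaries.groupby("fly_id", sort=False).agg(
        genotype=("genotype", "first"), sex=("sex", "first"), dead=("dead", "any")
    )
    pieces = [meta]
    metrics = [
        "total_sleep_min",
        "bout_count",
        "mean_bout_duration_min",
        "motion_bout_activity",
        "frac_short",
        "frac_medium",
        "frac_long",
    ]
    for phase in (DAY, NIGHT):
        sub = summaries[summaries["phase"] == phase]
        agg = sub.groupby("fly_id", sort=False)[metrics].mean()
        agg.columns = [f"{c}_{phase}" for c in agg.columns]
        pieces.append(agg)
    nights = summaries[summaries["phase"] == NIGHT]
    lat = nights.groupby("fly_id", sort=False)["latency_min"].mean().to_frame()
    pieces.append(lat)
    return pd.concat(pieces, axis=1).reset_index()


def sleep_profile(
    experiment: Experiment,
    bin_min: int = 30,
    threshold_min: int = SLEEP_THRESHOLD_MIN,
) -> pd.DataFrame:
    """Group mean +/- SEM sleep minutes per 30-min bin across live flies.

    Returns long format: genotype, bin_index, bin_start_min, mean, sem, n.
    Dead flies are excluded; a group with no live flies is an error.
    """
    per_group: dict[str, list[np.ndarray]] = {}
    for t in experiment.traces:
        if flag_dead(t):
            continue
        bouts = detect_sleep_bouts(t, threshold_min)
        asleep = sleep_indicator(len(t), bouts).astype(np.int64)
        n_bins = len(t) // bin_min
        per_bin = asleep[: n_bins * bin_min].reshape(n_bins, bin_min).sum(axis=1)
        per_group.setdefault(t.genotype, []).append(per_bin)
    for g in {t.genotype for t in experiment.traces}:
        if g not in per_group:
            raise ValueError(f"group {g!r} has no live flies")
    rows = []
    for g, arrs in per_group.items():
        mat = np.vstack(arrs).astype(float)
        n = mat.shape[0]
        mean = mat.mean(axis=0)
        sem = mat.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(mat.shape[1])
        for i in range(mat.shape[1]):
            rows.append(
                {
                    "genotype": g,
                    "bin_index": i,
                    "bin_start_min": i * bin_min,
                    "mean": mean[i],
                    "sem": sem[i],
                    "n": n,
                }
            )
    return pd.DataFrame(rows)
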