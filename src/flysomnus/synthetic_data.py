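"""Seedable generator of fly activity traces with known sleep structure.

The generative model is an alternating-renewal (semi-Markov) process: a fly
switches between WAKE and SLEEP bouts whose durations are drawn from
lognormal distributions (heavy right tail, matching long consolidated night
bouts versus short fragmented ones) with phase-dependent means and a common
shape, rounded to whole minutes with a 1-minute floor. Parameters are
evaluated once at bout onset and never re-drawn mid-bout, which keeps bouts
interpretable and renewal-theory expectations exact.

Structure of one simulated recording:

* Under LD, day and night bout means apply according to the phase at bout
  onset. At every lights-off transition the ongoing bout is terminated and
  a fresh wake bout with mean ``first_night_wake_mean`` begins — this is
  the evening activity peak, and it makes sleep latency tunable
  independently of fragmentation while rendering each night an independent
  renewal epoch.
* Under DD (after ``schedule.dd_start``) the wake mean is multiplied and
  the sleep mean divided by a circadian gate
  ``g(t) = 1 + gate_amplitude * cos(2*pi*(t - phi)/tau)`` evaluated at bout
  onset, with ``phi`` anchored at projected mid-(subjective-)day, so free-
  running rest/activity rhythmicity persists at period ``tau``.
* Wake minutes emit counts from a zero-truncated Poisson; sleep minutes
  emit 0. Each wake minute independently becomes a 0-count
  "micro-quiescence" minute with ``micro_quiescence_prob`` (a knob for
  probing the 5-minute sleep threshold; 0 by default so detected quiescence
  equals the latent sleep state exactly).
* Mechanical deprivation is an overlay: inside ``deprivation_window`` every
  minute's count is forced to the wake draw (>= 1) regardless of latent
  state, and sleep bouts *onsetting* within ``rebound_hours`` after the
  window end have their durations scaled by ``rebound_multiplier``. With
  multiplier 1 an equal-seed trace is identical to the undisturbed one
  outside the window.

All randomness flows from ``SimConfig.seed`` through independent
substreams (bouts, counts, micro-quiescence), so traces are
bit-reproducible and deprivation overlays never perturb the bout stream.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from datetime import time as dtime
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dam_io import ActivityTrace, Experiment, LightSchedule, write_dam

logger = logging.getLogger(__name__)

WAKE = 0
SLEEP = 1


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one simulated fly (all durations in minutes)."""

    wake_bout_mean_day: float = 30.0
    wake_bout_mean_night: float = 15.0
    sleep_bout_mean_day: float = 30.0
    sleep_bout_mean_night: float = 90.0
    bout_shape: float = 0.6  # lognormal sigma
    wake_count_rate: float = 2.0  # mean beam crosses per waking minute
    micro_quiescence_prob: float = 0.0
    gate_amplitude: float = 0.6
    free_running_period_h: float = 23.6
    first_night_wake_mean: float = 40.0
    deprivation_window: tuple[int, int] | None = None
    rebound_multiplier: float = 1.0
    rebound_hours: float = 3.0
    death_time_min: int | None = None
    seed: int = 0
    bout_distribution: str = "lognormal"  # or "geometric"
    sex: str = "M"

    def __post_init__(self) -> None:
        means = (
            self.wake_bout_mean_day,
            self.wake_bout_mean_night,
            self.sleep_bout_mean_day,
            self.sleep_bout_mean_night,
            self.first_night_wake_mean,
        )
        for m in means:
            if not (np.isfinite(m) and m > 0):
                raise ValueError(f"bout means must be finite and positive, got {m}")
        if not (np.isfinite(self.bout_shape) and self.bout_shape > 0):
            raise ValueError("bout_shape must be positive")
        if not (np.isfinite(self.wake_count_rate) and self.wake_count_rate > 0):
            raise ValueError("wake_count_rate must be positive")
        if not 0.0 <= self.micro_quiescence_prob <= 1.0:
            raise ValueError("micro_quiescence_prob must lie in [0, 1]")
        if not 0.0 <= self.gate_amplitude < 1.0:
            raise ValueError("gate_amplitude must lie in [0, 1)")
        if not self.free_running_period_h > 0:
            raise ValueError("free_running_period_h must be positive")
        if self.rebound_multiplier < 1.0:
            raise ValueError("rebound_multiplier must be >= 1")
        if self.rebound_hours < 0.0:
            raise ValueError("rebound_hours must be >= 0")
        if self.bout_distribution not in ("lognormal", "geometric"):
            raise ValueError("bout_distribution must be 'lognormal' or 'geometric'")
        if self.deprivation_window is not None:
            a, b = self.deprivation_window
            if not a < b:
                raise ValueError("deprivation_window must satisfy start < end")


# Calibration anchors: sleep-onset latencies of 40 (control M) / 70 (mutant M)
# and 70 (control F) / 110 (mutant F) minutes; free-running periods 23.5-23.6 h.
# Night architecture: mutants have roughly halved night sleep-bout means with
# unchanged night wake means -> shorter, more numerous bouts (fragmentation).
PRESETS: dict[str, SimConfig] = {
    "control_male": SimConfig(
        wake_bout_mean_day=30, sleep_bout_mean_day=30,
        wake_bout_mean_night=15, sleep_bout_mean_night=90,
        first_night_wake_mean=40, free_running_period_h=23.6, sex="M",
    ),
    "nowl_like_male": SimConfig(
        wake_bout_mean_day=40, sleep_bout_mean_day=20,
        wake_bout_mean_night=15, sleep_bout_mean_night=45,
        first_night_wake_mean=70, free_running_period_h=23.5, sex="M",
    ),
    "control_female": SimConfig(
        wake_bout_mean_day=45, sleep_bout_mean_day=15,
        wake_bout_mean_night=15, sleep_bout_mean_night=75,
        first_night_wake_mean=70, free_running_period_h=23.5, sex="F",
    ),
    "nowl_like_female": SimConfig(
        wake_bout_mean_day=50, sleep_bout_mean_day=10,
        wake_bout_mean_night=15, sleep_bout_mean_night=38,
        first_night_wake_mean=110, free_running_period_h=23.5, sex="F",
    ),
    "arrhythmic": SimConfig(
        wake_bout_mean_day=30, sleep_bout_mean_day=30,
        wake_bout_mean_night=15, sleep_bout_mean_night=90,
        first_night_wake_mean=40, gate_amplitude=0.0, sex="M",
    ),
    "dead": SimConfig(
        wake_bout_mean_day=30, sleep_bout_mean_day=30,
        wake_bout_mean_night=15, sleep_bout_mean_night=90,
        first_night_wake_mean=40, death_time_min=1440, sex="M",
    ),
}


def preset(name: str, **overrides) -> SimConfig:
    """A named preset configuration, optionally with field overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)


def apply_deprivation(config: SimConfig, window: tuple[int, int]) -> SimConfig:
    """Arm mechanical deprivation over ``window`` (minutes from trace start)."""
    a, b = window
    if not a < b:
        raise ValueError(f"inverted deprivation window {window}")
    return replace(config, deprivation_window=(int(a), int(b)))


def _draw_duration(rng: np.random.Generator, mean: float, config: SimConfig) -> float:
    if config.bout_distribution == "geometric":
        return float(rng.geometric(min(1.0, 1.0 / mean)))
    mu = math.log(mean) - 0.5 * config.bout_shape**2
    return float(rng.lognormal(mu, config.bout_shape))


def simulate_fly(
    config: SimConfig,
    duration_min: int,
    fly_id: str = "sim",
    genotype: str = "sim",
    start: pd.Timestamp | None = None,
    schedule: LightSchedule | None = None,
) -> ActivityTrace:
    """Simulate one fly as an alternating sleep/wake renewal process.

    The recording starts awake at ``start`` (default: lights-on of the
    schedule's cycle). With a fixed seed output is bit-reproducible.
    """
    if duration_min < 1440:
        raise ValueError("duration_min must be at least one full day (1440)")
    schedule = schedule or LightSchedule()
    start = pd.Timestamp(start) if start is not None else pd.Timestamp(
        "2024-01-01"
    ).replace(hour=schedule.lights_on.hour, minute=schedule.lights_on.minute)

    ss = np.random.SeedSequence(config.seed)
    rng_bouts, rng_counts, rng_mq = (np.random.default_rng(s) for s in ss.spawn(3))

    zt0 = schedule.zt_minutes(start)  # ZT of minute 0
    photoperiod = schedule.photoperiod_min
    if schedule.regime == "DD":
        dd_min = max(
            0, int(round((schedule.dd_start - start).total_seconds() / 60.0))
        )
    else:
        dd_min = duration_min + 1  # never reached

    tau_min = config.free_running_period_h * 60.0
    # gate peaks at projected mid-day so subjective night carries most sleep
    phi = (-zt0) % 1440 + photoperiod / 2.0
    gm_wake = math.sqrt(config.wake_bout_mean_day * config.wake_bout_mean_night)
    gm_sleep = math.sqrt(config.sleep_bout_mean_day * config.sleep_bout_mean_night)

    if config.deprivation_window is not None:
        dep_a, dep_b = config.deprivation_window
        reb_end = dep_b + int(round(config.rebound_hours * 60))
    else:
        dep_a = dep_b = reb_end = -1

    def next_lights_off(t: int) -> int:
        """First lights-off transition strictly after minute t (or inf in DD)."""
        off = ((photoperiod - zt0 - t) % 1440) + t
        if off <= t:
            off += 1440
        return off if off < dd_min else duration_min + 10**9

    asleep = np.zeros(duration_min, dtype=bool)
    t = 0
    state = WAKE
    use_first_night = zt0 == photoperiod  # recording starting exactly at lights-off
    while t < duration_min:
        in_dd = t >= dd_min
        if state == WAKE:
            if use_first_night:
                mean = config.first_night_wake_mean
            elif in_dd:
                g = 1.0 + config.gate_amplitude * math.cos(
                    2.0 * math.pi * (t - phi) / tau_min
                )
                mean = gm_wake * g
            else:
                day = (zt0 + t) % 1440 < photoperiod
                mean = config.wake_bout_mean_day if day else config.wake_bout_mean_night
        else:
            if in_dd:
                g = 1.0 + config.gate_amplitude * math.cos(
                    2.0 * math.pi * (t - phi) / tau_min
                )
                mean = gm_sleep / g
            else:
                day = (zt0 + t) % 1440 < photoperiod
                mean = (
                    config.sleep_bout_mean_day if day else config.sleep_bout_mean_night
                )
        use_first_night = False
        x = _draw_duration(rng_bouts, mean, config)
        if state == SLEEP and config.rebound_multiplier != 1.0 and dep_b <= t < reb_end:
            x *= config.rebound_multiplier
        d = max(1, int(round(x)))
        off = next_lights_off(t)
        end = min(t + d, off, duration_min)
        if state == SLEEP:
            asleep[t:end] = True
        if end == off:
            state = WAKE
            use_first_night = True
        else:
            state = SLEEP if state == WAKE else WAKE
        t = end

    # per-minute count layers, drawn for every minute so that overlays
    # (deprivation, rebound) never shift the substreams
    lam = config.wake_count_rate
    p0 = math.exp(-lam)
    u = rng_counts.uniform(size=duration_min)
    wake_counts = sps.poisson.ppf(p0 + u * (1.0 - p0), lam).astype(np.int64)
    micro_q = rng_mq.uniform(size=duration_min) < config.micro_quiescence_prob

    counts = np.where(~asleep & ~micro_q, wake_counts, 0)
    if config.deprivation_window is not None:
        a, b = max(0, dep_a), min(duration_min, dep_b)
        counts[a:b] = wake_counts[a:b]  # forced wake, count >= 1 every minute
    if config.death_time_min is not None:
        counts[max(0, int(config.death_time_min)):] = 0

    return ActivityTrace(
        fly_id=fly_id,
        genotype=genotype,
        sex=config.sex,
        start=start,
        bin_min=1,
        counts=counts,
        schedule=schedule,
    )


def per_fly_seed(master_seed: int, index: int) -> int:
    """Deterministic per-fly seed: ``SeedSequence([master_seed, index])``.

    The counter scheme means cohorts can be extended without reshuffling
    earlier flies.
    """
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0])


def simulate_experiment(
    design: list[tuple[SimConfig | str, int, str]],
    days: int = 5,
    seed: int = 0,
    out_dir: str | Path | None = None,
    start: pd.Timestamp | None = None,
    schedule: LightSchedule | None = None,
) -> Experiment:
    """Simulate a labelled cohort and optionally write DAM monitor files.

    ``design`` lists ``(preset-name-or-SimConfig, n, label)`` groups; the
    label becomes the genotype of its traces. Per-fly seeds derive from the
    master seed via :func:`per_fly_seed` with a global fly counter.
    """
    labels = [lab for _, _, lab in design]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate group labels in design")
    traces: list[ActivityTrace] = []
    idx = 0
    for cfg, n, label in design:
        if n == 0:
            logger.warning("group %r has n=0; skipped", label)
            continue
        base = preset(cfg) if isinstance(cfg, str) else cfg
        for j in range(n):
            traces.append(
                simulate_fly(
                    replace(base, seed=per_fly_seed(seed, idx)),
                    duration_min=days * 1440,
                    fly_id=f"{label}_{j:03d}",
                    genotype=label,
                    start=start,
                    schedule=schedule,
                )
            )
            idx += 1
    if not traces:
        raise ValueError("design produced no flies")
    experiment = Experiment(traces=traces)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = write_dam(experiment, out_dir / "monitor.txt", allow_split=True)
        experiment.monitor_files = [str(p) for p, _ in written]
    return experiment
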