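"""Reading, writing and conditioning of Drosophila Activity Monitor (DAM) data.

A TriKinetics DAM monitor reports, for each of 32 glass-tube channels, the
number of infrared-beam crossings per recording bin (normally one minute).
The on-disk dialect handled here is the de-facto DAM2 text layout: one row
per bin, tab-separated, with a leading record index, a date (``8 Jan 12``),
a time (``HH:MM:SS``), a status code, six auxiliary columns and then the 32
integer count columns.

Light phase is always derived from the configured :class:`LightSchedule`
(the incubator program), never from a monitor light-sensor column.
Bins are half-open ``[t, t + bin_min)``: a lights transition at time ``T``
belongs to the bin starting at ``T``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import time as dtime
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: status code a DAM2 monitor writes for a valid data row
VALID_STATUS = 1

_N_CHANNELS = 32
_N_AUX = 6
_N_COLUMNS = 4 + _N_AUX + _N_CHANNELS

DAY = "day"
NIGHT = "night"
SUBJECTIVE = "subjective"


class DAMParseError(ValueError):
    """A monitor file violates the DAM dialect (carries the offending line)."""


@dataclass(frozen=True)
class LightSchedule:
    """Incubator light program: 12:12 LD by default, optional release into DD.

    Parameters
    ----------
    regime:
        ``"LD"`` for an entrained light:dark cycle, ``"DD"`` when the
        recording is released into constant darkness at ``dd_start``.
    lights_on:
        Clock time of lights-on (ZT0).
    photoperiod_min:
        Minutes of light per cycle; 720 gives the standard 12:12 cycle.
    dd_start:
        Timestamp of the lights-off transition into constant darkness;
        required when ``regime == "DD"``. Bins at or after it are labelled
        ``"subjective"``.
    """

    regime: str = "LD"
    lights_on: dtime = dtime(8, 0)
    photoperiod_min: int = 720
    dd_start: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if self.regime not in ("LD", "DD"):
            raise ValueError(f"regime must be 'LD' or 'DD', got {self.regime!r}")
        if not 0 < self.photoperiod_min < 1440:
            raise ValueError("photoperiod_min must lie strictly between 0 and 1440")
        if self.regime == "DD" and self.dd_start is None:
            raise ValueError("regime 'DD' requires dd_start")

    @property
    def lights_on_min(self) -> int:
        return self.lights_on.hour * 60 + self.lights_on.minute

    def zt_minutes(self, ts: pd.Timestamp) -> int:
        """Zeitgeber time of ``ts`` in minutes (0 = lights-on)."""
        clock = ts.hour * 60 + ts.minute
        return (clock - self.lights_on_min) % 1440


@dataclass
class ActivityTrace:
    """One fly's per-bin beam-crossing counts plus experiment annotations."""

    fly_id: str
    genotype: str
    sex: str
    start: pd.Timestamp
    bin_min: int
    counts: np.ndarray
    schedule: LightSchedule = field(default_factory=LightSchedule)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.bin_min < 1:
            raise ValueError("bin_min must be a positive integer")
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")
        self.counts = self.counts.astype(np.int64)
        self.start = pd.Timestamp(self.start)

    def __len__(self) -> int:
        return int(self.counts.size)

    @property
    def duration_min(self) -> int:
        return len(self) * self.bin_min

    def bin_start(self, i: int) -> pd.Timestamp:
        return self.start + pd.Timedelta(minutes=i * self.bin_min)

    def zt0_offset_min(self) -> int:
        """Minutes from trace start to the first lights-on clock time."""
        return (-self.schedule.zt_minutes(self.start)) % 1440

    def phase_labels(self) -> np.ndarray:
        """Phase (``day``/``night``/``subjective``) of every bin.

        Derived solely from the schedule; under DD every bin at or after
        ``dd_start`` is ``subjective``.
        """
        i = np.arange(len(self))
        zt = (self.schedule.zt_minutes(self.start) + i * self.bin_min) % 1440
        labels = np.where(zt < self.schedule.photoperiod_min, DAY, NIGHT)
        labels = labels.astype(object)
        if self.schedule.regime == "DD":
            dd_bin = self._bins_until(self.schedule.dd_start)
            labels[max(dd_bin, 0):] = SUBJECTIVE
        return labels

    def _bins_until(self, ts: pd.Timestamp) -> int:
        delta = (pd.Timestamp(ts) - self.start).total_seconds() / 60.0
        return int(np.ceil(delta / self.bin_min))

    def slice_bins(self, start: int, stop: int) -> "ActivityTrace":
        if not 0 <= start < stop <= len(self):
            raise ValueError(f"bin slice [{start}, {stop}) outside trace")
        return replace(
            self,
            start=self.bin_start(start),
            counts=self.counts[start:stop].copy(),
        )


@dataclass
class Experiment:
    """A set of traces sharing a bin width, with file provenance and design."""

    traces: list[ActivityTrace]
    monitor_files: list[str] = field(default_factory=list)
    design: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [t.fly_id for t in self.traces]
        if len(set(ids)) != len(ids):
            raise ValueError("fly_ids must be unique within an Experiment")
        widths = {t.bin_min for t in self.traces}
        if len(widths) > 1:
            raise ValueError(f"traces mix bin widths {sorted(widths)}")

    def __len__(self) -> int:
        return len(self.traces)

    def groups(self) -> dict[str, list[ActivityTrace]]:
        out: dict[str, list[ActivityTrace]] = {}
        for t in self.traces:
            out.setdefault(t.genotype, []).append(t)
        return out


# ---------------------------------------------------------------------------
# DAM file reading / writing
# ---------------------------------------------------------------------------

def _parse_row(line: str, lineno: int) -> tuple[pd.Timestamp, int, np.ndarray]:
    parts = line.rstrip("\n").split("\t")
    if len(parts) != _N_COLUMNS:
        raise DAMParseError(
            f"line {lineno}: expected {_N_COLUMNS} tab-separated columns, "
            f"got {len(parts)}"
        )
    try:
        ts = pd.to_datetime(parts[1] + " " + parts[2], format="%d %b %y %H:%M:%S")
        status = int(parts[3])
        counts = np.array([int(x) for x in parts[4 + _N_AUX:]], dtype=np.int64)
    except (ValueError, TypeError) as exc:
        raise DAMParseError(f"line {lineno}: {exc}") from exc
    return ts, status, counts


def read_dam(
    path: str | Path,
    design: Mapping[int, Mapping[str, str]],
    schedule: LightSchedule,
    native_bin_min: int = 1,
    drop_error_rows: bool = False,
) -> Experiment:
    """Read one DAM monitor file into an :class:`Experiment`.

    ``design`` maps 1-based channel numbers to ``{"genotype": ..., "sex":
    ..., "fly_id": ...}`` (``fly_id`` optional). Unmapped channels are
    dropped with a log note. Timestamps must advance by exactly
    ``native_bin_min`` minutes — a gap is an error, never imputed, because
    sleep-run detection is undefined across gaps.

    Rows whose status code differs from :data:`VALID_STATUS` are retained
    and flagged by default; with ``drop_error_rows`` they are removed, which
    is only permitted at the file head or tail (an interior drop would leave
    a gap).
    """
    path = Path(path)
    if native_bin_min < 1:
        raise ValueError("native_bin_min must be >= 1")
    rows: list[tuple[pd.Timestamp, int, np.ndarray]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            rows.append(_parse_row(line, lineno))
    if not rows:
        raise DAMParseError(f"{path}: empty monitor file")

    status = np.array([r[1] for r in rows])
    bad = status != VALID_STATUS
    if drop_error_rows and bad.any():
        good = np.flatnonzero(~bad)
        if good.size == 0:
            raise DAMParseError(f"{path}: no valid-status rows")
        lo, hi = good[0], good[-1] + 1
        if bad[lo:hi].any():
            raise DAMParseError(
                f"{path}: dropping interior error rows would leave a timing gap"
            )
        logger.info("%s: dropped %d error-status edge rows", path.name, int(bad.sum()))
        rows = rows[lo:hi]
        bad = bad[lo:hi]
    elif bad.any():
        logger.warning(
            "%s: %d rows carry status != %d (retained, flagged)",
            path.name, int(bad.sum()), VALID_STATUS,
        )

    times = pd.DatetimeIndex([r[0] for r in rows])
    step = pd.Timedelta(minutes=native_bin_min)
    deltas = np.diff(times.asi8)
    if np.any(deltas <= 0):
        raise DAMParseError(f"{path}: non-monotonic timestamps")
    if np.any(deltas != step.value):
        i = int(np.argmax(deltas != step.value))
        raise DAMParseError(
            f"{path}: timing gap between rows {i + 1} and {i + 2} "
            f"(expected {native_bin_min}-min cadence)"
        )

    matrix = np.vstack([r[2] for r in rows])  # rows x 32
    traces = []
    for ch in sorted(design):
        if not 1 <= int(ch) <= _N_CHANNELS:
            raise ValueError(f"design channel {ch} outside 1..{_N_CHANNELS}")
        meta = design[ch]
        fly_id = meta.get("fly_id", f"{path.stem}.ch{int(ch):02d}")
        traces.append(
            ActivityTrace(
                fly_id=fly_id,
                genotype=meta["genotype"],
                sex=meta["sex"],
                start=times[0],
                bin_min=native_bin_min,
                counts=matrix[:, int(ch) - 1],
                schedule=schedule,
            )
        )
    unmapped = _N_CHANNELS - len(design)
    logger.info(
        "%s: %d channels mapped, %d unmapped channels dropped",
        path.name, len(design), unmapped,
    )
    exp = Experiment(
        traces=traces,
        monitor_files=[str(path)],
        design={int(c): dict(m) for c, m in design.items()},
    )
    exp.status_flags = bad  # type: ignore[attr-defined]
    return exp


def write_dam(
    experiment: Experiment,
    path: str | Path,
    allow_split: bool = False,
) -> list[tuple[Path, dict[int, dict[str, str]]]]:
    """Write an experiment as DAM monitor file(s).

    Returns ``[(file_path, channel_design), ...]`` so the files can be read
    back with :func:`read_dam`. Channels beyond the written traces are
    filled with zeros (an unloaded monitor position). More than 32 traces
    require ``allow_split``, which emits numbered sibling files.
    """
    path = Path(path)
    traces = experiment.traces
    if not traces:
        raise ValueError("cannot write an empty experiment")
    lengths = {len(t) for t in traces}
    if len(lengths) != 1:
        raise ValueError("all traces must have equal length")
    starts = {t.start for t in traces}
    bins = {t.bin_min for t in traces}
    if len(starts) != 1 or len(bins) != 1:
        raise ValueError("all traces must share start time and bin width")
    if len(traces) > _N_CHANNELS and not allow_split:
        raise ValueError(
            f"{len(traces)} traces exceed one monitor's {_N_CHANNELS} channels; "
            "pass allow_split=True"
        )

    chunks = [traces[i:i + _N_CHANNELS] for i in range(0, len(traces), _N_CHANNELS)]
    n_rows = lengths.pop()
    start = starts.pop()
    bin_min = bins.pop()
    out: list[tuple[Path, dict[int, dict[str, str]]]] = []
    for k, chunk in enumerate(chunks):
        fpath = path if len(chunks) == 1 else path.with_name(
            f"{path.stem}_{k + 1}{path.suffix or '.txt'}"
        )
        matrix = np.zeros((n_rows, _N_CHANNELS), dtype=np.int64)
        design: dict[int, dict[str, str]] = {}
        for j, t in enumerate(chunk):
            matrix[:, j] = t.counts
            design[j + 1] = {"fly_id": t.fly_id, "genotype": t.genotype, "sex": t.sex}
        with open(fpath, "w") as fh:
            for i in range(n_rows):
                ts = start + pd.Timedelta(minutes=i * bin_min)
                stamp = f"{ts.day} {ts.strftime('%b %y')}\t{ts.strftime('%H:%M:%S')}"
                aux = "\t".join(["0"] * _N_AUX)
                row = "\t".join(str(c) for c in matrix[i])
                fh.write(f"{i + 1}\t{stamp}\t{VALID_STATUS}\t{aux}\t{row}\n")
        out.append((fpath, design))
    return out


# ---------------------------------------------------------------------------
# Trace conditioning
# ---------------------------------------------------------------------------

def rebin(trace: ActivityTrace, width_min: int) -> ActivityTrace:
    """Aggregate counts into ``width_min``-minute bins by summation.

    ``width_min`` must be a positive multiple of the trace's bin width; a
    trailing partial bin is dropped with a log note. Total counts are
    conserved over the complete output bins.
    """
    if width_min < trace.bin_min:
        raise ValueError(
            f"cannot rebin from {trace.bin_min} min to finer {width_min} min"
        )
    if width_min % trace.bin_min:
        raise ValueError(
            f"width {width_min} is not a multiple of bin width {trace.bin_min}"
        )
    ratio = width_min // trace.bin_min
    if ratio == 1:
        return replace(trace, counts=trace.counts.copy())
    n_out = len(trace) // ratio
    if n_out == 0:
        raise ValueError(
            f"trace of {len(trace)} bins is shorter than one {width_min}-min bin"
        )
    dropped = len(trace) - n_out * ratio
    if dropped:
        logger.info(
            "%s: dropped %d trailing bins in rebin to %d min",
            trace.fly_id, dropped, width_min,
        )
    counts = trace.counts[: n_out * ratio].reshape(n_out, ratio).sum(axis=1)
    return replace(trace, bin_min=width_min, counts=counts)


def trim_acclimation(
    trace: ActivityTrace,
    policy: str = "first_lights_on",
    min_hours: float = 12.0,
    fixed_hours: float = 24.0,
) -> ActivityTrace:
    """Discard the acclimatization period at the head of a recording.

    ``first_lights_on`` (default) drops everything before the first
    lights-on transition occurring at least ``min_hours`` after recording
    start; ``fixed_hours`` drops exactly that many hours. The result must
    still span at least one full 24-h cycle.
    """
    if policy == "first_lights_on":
        offset = trace.zt0_offset_min()
        while offset < min_hours * 60:
            offset += 1440
        if offset % trace.bin_min:
            raise ValueError("lights-on transition not aligned to bin grid")
        start_bin = offset // trace.bin_min
    elif policy == "fixed_hours":
        cut = int(round(fixed_hours * 60))
        if cut % trace.bin_min:
            raise ValueError("fixed trim not aligned to bin grid")
        start_bin = cut // trace.bin_min
    else:
        raise ValueError(f"unknown trim policy {policy!r}")

    remaining_min = (len(trace) - start_bin) * trace.bin_min
    if remaining_min < 1440:
        raise ValueError(
            f"only {remaining_min} min remain after trimming {start_bin * trace.bin_min} "
            "min; need at least one full cycle"
        )
    logger.info(
        "%s: trimmed first %d min (%s policy)",
        trace.fly_id, start_bin * trace.bin_min, policy,
    )
    return trace.slice_bins(start_bin, len(trace))


# ---------------------------------------------------------------------------
# Tabular serialization (round-trips every trace and schedule field)
# ---------------------------------------------------------------------------

def experiment_to_frame(experiment: Experiment) -> pd.DataFrame:
    """Long-format table: one row per (fly, bin), metadata repeated."""
    frames = []
    for t in experiment.traces:
        s = t.schedule
        frames.append(
            pd.DataFrame(
                {
                    "fly_id": t.fly_id,
                    "genotype": t.genotype,
                    "sex": t.sex,
                    "start": t.start.isoformat(),
                    "bin_min": t.bin_min,
                    "bin_index": np.arange(len(t)),
                    "count": t.counts,
                    "regime": s.regime,
                    "lights_on": s.lights_on.strftime("%H:%M"),
                    "photoperiod_min": s.photoperiod_min,
                    "dd_start": s.dd_start.isoformat() if s.dd_start is not None else "",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def experiment_from_frame(df: pd.DataFrame) -> Experiment:
    traces = []
    for fly_id, g in df.groupby("fly_id", sort=False):
        g = g.sort_values("bin_index")
        r = g.iloc[0]
        hh, mm = str(r["lights_on"]).split(":")
        schedule = LightSchedule(
            regime=str(r["regime"]),
            lights_on=dtime(int(hh), int(mm)),
            photoperiod_min=int(r["photoperiod_min"]),
            dd_start=pd.Timestamp(r["dd_start"]) if str(r["dd_start"]) else None,
        )
        traces.append(
            ActivityTrace(
                fly_id=str(fly_id),
                genotype=str(r["genotype"]),
                sex=str(r["sex"]),
                start=pd.Timestamp(r["start"]),
                bin_min=int(r["bin_min"]),
                counts=g["count"].to_numpy(),
                schedule=schedule,
            )
        )
    return Experiment(traces=traces)


def save_experiment(experiment: Experiment, path: str | Path) -> None:
    experiment_to_frame(experiment).to_parquet(path, index=False)


def load_experiment(path: str | Path) -> Experiment:
    return experiment_from_frame(pd.read_parquet(path))
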