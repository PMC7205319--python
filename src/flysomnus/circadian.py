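"""Free-running rhythm analysis: chi-square periodogram and actograms.

The period statistic is the classical Sokolove-Bushell chi-square
periodogram. For a candidate period of ``p`` bins, the first ``K*p`` bins
(``K = floor(N/p)``) are folded into a ``K x p`` array; with column means
``B_h`` and grand mean ``xbar`` over the used bins,

    Q_p = K * sum_h (B_h - xbar)**2 / s2,   s2 = sum_i (x_i - xbar)**2 / N

whose large-sample null reference is a chi-square law with ``p - 1``
degrees of freedom. Because the numerator sum of squares is a component of
the denominator, the exact finite-sample null (independent Gaussian bins)
is ``Q/N ~ Beta((p-1)/2, (N-p)/2)`` with ``N = K*p``; the default
significance line is the pointwise upper-alpha quantile of that exact law
(``sig_method="beta"``), with the classical chi-square approximation
available as ``sig_method="chi2"`` (it overstates the threshold when the
folded table consumes a sizable share of the degrees of freedom, i.e. at
long candidate periods in short windows). The peak is the super-threshold
candidate maximising ``Q - sig_line``; its height above the line ("power")
and the width of the contiguous super-threshold interval containing it are
both rhythm-strength measures.

Conventions follow standard DAM practice: activity is aggregated into
30-minute bins, candidate periods span 16-32 h on the bin grid (0.5-h
resolution), and the analysis window opens a configurable offset after the
lights-off transition into constant darkness and spans a fixed number of
days (defaults: 24 h and 6 days).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .dam_io import ActivityTrace, Experiment, rebin
from .sleep_metrics import flag_dead

DEFAULT_BIN_MIN = 30
DEFAULT_PERIOD_RANGE_H = (16.0, 32.0)
DEFAULT_DD_OFFSET_H = 24.0
DEFAULT_DD_DAYS = 6


@dataclass
class PeriodogramResult:
    candidate_periods_h: np.ndarray
    Q: np.ndarray
    sig_line: np.ndarray
    peak_period_h: float | None
    power: float | None
    width_h: float | None
    rhythmic: bool


def _dd_window(trace: ActivityTrace, offset_h: float, days: int) -> ActivityTrace:
    """Slice the DD analysis window (minute-resolution trace)."""
    if trace.schedule.regime != "DD" or trace.schedule.dd_start is None:
        raise ValueError("periodogram needs a DD schedule with dd_start")
    dd_bin = max(trace._bins_until(trace.schedule.dd_start), 0)
    start = dd_bin + int(round(offset_h * 60)) // trace.bin_min
    stop = start + days * 1440 // trace.bin_min
    if stop > len(trace):
        raise ValueError(
            f"trace too short for a {days}-day window starting {offset_h} h into DD"
        )
    return trace.slice_bins(start, stop)


def chi_square_periodogram(
    trace: ActivityTrace,
    period_range_h: tuple[float, float] = DEFAULT_PERIOD_RANGE_H,
    alpha: float = 0.05,
    bin_min: int = DEFAULT_BIN_MIN,
    dd_offset_h: float = DEFAULT_DD_OFFSET_H,
    dd_days: int = DEFAULT_DD_DAYS,
    take_dd_window: bool = True,
    bonferroni: bool = False,
    sig_method: str = "beta",
) -> PeriodogramResult:
    """Sokolove-Bushell chi-square periodogram of a DD activity trace.

    With ``take_dd_window`` (default) the analysis window is extracted from
    the trace's DD segment first. ``bonferroni`` divides alpha by the
    number of candidates (off by default: the significance line is the
    pointwise 5% level). ``sig_method`` selects the exact finite-sample
    (``"beta"``, default) or classical asymptotic (``"chi2"``) null
    quantile for the significance line.
    """
    if sig_method not in ("beta", "chi2"):
        raise ValueError("sig_method must be 'beta' or 'chi2'")
    if take_dd_window:
        trace = _dd_window(trace, dd_offset_h, dd_days)
    if trace.bin_min != bin_min:
        trace = rebin(trace, bin_min)
    x = trace.counts.astype(float)
    n = x.size
    bin_h = bin_min / 60.0

    p_lo = int(np.ceil(period_range_h[0] / bin_h))
    p_hi = int(np.floor(period_range_h[1] / bin_h))
    if p_hi < p_lo:
        raise ValueError("empty candidate-period grid")
    if n < 2 * p_hi:
        raise ValueError(
            f"window of {n} bins is shorter than twice the longest candidate "
            f"period ({p_hi} bins)"
        )
    periods = np.arange(p_lo, p_hi + 1)
    level = alpha / periods.size if bonferroni else alpha

    Q = np.empty(periods.size)
    sig = np.empty(periods.size)
    for i, p in enumerate(periods):
        k = n // p
        used = x[: k * p].reshape(k, p)
        xbar = used.mean()
        denom = ((used - xbar) ** 2).sum()
        if denom == 0:
            raise ValueError("zero variance in analysis window")
        col_means = used.mean(axis=0)
        n_used = k * p
        s2 = denom / n_used
        Q[i] = k * ((col_means - xbar) ** 2).sum() / s2
        if sig_method == "beta":
            sig[i] = n_used * sps.beta.ppf(1.0 - level, (p - 1) / 2, (n_used - p) / 2)
        else:
            sig[i] = sps.chi2.ppf(1.0 - level, p - 1)

    excess = Q - sig
    above = excess > 0
    if above.any():
        peak = int(np.argmax(np.where(above, excess, -np.inf)))
        lo = peak
        while lo > 0 and above[lo - 1]:
            lo -= 1
        hi = peak
        while hi < above.size - 1 and above[hi + 1]:
            hi += 1
        result = PeriodogramResult(
            candidate_periods_h=periods * bin_h,
            Q=Q,
            sig_line=sig,
            peak_period_h=float(periods[peak] * bin_h),
            power=float(excess[peak]),
            width_h=float((hi - lo + 1) * bin_h),
            rhythmic=True,
        )
    else:
        result = PeriodogramResult(
            candidate_periods_h=periods * bin_h,
            Q=Q,
            sig_line=sig,
            peak_period_h=None,
            power=None,
            width_h=None,
            rhythmic=False,
        )
    return result


def rhythmicity_table(
    experiment: Experiment,
    **periodogram_kwargs,
) -> pd.DataFrame:
    """Per-group percent rhythmic and mean period/power/width.

    Non-rhythmic flies are excluded from the period, power and width means
    (only rhythmic flies inform rhythm parameters); dead flies are excluded
    entirely. Flies whose analysis window has zero variance are treated as
    dead.
    """
    rows = []
    for genotype, traces in experiment.groups().items():
        per_fly = []
        for t in traces:
            if flag_dead(t):
                continue
            try:
                per_fly.append(chi_square_periodogram(t, **periodogram_kwargs))
            except ValueError:
                continue  # zero-variance window: effectively no activity
        if not per_fly:
            continue
        rhythmic = [r for r in per_fly if r.rhythmic]
        rows.append(
            {
                "genotype": genotype,
                "n": len(per_fly),
                "n_rhythmic": len(rhythmic),
                "percent_rhythmic": 100.0 * len(rhythmic) / len(per_fly),
                "mean_period_h": (
                    float(np.mean([r.peak_period_h for r in rhythmic]))
                    if rhythmic else np.nan
                ),
                "mean_power": (
                    float(np.mean([r.power for r in rhythmic])) if rhythmic else np.nan
                ),
                "mean_width_h": (
                    float(np.mean([r.width_h for r in rhythmic])) if rhythmic else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def actogram_matrix(
    trace: ActivityTrace,
    double_plot: bool = True,
    bin_min: int = DEFAULT_BIN_MIN,
) -> np.ndarray:
    """Day-by-time matrix of binned activity for actogram plotting.

    Row ``d`` holds day ``d``; when double-plotted, day ``d + 1`` is
    concatenated to its right (so consecutive rows overlap by one day) and
    missing trailing data are NaN.
    """
    if trace.bin_min != bin_min:
        trace = rebin(trace, bin_min)
    per_day = 1440 // bin_min
    n_days = int(np.ceil(len(trace) / per_day))
    padded = np.full(n_days * per_day, np.nan)
    padded[: len(trace)] = trace.counts
    days = padded.reshape(n_days, per_day)
    if not double_plot:
        return days
    right = np.full_like(days, np.nan)
    right[:-1] = days[1:]
    return np.hstack([days, right])
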