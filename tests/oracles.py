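"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles (brute force,
enumeration, or direct numerical evaluation of renewal theory) and shares
no code with the package implementation it checks.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
from scipy import stats as sps


# ---------------------------------------------------------------------------
# Sleep-bout detection: run-length-encoding oracle
# ---------------------------------------------------------------------------

def rle_sleep_bouts(counts, threshold: int = 5) -> list[tuple[int, int]]:
    """(onset, duration) of every maximal zero run of length >= threshold."""
    bouts = []
    run = 0
    for i, c in enumerate(counts):
        if c == 0:
            run += 1
        else:
            if run >= threshold:
                bouts.append((i - run, run))
            run = 0
    if run >= threshold:
        bouts.append((len(counts) - run, run))
    return bouts


# ---------------------------------------------------------------------------
# Renewal theory for the simulator's night dynamics
# ---------------------------------------------------------------------------

def rounded_lognormal_pmf(mean: float, sigma: float, tail: float = 1e-10):
    """pmf of max(1, round(X)) for X ~ lognormal with the given mean.

    Returns (support 1..kmax as ints, probabilities).
    """
    mu = math.log(mean) - 0.5 * sigma**2
    dist = sps.lognorm(s=sigma, scale=math.exp(mu))
    kmax = max(2, int(math.ceil(dist.ppf(1.0 - tail))) + 2)
    k = np.arange(1, kmax + 1)
    pmf = dist.cdf(k + 0.5) - dist.cdf(k - 0.5)
    pmf[0] += dist.cdf(1.5) - pmf[0]  # all mass below 1.5 maps to 1
    pmf = np.clip(pmf, 0, None)
    return k, pmf / pmf.sum()


def _dense(k: np.ndarray, pmf: np.ndarray, length: int) -> np.ndarray:
    out = np.zeros(length)
    sel = k < length
    out[k[sel]] = pmf[sel]
    return out


def night_renewal_expectations(
    wake_mean: float,
    sleep_mean: float,
    first_wake_mean: float,
    sigma: float,
    threshold: int = 5,
    night_len: int = 720,
) -> dict[str, float]:
    """Exact expectations for one night of the alternating renewal process.

    The night starts at lights-off with a fresh wake bout drawn from the
    first-night distribution; thereafter wake and sleep bouts alternate
    with night-phase means. Computed by direct convolution dynamic
    programming at minute resolution:

    * ``total_sleep``: E[minutes asleep in the 720-min window]
    * ``bout_count``: E[# sleep bouts with onset in the window and
      duration >= threshold] (the detectable ones)
    * ``mean_bout_duration``: E[duration | duration >= threshold]
    * ``latency``: E[measured latency], i.e. onset of the first detectable
      sleep bout, or the window length when none occurs.
    """
    L = night_len
    kw, fw = rounded_lognormal_pmf(wake_mean, sigma)
    ks, fs = rounded_lognormal_pmf(sleep_mean, sigma)
    k1, f1 = rounded_lognormal_pmf(first_wake_mean, sigma)
    fw_d = _dense(kw, fw, L)
    fs_d = _dense(ks, fs, L)
    f1_d = _dense(k1, f1, L)

    # S[t] / W[t]: P(sleep / non-first wake bout onsets at minute t)
    S = np.zeros(L)
    W = np.zeros(L)
    for t in range(1, L):
        s = f1_d[t]
        if t >= 2:
            s += float(np.dot(W[1:t], fw_d[1:t][::-1]))
        S[t] = s
        W[t] = float(np.dot(S[1:t], fs_d[1:t][::-1])) if t >= 2 else 0.0

    # surv[j] = P(sleep duration > j); minute m of a bout onsetting at u is
    # asleep iff duration > m - u
    surv = 1.0 - np.cumsum(_dense(ks, fs, L + 1))
    p_asleep = np.array(
        [float(np.dot(S[: m + 1], surv[: m + 1][::-1])) for m in range(L)]
    )
    p_detect = float(fs[ks >= threshold].sum())
    mean_detected = float((ks[ks >= threshold] * fs[ks >= threshold]).sum() / p_detect)

    # first *detectable* sleep onset: short sleep bouts (< threshold) may
    # precede it without ending the wait
    fs_short = np.where(np.arange(L) > 0, fs_d, 0.0).copy()
    fs_short[threshold:] = 0.0
    A = np.zeros(L)  # any-sleep onset at t, no detectable bout so far
    B = np.zeros(L)  # wake onset at t after an undetected sleep bout
    for t in range(1, L):
        a = f1_d[t]
        if t >= 2:
            a += float(np.dot(B[1:t], fw_d[1:t][::-1]))
        A[t] = a
        B[t] = float(np.dot(A[1:t], fs_short[1:t][::-1])) if t >= 2 else 0.0
    p_first = A * p_detect
    latency = float(np.dot(np.arange(L), p_first) + L * (1.0 - p_first.sum()))

    return {
        "total_sleep": float(p_asleep.sum()),
        "bout_count": float(S.sum() * p_detect),
        "mean_bout_duration": mean_detected,
        "latency": latency,
        "sleep_fraction_stationary": (
            _pmf_mean(ks, fs) / (_pmf_mean(ks, fs) + _pmf_mean(kw, fw))
        ),
    }


def _pmf_mean(k: np.ndarray, pmf: np.ndarray) -> float:
    return float(np.dot(k, pmf))


# ---------------------------------------------------------------------------
# Brute-force chi-square periodogram folding
# ---------------------------------------------------------------------------

def brute_force_Q(x: np.ndarray, p_bins: int) -> float:
    """Sokolove-Bushell statistic computed by explicit row/column loops."""
    x = np.asarray(x, dtype=float)
    k = len(x) // p_bins
    used = [x[r * p_bins + c] for r in range(k) for c in range(p_bins)]
    xbar = sum(used) / len(used)
    col_means = []
    for c in range(p_bins):
        col = [x[r * p_bins + c] for r in range(k)]
        col_means.append(sum(col) / k)
    num = k * sum((b - xbar) ** 2 for b in col_means)
    s2 = sum((v - xbar) ** 2 for v in used) / len(used)
    return num / s2


# ---------------------------------------------------------------------------
# Mann-Whitney exact enumeration
# ---------------------------------------------------------------------------

def mw_u(a, b) -> float:
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def mw_exact_enumeration(a, b) -> tuple[float, float]:
    """U and two-sided p by enumerating all group assignments of the pool."""
    a, b = list(a), list(b)
    n_a = len(a)
    pooled = a + b
    idx = range(len(pooled))
    u_obs = mw_u(a, b)
    us = []
    for comb in combinations(idx, n_a):
        sel = set(comb)
        aa = [pooled[i] for i in comb]
        bb = [pooled[i] for i in idx if i not in sel]
        us.append(mw_u(aa, bb))
    us = np.array(us)
    total = us.size
    p_lo = (us <= u_obs + 1e-9).sum() / total
    p_hi = (us >= u_obs - 1e-9).sum() / total
    return u_obs, min(1.0, 2.0 * min(p_lo, p_hi))
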