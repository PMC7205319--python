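"""Nonparametric group-comparison layer for sleep-metric screens.

Multi-group designs (an RNAi screen of many genotypes against one pooled
control) are tested with the Kruskal-Wallis rank test followed by Dunn's
post-hoc z comparisons on the pooled mid-ranks; pairwise designs use the
Mann-Whitney U test, exact by permutation enumeration at small n and
tie-corrected normal approximation (with continuity correction) otherwise.

Because the multiple-comparison adjustment inside "Dunn's post hoc" is a
convention rather than a single formula, the adjustment is an explicit,
recorded choice: ``prism_style_family`` (Bonferroni over the tested family,
the behaviour of mainstream GUI statistics packages), ``bonferroni`` (over
all k*(k-1)/2 pairs regardless of the tested subset), or ``none``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_MW_CUTOFF = 12  # enumeration is tractable with both n at or below this

ADJUSTMENTS = ("prism_style_family", "bonferroni", "none")


@dataclass
class PairResult:
    pair: tuple[str, str]
    z: float
    p_raw: float
    p_adjusted: float


@dataclass
class GroupComparison:
    H: float
    p_global: float
    pairwise: list[PairResult] = field(default_factory=list)
    adjustment: str = "prism_style_family"
    family_size: int = 0


def _as_groups(groups: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    out = {}
    for label, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {label!r} is empty")
        out[label] = arr
    if len(out) < 2:
        raise ValueError("need at least two groups")
    return out


def kruskal_wallis(groups: Mapping[str, Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Degenerate all-tied data yield ``H = 0, p = 1`` (no evidence of any
    location difference) rather than an error.
    """
    gs = _as_groups(groups)
    pooled = np.concatenate(list(gs.values()))
    if pooled.size < 3:
        raise ValueError("need at least 3 observations in total")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = sps.kruskal(*gs.values())
    return float(h), float(p)


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float((counts.astype(float) ** 3 - counts).sum())


def dunn_posthoc(
    groups: Mapping[str, Sequence[float]],
    control_label: str | None = None,
    adjustment: str = "prism_style_family",
) -> GroupComparison:
    """Dunn's z comparisons on pooled mid-ranks with tie-corrected variance.

    With ``control_label`` set only genotype-versus-control pairs are
    tested (the screen design, which also shrinks the adjustment family);
    otherwise all pairs are. The returned object records the adjustment
    used and the global Kruskal-Wallis test.
    """
    if adjustment not in ADJUSTMENTS:
        raise ValueError(f"adjustment must be one of {ADJUSTMENTS}")
    gs = _as_groups(groups)
    if control_label is not None and control_label not in gs:
        raise ValueError(f"control label {control_label!r} not among groups")
    h, p_global = kruskal_wallis(gs)

    labels = list(gs)
    pooled = np.concatenate([gs[k] for k in labels])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    mean_ranks = {}
    i = 0
    for k in labels:
        n_k = gs[k].size
        mean_ranks[k] = ranks[i:i + n_k].mean()
        i += n_k

    tie_correction = _tie_term(pooled) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_correction

    if control_label is not None:
        pairs = [(k, control_label) for k in labels if k != control_label]
    else:
        pairs = [
            (labels[i], labels[j])
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        ]
    n_family = len(pairs)
    n_all_pairs = len(labels) * (len(labels) - 1) // 2

    results = []
    for a, b in pairs:
        var = base_var * (1.0 / gs[a].size + 1.0 / gs[b].size)
        if var <= 0:
            z, p_raw = 0.0, 1.0
        else:
            z = (mean_ranks[a] - mean_ranks[b]) / np.sqrt(var)
            p_raw = float(2.0 * sps.norm.sf(abs(z)))
        if adjustment == "prism_style_family":
            p_adj = min(1.0, p_raw * n_family)
        elif adjustment == "bonferroni":
            p_adj = min(1.0, p_raw * n_all_pairs)
        else:
            p_adj = p_raw
        results.append(PairResult((a, b), float(z), p_raw, p_adj))

    return GroupComparison(
        H=h,
        p_global=p_global,
        pairwise=results,
        adjustment=adjustment,
        family_size=n_family,
    )


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U of the first sample: pairs with a_i > b_j, ties counting one half."""
    greater = (a[:, None] > b[None, :]).sum()
    ties = (a[:, None] == b[None, :]).sum()
    return float(greater) + 0.5 * float(ties)


def _exact_u_distribution(pooled_double_ranks: np.ndarray, n_a: int):
    """Permutation distribution of the rank sum of a size-``n_a`` subset.

    Dynamic programme over doubled mid-ranks (integers even with ties);
    returns (support of doubled rank sums, counts).
    """
    d = np.sort(pooled_double_ranks.astype(np.int64))
    max_w = int(d[-n_a:].sum()) if n_a else 0
    dp = np.zeros((n_a + 1, max_w + 1), dtype=float)
    dp[0, 0] = 1.0
    for r in d:
        for j in range(n_a - 1, -1, -1):
            row = dp[j]
            nz = np.flatnonzero(row)
            if nz.size:
                dp[j + 1, nz + r] += row[nz]
    w = np.arange(max_w + 1)
    counts = dp[n_a]
    keep = counts > 0
    return w[keep], counts[keep]


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    mode: str = "auto",
) -> tuple[float, float]:
    """Mann-Whitney U of the first sample and its two-sided p-value.

    ``mode``: ``exact_small_n`` enumerates the permutation distribution of
    U over all group assignments (ties handled through mid-ranks);
    ``normal_approx_tie_corrected`` uses the tie-corrected normal
    approximation with continuity correction; ``auto`` picks exact when
    both samples have at most 12 observations.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if mode == "auto":
        mode = (
            "exact_small_n"
            if max(a.size, b.size) <= EXACT_MW_CUTOFF
            else "normal_approx_tie_corrected"
        )
    u = _u_statistic(a, b)
    n_a, n_b = a.size, b.size

    if mode == "exact_small_n":
        pooled = np.concatenate([a, b])
        double_ranks = np.rint(2.0 * sps.rankdata(pooled)).astype(np.int64)
        w_support, counts = _exact_u_distribution(double_ranks, n_a)
        total = counts.sum()
        # doubled U of sample a from its doubled rank sum W2:
        # U = R1 - n_a*(n_a+1)/2, so 2U = W2 - n_a*(n_a+1)
        u2_support = w_support - n_a * (n_a + 1)
        u2_obs = int(round(2 * u))
        p_lo = counts[u2_support <= u2_obs].sum() / total
        p_hi = counts[u2_support >= u2_obs].sum() / total
        p = min(1.0, 2.0 * min(p_lo, p_hi))
    elif mode == "normal_approx_tie_corrected":
        pooled = np.concatenate([a, b])
        n = n_a + n_b
        mean_u = n_a * n_b / 2.0
        var_u = (
            n_a * n_b / 12.0 * ((n + 1) - _tie_term(pooled) / (n * (n - 1)))
        )
        if var_u <= 0:
            return u, 1.0
        z = (abs(u - mean_u) - 0.5) / np.sqrt(var_u)
        p = min(1.0, float(2.0 * sps.norm.sf(max(z, 0.0))))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return u, float(p)


# ---------------------------------------------------------------------------
# Screen-table assembly
# ---------------------------------------------------------------------------

def screen_table(
    metrics_df: pd.DataFrame,
    metrics: Sequence[str],
    control_label: str,
    adjustment: str = "prism_style_family",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-genotype screen results against a pooled control.

    ``metrics_df`` holds one row per fly (``genotype`` plus one column per
    metric; a ``dead`` column, if present, excludes those flies). Each
    output row carries group mean, SEM, n, the Dunn-vs-control adjusted p
    and a significance flag at ``alpha``; the control row appears once per
    metric with no p-value.
    """
    df = metrics_df
    if "dead" in df.columns:
        df = df[~df["dead"].astype(bool)]
    if control_label not in set(df["genotype"]):
        raise ValueError(f"control group {control_label!r} absent")
    rows = []
    for metric in metrics:
        if metric not in df.columns:
            raise ValueError(f"metric {metric!r} absent from summaries")
        sub = df[["genotype", metric]].dropna()
        groups = {
            g: v[metric].to_numpy() for g, v in sub.groupby("genotype", sort=False)
        }
        comp = dunn_posthoc(groups, control_label=control_label, adjustment=adjustment)
        p_by_genotype = {pr.pair[0]: pr.p_adjusted for pr in comp.pairwise}
        for g, vals in groups.items():
            n = vals.size
            sem = float(vals.std(ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            p_adj = p_by_genotype.get(g, np.nan)
            rows.append(
                {
                    "metric": metric,
                    "genotype": g,
                    "mean": float(vals.mean()),
                    "sem": sem,
                    "n": int(n),
                    "p_adjusted": p_adj,
                    "significant": bool(p_adj <= alpha) if g != control_label else False,
                    "adjustment": adjustment,
                    "is_control": g == control_label,
                }
            )
    return pd.DataFrame(rows)
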