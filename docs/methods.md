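# Methods

This note documents the models, conventions and numerical choices behind
`flysomnus`, and what the simulator-based tests do and do not demonstrate
about real monitor data.

## Data model and conventions

A recording is a per-minute (or coarser) vector of non-negative
beam-crossing counts per fly, annotated with a light schedule. Bins are
half-open `[t, t + bin)`; a lights transition at time `T` belongs to the
bin starting at `T`. Phase labels (day / night / subjective) derive solely
from the configured incubator program — never from a monitor light-sensor
column — with ZT0 at lights-on and a 12:12 cycle by default. Timestamps
must be gap-free at a fixed cadence; a missing minute is an error rather
than something to impute, because run-length sleep detection is undefined
across gaps. DAM files follow the de-facto DAM2 text dialect (record
index, date, time, status code, six auxiliary columns, 32 count columns);
rows with a non-valid status are retained and flagged by default, and may
be dropped only at the file edges.

Acclimatization handling discards everything before the first lights-on
transition at least 12 h after recording start (both the bound and a
fixed-hours alternative are configurable), reflecting the usual 12–24 h
settling period before analysis.

## Sleep metrics

Sleep is the standard fly proxy: a maximal run of ≥ 5 consecutive
zero-count minutes. Detection requires minute resolution and is an exact
run-length operation; quiescence runs touching a trace boundary are kept at
their observed length and flagged censored.

Attribution across the day/night boundary follows two deliberate rules:

- totals, waking-activity denominators and bout-size fractions use
  per-minute clipping to the window, so minutes are conserved
  (sleep + wake = window length, always);
- bout count and mean bout duration use bouts whose *onset* lies in the
  window, at full unclipped duration, because bout-architecture statistics
  describe episodes, which fly studies attribute wholesale to the phase in
  which they begin.

Latency is minutes from lights-off to the first bout onset at or after
lights-off; 0 if a bout is ongoing at lights-off; the full window length
with a `no_sleep` flag when no bout occurs, which keeps the quantity
defined and bounded for group statistics. Night bout-size classes are
≤ 49 / 50–149 / 150–720 min on window-clipped durations; the short class
is open at the bottom so phase-clipped fragments still land in a class and
fractions always sum to one (unclipped detected bouts are ≥ 5 min by
construction). The dead-fly filter counts minutes with at least one
crossing (< 10 such minutes in any complete light or dark phase = dead);
counting active minutes rather than total crossings matches common DAM
practice, and the alternative reading is a parameter.

"Waking activity" divides window counts by window minutes not covered by
any detected bout, so sub-threshold quiescent minutes count as waking time
(the default; the exclusion variant is a flag).

## Simulator

The generator is an alternating-renewal (semi-Markov) process chosen to
match the statistical structure the analysis assumes, while remaining
analytically tractable:

- Wake and sleep bout durations are lognormal (heavy right tail: long
  consolidated night bouts versus short fragmented ones) with
  phase-dependent means, a common shape parameter σ = 0.6, rounded to
  whole minutes with a 1-min floor. A geometric option exists for
  oracle simplicity. Parameters are fixed at bout onset, never re-drawn
  mid-bout, which keeps renewal expectations exact.
- At every lights-off transition the ongoing bout is terminated and a
  fresh wake bout with mean `first_night_wake_mean` begins. This models
  the evening activity peak, makes sleep-onset latency tunable
  independently of fragmentation, and renders each night an independent
  renewal epoch — enabling an exact dynamic-programming oracle for night
  totals, bout counts, durations and latency.
- Wake minutes emit zero-truncated Poisson counts (rate 2/min by
  default), sleep minutes emit zero, so with
  `micro_quiescence_prob = 0` detected quiescence equals the latent sleep
  state exactly. That probability exists solely to inject spurious
  zero-count wake minutes for probing the 5-min threshold's robustness.
- Under DD, the wake mean is multiplied and the sleep mean divided by the
  gate `g(t) = 1 + A·cos(2π(t − φ)/τ)` at bout onset, with φ anchored at
  projected mid-day and baseline means the geometric mean of the day and
  night values. Amplitude A = 0.6 yields strongly rhythmic flies; A = 0
  removes the clock.
- Deprivation is an overlay on the undisturbed latent process: inside the
  window every minute's count is forced to its pre-drawn wake value
  (≥ 1), and sleep bouts *onsetting* within `rebound_hours` after the
  window have their continuous durations multiplied by
  `rebound_multiplier` before rounding. With multiplier 1 an equal-seed
  trace is bit-identical outside the window, so deprivation alone cannot
  bias the excess-sleep metric — its expectation is exactly zero.
- All randomness flows from one seed through independent substreams
  (bouts, counts, micro-quiescence); per-fly seeds derive from a master
  seed by the counter scheme `SeedSequence([master, fly_index])`, so
  cohorts extend without reshuffling existing flies.

Preset parameters encode the calibration anchors of the motivating study
system: sleep-onset latencies of 40 (control male) / 70 (mutant-like male)
/ 70 (control female) / 110 (mutant-like female) minutes; free-running
periods of 23.5–23.6 h; and mutant-like night sleep-bout means roughly
half of control with unchanged night wake means, producing shorter, more
numerous bouts (fragmentation) and reduced total sleep. Day/night means
(e.g. control male: wake 30/15, sleep 30/90 min) were set once to give
realistic totals — roughly 360 min day sleep and 590 min night sleep for
control males, with females sleeping less by day — and are not fitted
quantities.

What the simulator does *not* model: mechanical-stimulus beam-crossing
artifacts, positional multi-beam data, arousal thresholds, temperature
effects, and two-process homeostat dynamics (rebound is injected by the
multiplier, not produced by accumulated sleep pressure). Passing
simulator-based tests therefore certifies the *computational* layer — the
metrics, statistics and file handling — not the biological fidelity of any
particular dataset.

## Chi-square periodogram

The statistic is the classical Sokolove–Bushell form. For candidate period
`p` bins (30-min bins; grid 16–32 h in 0.5-h steps), fold the first
`K·p` bins (`K = ⌊N/p⌋`, remainder discarded to preserve the reference
distribution) into a `K × p` array and compute
`Q_p = K Σ_h (B̄_h − x̄)² / s²` with `s² = Σ (x_i − x̄)²/N` over used bins.

Under an independent-noise null the numerator and denominator sums of
squares decompose orthogonally, giving the exact law
`Q_p / N ~ Beta((p−1)/2, (N−p)/2)` — the χ²(p−1) reference is its
large-`N` limit. The default significance line is the pointwise 5%
quantile of the exact Beta law; with 6-day windows the χ² approximation
overstates thresholds at long candidate periods (where the folded table
consumes over a fifth of the degrees of freedom), deflating the false-
positive rate to ≈ 0.024 instead of 0.05. The χ² line is retained as
`sig_method="chi2"` for comparability with legacy software. The line is
pointwise (per candidate) by default, matching how rhythm-strength "power"
is conventionally read; a Bonferroni option divides α by the number of
candidates.

A fly is called rhythmic when any candidate exceeds the line; the peak is
the super-threshold candidate maximizing `Q − sig_line`; power is that
excess and width the length of the contiguous super-threshold interval —
both descriptive strength measures. The analysis window opens 24 h after
the lights-off transition into DD and spans 6 days by default; both are
configurable (reported protocols vary between starting 2 h and 24 h after
the transition, so the offset is surfaced rather than hard-coded).

Two caveats, verified by simulation and documented rather than hidden:

1. The null calibration statement (per-candidate false-positive rate ≈ 5%)
   holds for independent noise. Renewal sleep/wake traces are strongly
   autocorrelated at 30-min lags, and *any* periodogram referenced against
   an independence null over-calls rhythmicity on such data: the gate-free
   (`arrhythmic`) preset is called rhythmic far above the 5% level despite
   having no circadian structure. Percent-rhythmic comparisons between
   groups remain meaningful; the absolute rate is not a p-value.
2. Periods are reported on the 0.5-h grid forced by 30-min bins, hence
   recovered values like 23.5 or 24.0 rather than arbitrary reals.

## Deprivation metrics

The deprivation window is the final 6 h of a designated night, ending at
lights-on. Efficacy is sleep remaining inside the window (exactly 0 under
simulator-forced wake). Excess (rebound) sleep is computed per fly —
first-3-h-of-light sleep after the deprivation night minus the identical
clock window after the undisturbed baseline night — then averaged, which
is the form group SEMs require. Bouts spanning into a window contribute
clipped minutes, consistent with the totals rule; recovery consolidation
averages full durations of bouts initiated within the first 120 min of
light.

## Screen statistics

Kruskal–Wallis (tie-corrected, χ²(k−1) reference; all-tied data return
H = 0, p = 1) gates Dunn's post-hoc z comparisons on the pooled mid-ranks
with tie-corrected variance. When a control is designated, only
genotype-versus-control pairs are tested — the screen design, which also
shrinks the multiplicity family and preserves power. The adjustment is an
explicit recorded choice because "Dunn's post hoc" does not name one:
`prism_style_family` (default) multiplies raw p by the tested-family size,
matching mainstream GUI statistics software; `bonferroni` uses all
k(k−1)/2 pairs regardless of the tested subset; `none` reports raw p.

Mann–Whitney U (statistic of the first sample: pairs `a_i > b_j` plus
half-ties) is exact when both n ≤ 12 — the permutation distribution over
group assignments is computed by dynamic programming on doubled mid-ranks,
handling ties exactly, with two-sided p = 2·min(lower tail, upper tail)
capped at 1 — and otherwise uses the tie-corrected normal approximation
with continuity correction.

Screen tables report group mean, SEM (matching the convention of reporting
means with SEM), live-fly n, the Dunn-vs-control adjusted p and a flag at
α = 0.05; dead flies are excluded upstream.

## Test design and problem sizes

Expected values in tests come from independent oracles, not from the code
under test: run-length encoding for bout detection; an exact
minute-resolution convolution DP over the rounded-lognormal renewal
process for night sleep, bout counts, durations and latency; brute-force
folding for the periodogram; complete enumeration for exact Mann–Whitney;
and hand-derived rank arithmetic for Kruskal–Wallis.

The end-to-end suite runs, per property: 10,000 random traces against the
run-length oracle; 1,000 simulated flies for conservation laws; 200 flies
per preset (3 analyzed nights each) for renewal recovery within 3 Monte-
Carlo SE, including the 40-min latency anchor; 50 flies per τ ∈ {23.0,
23.5, 24.0, 24.5} h for modal period recovery within one grid step; 500
iid-noise replicates for significance-line calibration within 3 SE of
0.05; 500 flies (multiplier 1) and 20 seed sets × 200 flies (multiplier 2)
for rebound calibration; 500 resampled null screens for family-wise error
≤ 0.05 + 3 SE; and byte-exact DAM round trips on a 40-fly, two-monitor
cohort. These sizes keep the suite to a few minutes on one CPU while
leaving Monte-Carlo bands far smaller than the effects of interest.
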