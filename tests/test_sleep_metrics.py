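import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flysomnus import (
    Experiment,
    bin_fractions,
    detect_sleep_bouts,
    flag_dead,
    phase_windows,
    sleep_profile,
    summarize_experiment,
    summarize_trace,
    summarize_window,
)
from flysomnus.sleep_metrics import Window, sleep_latency_in, sleep_indicator

from oracles import rle_sleep_bouts


class TestDetectSleepBouts:
    def test_five_minute_rule(self):
        bouts = detect_sleep_bouts([1, 0, 0, 0, 0, 0, 1])
        assert [(b.onset, b.duration_min) for b in bouts] == [(1, 5)]

    def test_subthreshold_runs_are_not_sleep(self):
        counts = [1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 2]
        bouts = detect_sleep_bouts(counts)
        assert [(b.onset, b.duration_min) for b in bouts] == [(6, 6)]

    def test_boundary_runs_are_censored(self):
        bouts = detect_sleep_bouts([0] * 7 + [1] + [0] * 6)
        assert bouts[0].censored_start and not bouts[0].censored_end
        assert bouts[1].censored_end and not bouts[1].censored_start

    def test_non_minute_bins_are_an_error(self, make_trace):
        from flysomnus import rebin

        tr = rebin(make_trace(np.ones(60, dtype=int)), 30)
        with pytest.raises(ValueError, match="1-min"):
            detect_sleep_bouts(tr)

    @given(st.lists(st.integers(0, 1), min_size=1, max_size=300))
    def test_matches_rle_oracle(self, counts):
        got = [(b.onset, b.duration_min) for b in detect_sleep_bouts(counts)]
        assert got == rle_sleep_bouts(counts)

    @given(
        st.lists(st.integers(0, 1), min_size=1, max_size=200),
        st.integers(1, 10),
        st.integers(1, 10),
    )
    def test_raising_threshold_is_monotone(self, counts, t1, t2):
        lo, hi = sorted((t1, t2))
        b_lo = detect_sleep_bouts(counts, lo)
        b_hi = detect_sleep_bouts(counts, hi)
        assert len(b_hi) <= len(b_lo)
        assert sum(b.duration_min for b in b_hi) <= sum(b.duration_min for b in b_lo)


class TestSummarizeWindow:
    def test_fully_asleep_night(self, make_trace):
        counts = np.ones(1440, dtype=int)
        counts[720:] = 0
        tr = make_trace(counts)
        night = phase_windows(tr)[1]
        s = summarize_window(tr, detect_sleep_bouts(tr), night)
        assert s.total_sleep_min == 720
        assert s.bout_count == 1 and s.mean_bout_duration_min == 720
        assert s.motion_bout_activity is None

    def test_motion_bout_activity_averages_waking_counts(self, make_trace):
        counts = np.zeros(1440, dtype=int)
        counts[0], counts[1] = 2, 4  # the only waking minutes of the day window
        tr = make_trace(counts)
        day = phase_windows(tr)[0]
        s = summarize_window(tr, detect_sleep_bouts(tr), day)
        assert s.motion_bout_activity == pytest.approx(3.0)

    def test_cross_boundary_bout_attribution(self, make_trace):
        # sleep bout onsets at night minute 700 (trace minute 1420), lasts 100
        counts = np.ones(2880, dtype=int)
        counts[1420:1520] = 0
        tr = make_trace(counts)
        windows = phase_windows(tr)
        night0 = [w for w in windows if w.phase == "night" and w.cycle == 0][0]
        day1 = [w for w in windows if w.phase == "day" and w.cycle == 1][0]
        bouts = detect_sleep_bouts(tr)
        s_night = summarize_window(tr, bouts, night0)
        s_day = summarize_window(tr, bouts, day1)
        assert s_night.total_sleep_min == 20
        assert s_night.bout_count == 1
        assert s_night.mean_bout_duration_min == 100  # unclipped
        assert s_day.total_sleep_min == 80
        assert s_day.bout_count == 0

    def test_empty_window_is_an_error(self, make_trace):
        tr = make_trace(np.ones(1440, dtype=int))
        with pytest.raises(ValueError):
            summarize_window(tr, [], Window("day", 0, 100, 100))

    def test_conservation_sleep_plus_wake_is_window_length(self, make_trace):
        rng = np.random.default_rng(4)
        tr = make_trace((rng.uniform(size=2880) < 0.4).astype(int))
        bouts = detect_sleep_bouts(tr)
        asleep = sleep_indicator(len(tr), bouts)
        for w in phase_windows(tr):
            s = summarize_window(tr, bouts, w)
            wake = (~asleep[w.start:w.stop]).sum()
            assert s.total_sleep_min + wake == len(w)


class TestLatency:
    def test_first_bout_after_lights_off(self):
        night = Window("night", 0, 720, 1440)
        bouts = detect_sleep_bouts(
            np.concatenate([np.ones(730, dtype=int), np.zeros(710, dtype=int)])
        )
        lat = sleep_latency_in(bouts, night)
        assert lat.minutes == 10 and not lat.no_sleep

    def test_asleep_across_lights_off_is_zero(self):
        counts = np.ones(1440, dtype=int)
        counts[700:900] = 0
        lat = sleep_latency_in(detect_sleep_bouts(counts), Window("night", 0, 720, 1440))
        assert lat.minutes == 0

    def test_sleepless_night_is_window_length_flagged(self):
        lat = sleep_latency_in([], Window("night", 0, 720, 1440))
        assert lat.minutes == 720 and lat.no_sleep


class TestBinFractions:
    def test_single_long_bout(self):
        assert bin_fractions([720]) == (0.0, 0.0, 1.0)

    def test_mixed_bouts(self):
        assert bin_fractions([10, 30, 60]) == (0.4, 0.6, 0.0)

    def test_no_sleep_gives_absent_fractions(self):
        assert bin_fractions([]) == (None, None, None)

    @given(st.lists(st.integers(1, 720), min_size=1, max_size=30))
    def test_fractions_sum_to_one(self, durations):
        fracs = bin_fractions(durations)
        assert sum(fracs) == pytest.approx(1.0)


class TestFlagDead:
    def test_nine_active_light_minutes_is_dead(self, make_trace):
        counts = np.zeros(1440, dtype=int)
        counts[:9] = 1       # 9 active minutes in the light phase
        counts[720:920] = 1  # plenty at night
        assert flag_dead(make_trace(counts))

    def test_ten_active_minutes_everywhere_is_alive(self, make_trace):
        counts = np.zeros(1440, dtype=int)
        counts[:10] = 1
        counts[720:730] = 1
        assert not flag_dead(make_trace(counts))

    def test_all_zero_trace_is_dead(self, make_trace):
        assert flag_dead(make_trace(np.zeros(1440, dtype=int)))


class TestSleepProfile:
    def test_fully_asleep_fly_fills_every_bin(self, make_trace):
        live = make_trace(np.ones(1440, dtype=int), fly_id="b", genotype="h")
        # an all-zero fly would be dead by the activity filter; one pulse
        # per hour keeps it alive while leaving every bin nearly full
        counts = np.zeros(1440, dtype=int)
        counts[np.arange(0, 1440, 60)] = 1  # 12 active min per phase
        tr = make_trace(counts, fly_id="a", genotype="g")
        prof = sleep_profile(Experiment(traces=[tr, live]))
        g = prof[prof.genotype == "g"]
        # every 30-min bin has 29 or 30 asleep minutes (one active pulse per hour)
        assert g["mean"].min() >= 29

    def test_mean_and_sem_across_flies(self, make_trace):
        counts_sleep = np.zeros(1440, dtype=int)
        counts_sleep[np.arange(0, 1440, 60)] = 1
        a = make_trace(counts_sleep, fly_id="a", genotype="g")
        b = make_trace(np.ones(1440, dtype=int), fly_id="b", genotype="g")
        prof = sleep_profile(Experiment(traces=[a, b]))
        row = prof[(prof.genotype == "g") & (prof.bin_index == 1)].iloc[0]
        assert row["mean"] == pytest.approx(15.0)
        assert row["sem"] == pytest.approx(15.0)
        assert row["n"] == 2

    def test_profile_sums_equal_total_sleep(self, make_trace):
        rng = np.random.default_rng(7)
        counts = (rng.uniform(size=2880) < 0.5).astype(int)
        counts[np.arange(0, 2880, 30)] = 1  # keep the fly alive
        tr = make_trace(counts, fly_id="a", genotype="g")
        prof = sleep_profile(Experiment(traces=[tr]))
        summ = summarize_trace(tr)
        assert prof["mean"].sum() == sum(s.total_sleep_min for s in summ)

    def test_group_with_no_live_flies_is_an_error(self, make_trace):
        dead = make_trace(np.zeros(1440, dtype=int), fly_id="a", genotype="g")
        with pytest.raises(ValueError, match="live"):
            sleep_profile(Experiment(traces=[dead]))


def test_summary_table_shape_and_phases(make_trace):
    rng = np.random.default_rng(1)
    traces = [
        make_trace((rng.uniform(size=2880) < 0.5).astype(int), fly_id=f"f{i}")
        for i in range(3)
    ]
    df = summarize_experiment(Experiment(traces=traces))
    assert len(df) == 3 * 4  # 2 days + 2 nights per fly
    assert set(df.phase) == {"day", "night"}
    assert df[df.phase == "day"]["latency_min"].isna().all()
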