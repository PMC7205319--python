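import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from flysomnus import (
    Experiment,
    LightSchedule,
    load_experiment,
    read_dam,
    rebin,
    save_experiment,
    simulate_experiment,
    trim_acclimation,
    write_dam,
)
from flysomnus.dam_io import DAMParseError, DAY

from conftest import START_ZT0


def _write_monitor(path, n_rows=2880, n_nonzero_channels=10, start=START_ZT0):
    rng = np.random.default_rng(0)
    counts = np.zeros((n_rows, 32), dtype=int)
    counts[:, :n_nonzero_channels] = rng.poisson(1.0, (n_rows, n_nonzero_channels))
    with open(path, "w") as fh:
        for i in range(n_rows):
            ts = start + pd.Timedelta(minutes=i)
            stamp = f"{ts.day} {ts.strftime('%b %y')}\t{ts.strftime('%H:%M:%S')}"
            fh.write(
                f"{i+1}\t{stamp}\t1\t" + "\t".join(["0"] * 6) + "\t"
                + "\t".join(map(str, counts[i])) + "\n"
            )
    return counts


class TestReadDam:
    def test_mapped_channels_become_traces(self, tmp_path, ld_schedule):
        path = tmp_path / "Monitor1.txt"
        counts = _write_monitor(path)
        design = {c: {"genotype": "ctrl", "sex": "M"} for c in range(1, 11)}
        exp = read_dam(path, design, ld_schedule)
        assert len(exp) == 10
        assert all(len(t) == 2880 for t in exp.traces)
        for c in range(1, 11):
            np.testing.assert_array_equal(exp.traces[c - 1].counts, counts[:, c - 1])

    def test_malformed_row_names_line(self, tmp_path, ld_schedule):
        path = tmp_path / "m.txt"
        _write_monitor(path, n_rows=200)
        lines = path.read_text().splitlines()
        lines[100] = "\t".join(lines[100].split("\t")[:-1])  # drop a column on line 101
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(DAMParseError, match="line 101"):
            read_dam(path, {1: {"genotype": "g", "sex": "M"}}, ld_schedule)

    def test_timing_gap_is_an_error(self, tmp_path, ld_schedule):
        path = tmp_path / "m.txt"
        _write_monitor(path, n_rows=100)
        lines = path.read_text().splitlines()
        del lines[50]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(DAMParseError, match="gap"):
            read_dam(path, {1: {"genotype": "g", "sex": "M"}}, ld_schedule)

    def test_empty_file_is_an_error(self, tmp_path, ld_schedule):
        path = tmp_path / "m.txt"
        path.write_text("")
        with pytest.raises(DAMParseError, match="empty"):
            read_dam(path, {1: {"genotype": "g", "sex": "M"}}, ld_schedule)

    def test_error_status_rows_flagged_or_dropped_at_edges(self, tmp_path, ld_schedule):
        path = tmp_path / "m.txt"
        _write_monitor(path, n_rows=100)
        lines = path.read_text().splitlines()
        parts = lines[0].split("\t")
        parts[3] = "51"
        lines[0] = "\t".join(parts)
        path.write_text("\n".join(lines) + "\n")
        design = {1: {"genotype": "g", "sex": "M"}}
        exp = read_dam(path, design, ld_schedule)
        assert exp.status_flags.sum() == 1 and len(exp.traces[0]) == 100
        exp2 = read_dam(path, design, ld_schedule, drop_error_rows=True)
        assert len(exp2.traces[0]) == 99


class TestWriteDam:
    def test_round_trip_preserves_counts_exactly(self, tmp_path):
        exp = simulate_experiment([("control_male", 5, "ctrl")], days=2, seed=3)
        files = write_dam(exp, tmp_path / "mon.txt")
        assert len(files) == 1
        back = read_dam(files[0][0], files[0][1], exp.traces[0].schedule)
        for a, b in zip(exp.traces, back.traces):
            assert a.fly_id == b.fly_id
            np.testing.assert_array_equal(a.counts, b.counts)

    def test_split_into_32_channel_files(self, tmp_path):
        exp = simulate_experiment([("control_male", 33, "c")], days=1, seed=0)
        with pytest.raises(ValueError, match="split"):
            write_dam(exp, tmp_path / "mon.txt")
        files = write_dam(exp, tmp_path / "mon.txt", allow_split=True)
        assert len(files) == 2
        assert len(files[0][1]) == 32 and len(files[1][1]) == 1

    def test_single_trace_row_count(self, tmp_path, make_trace):
        tr = make_trace(np.ones(60, dtype=int))
        files = write_dam(Experiment(traces=[tr]), tmp_path / "m.txt")
        assert len(files[0][0].read_text().splitlines()) == 60

    def test_empty_experiment_is_an_error(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            write_dam(Experiment(traces=[]), tmp_path / "m.txt")


class TestRebin:
    def test_sums_constituent_bins(self, make_trace):
        tr = make_trace([1, 0, 2, 0, 0, 1])
        np.testing.assert_array_equal(rebin(tr, 2).counts, [1, 2, 1])

    def test_width_equal_to_bin_is_identity(self, make_trace):
        tr = make_trace([3, 1, 4, 1, 5, 9])
        np.testing.assert_array_equal(rebin(tr, 1).counts, tr.counts)

    def test_trailing_partial_bin_dropped(self, make_trace):
        tr = make_trace([1, 1, 1, 1, 1, 1, 7])
        out = rebin(tr, 2)
        assert len(out) == 3 and out.counts.sum() == 6

    def test_finer_width_is_an_error(self, make_trace):
        with pytest.raises(ValueError):
            rebin(rebin(make_trace(np.ones(60, dtype=int)), 30), 10)

    @given(
        counts=st.lists(st.integers(0, 5), min_size=10, max_size=200),
        width=st.integers(1, 10),
    )
    def test_conserves_counts_over_complete_bins(self, counts, width, make_trace):
        tr = make_trace(counts)
        out = rebin(tr, width)
        n_in = (len(counts) // width) * width
        assert out.counts.sum() == sum(counts[:n_in])


class TestTrimAcclimation:
    def test_aligns_to_first_lights_on_after_12h(self, make_trace):
        # recording starts at ZT6: the qualifying lights-on is 18 h later
        start = START_ZT0 + pd.Timedelta(hours=6)
        tr = make_trace(np.ones(3 * 1440, dtype=int), start=start)
        out = trim_acclimation(tr)
        assert len(tr) - len(out) == 18 * 60
        assert out.schedule.zt_minutes(out.start) == 0

    def test_fixed_hours_removes_exactly(self, make_trace):
        tr = make_trace(np.ones(3 * 1440, dtype=int))
        out = trim_acclimation(tr, policy="fixed_hours", fixed_hours=24)
        assert len(tr) - len(out) == 1440

    def test_short_trace_is_an_error(self, make_trace):
        tr = make_trace(np.ones(720, dtype=int))
        with pytest.raises(ValueError):
            trim_acclimation(tr)


class TestPhaseLabels:
    def test_day_minutes_per_ld_day_equal_photoperiod(self, make_trace):
        for photoperiod in (480, 720, 960):
            sched = LightSchedule(photoperiod_min=photoperiod)
            tr = make_trace(np.ones(2 * 1440, dtype=int), schedule=sched)
            labels = tr.phase_labels()
            for d in range(2):
                day_min = (labels[d * 1440:(d + 1) * 1440] == DAY).sum()
                assert day_min == photoperiod

    def test_dd_bins_labelled_subjective(self, make_trace, dd_schedule):
        tr = make_trace(np.ones(3 * 1440, dtype=int), schedule=dd_schedule)
        labels = tr.phase_labels()
        assert set(labels[2160:]) == {"subjective"}
        assert "subjective" not in set(labels[:2160])


def test_tabular_serialization_round_trips_all_fields(tmp_path, dd_schedule):
    exp = simulate_experiment(
        [("control_male", 3, "a"), ("nowl_like_female", 2, "b")],
        days=2,
        seed=7,
        schedule=dd_schedule,
        start=START_ZT0,
    )
    path = tmp_path / "exp.parquet"
    save_experiment(exp, path)
    back = load_experiment(path)
    assert len(back) == len(exp)
    for a, b in zip(exp.traces, back.traces):
        assert (a.fly_id, a.genotype, a.sex, a.bin_min) == (
            b.fly_id, b.genotype, b.sex, b.bin_min
        )
        assert a.start == b.start and a.schedule == b.schedule
        np.testing.assert_array_equal(a.counts, b.counts)
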