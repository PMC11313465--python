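"""Event/diary parsing, overlap repair, and diary-driven windowing."""

import datetime as dt
import logging

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scedmove.events import (
    ActivityClass,
    DiaryEntry,
    FormatError,
    PostureEvent,
    read_diary,
    read_events,
    split_waking_days,
    write_events,
)

from conftest import T0, make_events


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadEvents:
    def test_parses_classes_in_order(self, tmp_path):
        p = _write(
            tmp_path,
            "ev.csv",
            "Time,Interval,ActivityCode,CumulativeStepCount\n"
            "2021-03-01T08:00:00,3600,0,0\n"
            "2021-03-01T09:00:00,600,1,0\n"
            "2021-03-01T09:10:00,300,2,550\n",
        )
        events = read_events(p)
        assert [e.activity_class for e in events] == [
            ActivityClass.SEDENTARY,
            ActivityClass.STANDING,
            ActivityClass.STEPPING,
        ]
        assert [e.duration_s for e in events] == [3600, 600, 300]
        assert events[2].cadence == pytest.approx(110.0)  # 550 steps / 5 min
        assert events[0].cadence == 0.0

    def test_empty_file_with_header(self, tmp_path):
        p = _write(tmp_path, "ev.csv", "Time,Interval,ActivityCode,CumulativeStepCount\n")
        assert read_events(p) == []

    def test_missing_column_names_it(self, tmp_path):
        p = _write(tmp_path, "ev.csv", "Time,Interval,ActivityCode\n")
        with pytest.raises(FormatError, match="CumulativeStepCount"):
            read_events(p)

    def test_unparseable_row_reports_line(self, tmp_path):
        p = _write(
            tmp_path,
            "ev.csv",
            "Time,Interval,ActivityCode,CumulativeStepCount\n"
            "2021-03-01T08:00:00,notanumber,0,0\n",
        )
        with pytest.raises(FormatError, match="line 2"):
            read_events(p)

    def test_unknown_activity_code_rejected(self, tmp_path):
        p = _write(
            tmp_path,
            "ev.csv",
            "Time,Interval,ActivityCode,CumulativeStepCount\n"
            "2021-03-01T08:00:00,600,7,0\n",
        )
        with pytest.raises(FormatError, match="activity code"):
            read_events(p)

    def test_excel_serial_times(self, tmp_path):
        # 44256.0 = 2021-03-01 00:00 in Excel serial days
        p = _write(
            tmp_path,
            "ev.csv",
            "Time,Interval,ActivityCode,CumulativeStepCount\n44256.5,600,0,0\n",
        )
        (ev,) = read_events(p)
        assert ev.start == dt.datetime(2021, 3, 1, 12, 0)

    def test_overlap_truncates_earlier_event(self, tmp_path, caplog):
        p = _write(
            tmp_path,
            "ev.csv",
            "Time,Interval,ActivityCode,CumulativeStepCount\n"
            "2021-03-01T08:00:00,3600,0,0\n"
            "2021-03-01T08:59:00,600,1,0\n",  # starts 60 s before first ends
        )
        with caplog.at_level(logging.WARNING):
            events = read_events(p)
        assert [e.duration_s for e in events] == [3540.0, 600.0]
        assert any("overlap" in r.message for r in caplog.records)


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", ["activpal_events", "simple"])
    def test_write_read_preserves_events(self, tmp_path, dialect):
        events = make_events([("s", 61.37), ("u", 2.5), ("w", 7.25, 112.5), ("s", 33.0)])
        p = tmp_path / "ev.csv"
        write_events(events, p, dialect=dialect)
        back = read_events(p, dialect=dialect)
        assert [(e.start, e.duration_s, e.activity_class) for e in back] == [
            (e.start, e.duration_s, e.activity_class) for e in events
        ]
        for a, b in zip(back, events):
            assert a.cadence == pytest.approx(b.cadence, abs=1e-9)


class TestReadDiary:
    def test_simple_window(self, tmp_path):
        p = _write(tmp_path, "d.csv", "date,rise_time,bed_time\n2021-03-01,07:30,23:00\n")
        (e,) = read_diary(p)
        assert e.window_hours == pytest.approx(15.5)

    def test_bed_after_midnight(self, tmp_path):
        p = _write(tmp_path, "d.csv", "date,rise_time,bed_time\n2021-03-01,08:00,00:30\n")
        (e,) = read_diary(p)
        assert e.window_hours == pytest.approx(16.5)
        assert e.bed.date() == dt.date(2021, 3, 2)

    def test_duplicate_date_rejected(self, tmp_path):
        p = _write(
            tmp_path,
            "d.csv",
            "date,rise_time,bed_time\n2021-03-01,07:30,23:00\n2021-03-01,08:00,22:00\n",
        )
        with pytest.raises(FormatError, match="duplicate"):
            read_diary(p)

    def test_participant_filter(self, tmp_path):
        p = _write(
            tmp_path,
            "d.csv",
            "participant_id,date,rise_time,bed_time\n"
            "A,2021-03-01,07:30,23:00\nB,2021-03-01,08:00,22:00\n",
        )
        entries = read_diary(p, participant_id="B")
        assert len(entries) == 1 and entries[0].rise_time == dt.time(8, 0)


class TestSplitWakingDays:
    def test_boundary_event_clipped(self):
        ev = [PostureEvent(dt.datetime(2021, 3, 1, 22, 0), 7200, ActivityClass.SEDENTARY)]
        diary = [DiaryEntry(dt.date(2021, 3, 1), dt.time(7, 30), dt.time(23, 0))]
        (day,) = split_waking_days(ev, diary)
        assert day.wear_hours == pytest.approx(1.0)
        assert day.events[0].end == dt.datetime(2021, 3, 1, 23, 0)

    def test_inside_window_unchanged(self):
        events = make_events([("s", 60), ("u", 30), ("w", 10, 110)])
        diary = [DiaryEntry(T0.date(), dt.time(7, 0), dt.time(23, 0))]
        (day,) = split_waking_days(events, diary)
        assert day.wear_hours == pytest.approx(100 / 60.0)

    def test_uncovered_date_dropped_with_warning(self, caplog):
        events = make_events([("s", 60)]) + make_events(
            [("s", 60)], start=T0 + dt.timedelta(days=1)
        )
        diary = [DiaryEntry(T0.date(), dt.time(7, 0), dt.time(23, 0))]
        with caplog.at_level(logging.WARNING):
            days = split_waking_days(events, diary, fallback=False)
        assert [d.date for d in days] == [T0.date()]
        assert any("dropped" in r.message for r in caplog.records)

    def test_no_diary_no_fallback_errors(self):
        events = make_events([("s", 60)])
        with pytest.raises(ValueError, match="2021-03-01"):
            split_waking_days(events, [], fallback=False)

    def test_fallback_uses_overnight_sitting(self, caplog):
        # night sitting 00:30-06:30, daytime activity, next night from 23:30
        events = [
            PostureEvent(dt.datetime(2021, 3, 1, 0, 30), 6 * 3600, ActivityClass.SEDENTARY),
            PostureEvent(dt.datetime(2021, 3, 1, 8, 0), 3600, ActivityClass.STANDING),
            PostureEvent(dt.datetime(2021, 3, 1, 23, 30), 7 * 3600, ActivityClass.SEDENTARY),
        ]
        with caplog.at_level(logging.WARNING):
            days = split_waking_days(events, [], fallback=True)
        day = days[0]
        assert day.rise == dt.datetime(2021, 3, 1, 6, 30)
        assert day.bed == dt.datetime(2021, 3, 1, 23, 30)
        # the daytime event survives, the sleep-side fragments do not
        assert any(e.activity_class is ActivityClass.STANDING for e in day.events)
        assert all(e.start >= day.rise and e.end <= day.bed for e in day.events)

    @given(
        durations=st.lists(st.floats(1.0, 7200.0), min_size=1, max_size=20),
        classes=st.lists(st.sampled_from("suw"), min_size=20, max_size=20),
        rise_h=st.floats(5.0, 9.0),
        window=st.floats(10.0, 16.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_clipping_conserves_in_window_time(self, durations, classes, rise_h, window):
        """Total in-window event seconds are identical before and after splitting."""
        start = dt.datetime(2021, 3, 1, 3, 0)
        spec = [(c, d / 60.0, 110.0 if c == "w" else 0.0) for c, d in zip(classes, durations)]
        events = make_events(spec, start=start)
        rise = dt.datetime(2021, 3, 1) + dt.timedelta(hours=rise_h)
        bed = rise + dt.timedelta(hours=window)
        diary = [
            DiaryEntry(dt.date(2021, 3, 1) + dt.timedelta(days=k),
                       rise.time(), bed.time() if bed.day == rise.day else bed.time())
            for k in range(3)
        ]
        days = split_waking_days(events, diary)
        total_after = sum(d.wear_hours for d in days) * 3600.0

        windows = [(d.rise, d.bed) for d in days]
        total_before = 0.0
        for e in events:
            for lo, hi in windows:
                s, t = max(e.start, lo), min(e.end, hi)
                total_before += max(0.0, (t - s).total_seconds())
        assert total_after == pytest.approx(total_before, abs=1e-6)
        for d in days:
            assert all(e.start >= d.rise and e.end <= d.bed for e in d.events)
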