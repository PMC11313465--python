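"""Shared builders for tests: tiny hand-constructed days and series."""

from __future__ import annotations

import datetime as dt

import pytest

from scedmove.design import DayRecord, ParticipantSeries
from scedmove.events import ActivityClass, PostureEvent, WakingDay
from scedmove.metrics import DayMetrics

T0 = dt.datetime(2021, 3, 1, 7, 30)


def make_events(spec, start=T0):
    """Build contiguous events from (class_letter, minutes[, cadence]) tuples.

    Class letters: 's' sedentary, 'u' standing (upright), 'w' stepping (walk).
    """
    classes = {"s": ActivityClass.SEDENTARY, "u": ActivityClass.STANDING,
               "w": ActivityClass.STEPPING}
    events, t = [], start
    for item in spec:
        letter, minutes = item[0], item[1]
        cadence = item[2] if len(item) > 2 else 0.0
        dur = minutes * 60.0
        events.append(PostureEvent(t, dur, classes[letter], cadence))
        t += dt.timedelta(seconds=dur)
    return events


def make_day(spec, start=T0, window_h=None):
    """A WakingDay tiled by `make_events(spec)`; window defaults to the events' span."""
    events = make_events(spec, start)
    end = events[-1].end if events else start
    if window_h is not None:
        end = start + dt.timedelta(hours=window_h)
    return WakingDay(date=start.date(), rise=start, bed=end, events=events)


def dm(value: float, outcome: str = "sedentary_hours", valid: bool = True, **extra) -> DayMetrics:
    """A DayMetrics carrying `value` in one outcome field, rest innocuous."""
    fields = dict(
        sedentary_hours=10.0,
        fragmentation_index=4.0,
        prolonged_bout_fraction=0.4,
        lpa_hours=4.0,
        mvpa_minutes=20.0,
        pct_waking_sedentary=65.0,
        sleep_hours=8.5,
        wear_hours=15.5,
        valid=valid,
    )
    fields[outcome] = value
    fields.update(extra)
    return DayMetrics(**fields)


def make_series(
    pre_vals,
    post_vals,
    baseline_days=None,
    outcome="sedentary_hours",
    pid="P1",
    group="PS",
    post_phase="B",
    start=dt.date(2021, 3, 1),
):
    """A ParticipantSeries with contiguous days: pre_vals in phase A, post_vals after."""
    if baseline_days is None:
        baseline_days = len(pre_vals)
    days = []
    for i, v in enumerate(list(pre_vals) + list(post_vals)):
        phase = "A" if i < len(pre_vals) else post_phase
        days.append(
            DayRecord(
                date=start + dt.timedelta(days=i),
                offset=i,
                phase=phase,
                metrics=dm(v, outcome),
            )
        )
    return ParticipantSeries(id=pid, group=group, baseline_days=baseline_days, days=days)


@pytest.fixture
def demo_bundle(tmp_path):
    """A small synthetic cohort materialized as files (2 per group)."""
    from scedmove.synth import SyntheticConfig, generate_cohort

    cfg = SyntheticConfig(n_per_group=2, seed=17)
    generate_cohort(cfg, tmp_path / "bundle")
    return tmp_path / "bundle", cfg
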