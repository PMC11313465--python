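"""Posture-event and wake-diary I/O, and diary-driven windowing.

Thigh-worn posture monitors (ActivPAL-class devices) export one row per
posture *event*: a timestamped maximal run of a single activity class
(sedentary, standing or stepping) with its duration in seconds and a
cumulative step count.  Analyses of daily movement behavior need those
events partitioned into per-day *waking windows*, which here come from a
wake/sleep diary kept by the participant; a simple overnight-sitting
heuristic is available as a fallback for days the diary does not cover.

Timestamps are naive local clock times.  All interval arithmetic uses the
recorded durations (seconds), never wall-clock subtraction, so daylight
saving transitions cannot corrupt daily totals.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

#: Excel serial day 0 (the convention ActivPAL export files use).
_EXCEL_EPOCH = dt.datetime(1899, 12, 30)

#: Two events are considered contiguous/non-overlapping within this slack (s).
TIME_TOLERANCE_S = 1e-6


class ActivityClass(str, Enum):
    """Posture classes reported by the monitor."""

    SEDENTARY = "sedentary"
    STANDING = "standing"
    STEPPING = "stepping"


#: Numeric activity codes used by the "activpal_events" CSV dialect.
ACTIVITY_CODES = {
    0: ActivityClass.SEDENTARY,
    1: ActivityClass.STANDING,
    2: ActivityClass.STEPPING,
}
_CODE_OF_CLASS = {v: k for k, v in ACTIVITY_CODES.items()}


class FormatError(ValueError):
    """Raised when an input file does not match its declared dialect."""


@dataclass(frozen=True)
class PostureEvent:
    """One monitor event: a maximal run of a single posture class.

    Parameters
    ----------
    start
        Naive local start time.
    duration_s
        Event length in seconds; strictly positive.
    activity_class
        Posture class of the event.
    cadence
        Step cadence in steps/min; 0 for non-stepping classes.
    """

    start: dt.datetime
    duration_s: float
    activity_class: ActivityClass
    cadence: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError(f"event duration must be > 0, got {self.duration_s}")
        if self.cadence < 0:
            raise ValueError("cadence must be >= 0")
        if self.activity_class is not ActivityClass.STEPPING and self.cadence != 0:
            raise ValueError("cadence must be 0 for non-stepping events")

    @property
    def end(self) -> dt.datetime:
        return self.start + dt.timedelta(seconds=self.duration_s)

    @property
    def steps(self) -> float:
        """Steps taken during the event (cadence integrated over duration)."""
        return self.cadence * self.duration_s / 60.0


@dataclass(frozen=True)
class DiaryEntry:
    """One wake-diary row: rise and bed time for a calendar date.

    A ``bed_time`` earlier than ``rise_time`` means the participant went to
    bed after midnight, i.e. the window ends on the next calendar day.
    """

    date: dt.date
    rise_time: dt.time
    bed_time: dt.time

    @property
    def rise(self) -> dt.datetime:
        return dt.datetime.combine(self.date, self.rise_time)

    @property
    def bed(self) -> dt.datetime:
        bed = dt.datetime.combine(self.date, self.bed_time)
        if self.bed_time <= self.rise_time:
            bed += dt.timedelta(days=1)
        return bed

    @property
    def window_hours(self) -> float:
        return (self.bed - self.rise).total_seconds() / 3600.0


@dataclass
class WakingDay:
    """Events of one calendar date clipped to the waking window [rise, bed)."""

    date: dt.date
    rise: dt.datetime
    bed: dt.datetime
    events: list[PostureEvent] = field(default_factory=list)

    @property
    def window_hours(self) -> float:
        return (self.bed - self.rise).total_seconds() / 3600.0

    @property
    def wear_hours(self) -> float:
        """Hours of recorded events inside the window."""
        return sum(e.duration_s for e in self.events) / 3600.0


# ---------------------------------------------------------------------------
# reading and writing event files
# ---------------------------------------------------------------------------

_DIALECTS = ("activpal_events", "simple")


def _parse_time(value, excel_serial: bool) -> dt.datetime:
    if excel_serial:
        return _EXCEL_EPOCH + dt.timedelta(days=float(value))
    return dt.datetime.fromisoformat(str(value))


def read_events(
    path: str | Path,
    dialect: str = "activpal_events",
    *,
    excel_serial: bool | None = None,
    class_map: dict | None = None,
) -> list[PostureEvent]:
    """Read a posture-event CSV and return sorted, non-overlapping events.

    Two dialects are supported.  ``"activpal_events"`` has columns
    ``Time`` (ISO 8601, or Excel serial days when ``excel_serial`` is true
    or the column is numeric), ``Interval`` (seconds), ``ActivityCode``
    (0 sedentary, 1 standing, 2 stepping) and ``CumulativeStepCount``;
    cadence is recovered from the step-count increments.  ``"simple"`` has
    columns ``start,duration_s,activity_class,cadence``.

    Overlapping events are repaired by truncating the earlier event to the
    start of the later one, with a logged warning.  Unknown activity codes
    are rejected unless ``class_map`` maps them to an :class:`ActivityClass`.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    path = Path(path)
    df = pd.read_csv(path)

    if dialect == "activpal_events":
        required = ["Time", "Interval", "ActivityCode", "CumulativeStepCount"]
    else:
        required = ["start", "duration_s", "activity_class", "cadence"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")

    events: list[PostureEvent] = []
    codes = dict(ACTIVITY_CODES)
    if class_map:
        codes.update(class_map)

    prev_cum = 0.0
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        try:
            if dialect == "activpal_events":
                serial = excel_serial
                if serial is None:
                    serial = not isinstance(row.Time, str)
                start = _parse_time(row.Time, serial)
                duration = float(row.Interval)
                code = int(row.ActivityCode)
                if code not in codes:
                    raise ValueError(f"unknown activity code {code}")
                cls = codes[code]
                cum = float(row.CumulativeStepCount)
                step_delta = cum - prev_cum
                prev_cum = cum
                cadence = (
                    step_delta / (duration / 60.0)
                    if cls is ActivityClass.STEPPING and duration > 0
                    else 0.0
                )
            else:
                start = _parse_time(row.start, False)
                duration = float(row.duration_s)
                cls = ActivityClass(str(row.activity_class))
                cadence = float(row.cadence)
            events.append(PostureEvent(start, duration, cls, cadence))
        except (ValueError, TypeError) as exc:
            raise FormatError(f"{path.name}: unparseable row at line {i}: {exc}") from exc

    events.sort(key=lambda e: e.start)
    return _resolve_overlaps(events, source=path.name)


def _resolve_overlaps(events: list[PostureEvent], source: str = "") -> list[PostureEvent]:
    """Truncate any event that overlaps its successor; drop zero-length rests."""
    out: list[PostureEvent] = []
    for ev in events:
        if out:
            prev = out[-1]
            overlap = (prev.end - ev.start).total_seconds()
            if overlap > TIME_TOLERANCE_S:
                logger.warning(
                    "%s: event at %s overlaps next by %.3f s; truncating",
                    source, prev.start, overlap,
                )
                new_dur = prev.duration_s - overlap
                if new_dur <= TIME_TOLERANCE_S:
                    out.pop()
                else:
                    out[-1] = replace(prev, duration_s=new_dur)
        out.append(ev)
    return out


def write_events(
    events: list[PostureEvent],
    path: str | Path,
    dialect: str = "activpal_events",
) -> None:
    """Write events to CSV in the given dialect (inverse of :func:`read_events`)."""
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    rows = []
    cum = 0.0
    for e in events:
        if dialect == "activpal_events":
            cum += float(e.steps)
            rows.append(
                {
                    "Time": e.start.isoformat(),
                    "Interval": repr(float(e.duration_s)),
                    "ActivityCode": _CODE_OF_CLASS[e.activity_class],
                    "CumulativeStepCount": repr(cum),
                }
            )
        else:
            rows.append(
                {
                    "start": e.start.isoformat(),
                    "duration_s": repr(float(e.duration_s)),
                    "activity_class": e.activity_class.value,
                    "cadence": repr(float(e.cadence)),
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# diaries
# ---------------------------------------------------------------------------


def read_diary(path: str | Path, participant_id: str | None = None) -> list[DiaryEntry]:
    """Read a wake-diary CSV (columns ``date, rise_time, bed_time``, with an
    optional ``participant_id`` column to filter on).

    One entry per date is enforced; windows must be in (0, 24] h.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    for col in ("date", "rise_time", "bed_time"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: missing required column {col!r}")
    if participant_id is not None and "participant_id" in df.columns:
        df = df[df["participant_id"] == str(participant_id)]

    entries: list[DiaryEntry] = []
    seen: set[dt.date] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            date = dt.date.fromisoformat(row.date)
            rise = dt.time.fromisoformat(row.rise_time)
            bed = dt.time.fromisoformat(row.bed_time)
        except ValueError as exc:
            raise FormatError(f"{path.name}: unparseable row at line {i}: {exc}") from exc
        if date in seen:
            raise FormatError(f"{path.name}: duplicate diary entry for {date}")
        seen.add(date)
        entry = DiaryEntry(date, rise, bed)
        if not 0 < entry.window_hours <= 24:
            raise FormatError(
                f"{path.name}: waking window on {date} is {entry.window_hours:.2f} h, "
                "must be in (0, 24]"
            )
        entries.append(entry)
    entries.sort(key=lambda e: e.date)
    return entries


# ---------------------------------------------------------------------------
# windowing
# ---------------------------------------------------------------------------


def _clip_event(ev: PostureEvent, lo: dt.datetime, hi: dt.datetime) -> PostureEvent | None:
    """Intersect an event with [lo, hi); return None if empty."""
    start = max(ev.start, lo)
    end = min(ev.end, hi)
    dur = (end - start).total_seconds()
    if dur <= TIME_TOLERANCE_S:
        return None
    return replace(ev, start=start, duration_s=dur)


def _fallback_window(events: list[PostureEvent], date: dt.date) -> tuple[dt.datetime, dt.datetime] | None:
    """Heuristic waking window when no diary entry exists for ``date``.

    The longest sedentary event overlapping 00:00-06:00 of a day is treated
    as the night's sleep; the waking window runs from the end of that event
    to the start of the next day's sleep event (23:59 if none is found).
    Diaries are always authoritative when present; this is a last resort and
    is logged whenever used.
    """

    def night_sleep(d: dt.date) -> PostureEvent | None:
        lo = dt.datetime.combine(d, dt.time(0, 0))
        hi = lo + dt.timedelta(hours=6)
        cands = [
            e
            for e in events
            if e.activity_class is ActivityClass.SEDENTARY and e.start < hi and e.end > lo
        ]
        return max(cands, key=lambda e: e.duration_s) if cands else None

    sleep = night_sleep(date)
    if sleep is None:
        return None
    rise = max(sleep.end, dt.datetime.combine(date, dt.time(0, 0)))
    nxt = night_sleep(date + dt.timedelta(days=1))
    if nxt is not None and nxt.start > rise:
        bed = nxt.start
    else:
        bed = dt.datetime.combine(date, dt.time(23, 59))
    if bed <= rise:
        return None
    return rise, bed


def split_waking_days(
    events: list[PostureEvent],
    diary: list[DiaryEntry],
    fallback: bool = False,
) -> list[WakingDay]:
    """Partition an event stream into per-day waking windows.

    Events are clipped at window edges: an event spanning a boundary is
    split and only the inside part kept, class preserved, so in-window time
    is conserved.  Dates with recorded events but no diary entry either use
    the overnight-sitting fallback heuristic (``fallback=True``) or are
    dropped with a warning.

    Raises
    ------
    ValueError
        If ``fallback`` is disabled, the diary is empty and there are events
        (no date can be windowed); uncovered dates are listed.
    """
    by_date = {d.date: (d.rise, d.bed) for d in diary}
    event_dates = sorted({e.start.date() for e in events})
    uncovered = [d for d in event_dates if d not in by_date]
    if uncovered and not fallback:
        if not by_date:
            raise ValueError(
                "no diary entries cover the recording and fallback is disabled; "
                f"uncovered dates: {', '.join(str(d) for d in uncovered)}"
            )
        for d in uncovered:
            logger.warning("no diary entry for %s and fallback disabled; day dropped", d)

    days: list[WakingDay] = []
    for date in event_dates:
        if date in by_date:
            rise, bed = by_date[date]
        elif fallback:
            win = _fallback_window(events, date)
            if win is None:
                logger.warning("fallback could not find a sleep window for %s; day dropped", date)
                continue
            rise, bed = win
            logger.warning(
                "no diary entry for %s; fallback window %s-%s used", date, rise.time(), bed.time()
            )
        else:
            continue
        clipped = [
            c for e in events if (c := _clip_event(e, rise, bed)) is not None
        ]
        days.append(WakingDay(date=date, rise=rise, bed=bed, events=clipped))
    return days
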