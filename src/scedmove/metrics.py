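"""Daily movement-behavior outcomes and the sedentary-pattern eligibility screen.

Outcomes per waking day:

* ``sedentary_hours`` — total time in the sedentary posture class.
* ``fragmentation_index`` — number of sedentary bouts per hour of sedentary
  time.  A *bout* is a maximal run of consecutive sedentary events with no
  in-window gap; any upright event or gap terminates it.  Higher values mean
  more interrupted sitting: a rise of 1.1 at 10 h of daily sitting is about
  11 extra interruptions.
* ``prolonged_bout_fraction`` — share of sedentary time accumulated in bouts
  strictly longer than 30 min.
* ``lpa_hours`` / ``mvpa_minutes`` — light vs moderate-to-vigorous physical
  activity.  Posture-class monitors carry no energy expenditure, so MVPA is
  proxied by stepping events at or above a cadence threshold (default
  100 steps/min); all other upright time counts as LPA.

The eligibility screen mirrors the inclusion criterion used to select highly
sedentary people: >= 9.5 h/day sedentary AND (more than half of sedentary
time in >30-min bouts OR below the 150 min/week MVPA guideline).
"""

from __future__ import annotations

from dataclasses import dataclass

from .events import ActivityClass, PostureEvent, WakingDay, TIME_TOLERANCE_S

#: Default cadence (steps/min) at or above which stepping counts as MVPA.
DEFAULT_MVPA_CADENCE = 100.0

#: Default minimum daily recorded wear for a valid day (hours).
DEFAULT_MIN_WEAR_HOURS = 10.0

#: Bout length (minutes) above which sedentary time counts as prolonged.
PROLONGED_BOUT_MIN = 30.0

SEDENTARY_DAILY_THRESHOLD_H = 9.5
PROLONGED_FRACTION_THRESHOLD = 0.5
MVPA_GUIDELINE_MIN_PER_WEEK = 150.0


@dataclass
class DayMetrics:
    """Derived movement-behavior metrics for one participant-day."""

    sedentary_hours: float
    fragmentation_index: float
    prolonged_bout_fraction: float
    lpa_hours: float
    mvpa_minutes: float
    pct_waking_sedentary: float
    sleep_hours: float
    wear_hours: float
    valid: bool


@dataclass
class EligibilityResult:
    """Outcome of the one-week sedentary-pattern screen."""

    mean_daily_sedentary_hours: float
    prolonged_criterion_met: bool
    mvpa_week_minutes: float
    guideline_not_met: bool
    eligible: bool


@dataclass(frozen=True)
class Bout:
    """A maximal run of consecutive sedentary events."""

    start: "object"  # datetime
    duration_s: float

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0


def sedentary_bouts(day: WakingDay) -> list[Bout]:
    """Group the day's sedentary events into maximal contiguous bouts.

    Adjacent sedentary events with zero gap merge into one bout; a
    non-sedentary event or any in-window gap (monitor removed, data lost)
    ends the bout.  No tolerance is applied across brief upright
    interruptions: event streams are already smoothed by the device, so a
    recorded 1-s upright event is a real posture change and breaks the bout.
    """
    bouts: list[Bout] = []
    cur_start = None
    cur_end = None
    for ev in day.events:
        if ev.activity_class is ActivityClass.SEDENTARY:
            if cur_end is not None and abs((ev.start - cur_end).total_seconds()) <= TIME_TOLERANCE_S:
                cur_end = ev.end
            else:
                if cur_start is not None:
                    bouts.append(Bout(cur_start, (cur_end - cur_start).total_seconds()))
                cur_start, cur_end = ev.start, ev.end
        else:
            if cur_start is not None:
                bouts.append(Bout(cur_start, (cur_end - cur_start).total_seconds()))
                cur_start = cur_end = None
    if cur_start is not None:
        bouts.append(Bout(cur_start, (cur_end - cur_start).total_seconds()))
    return bouts


def day_metrics(
    day: WakingDay,
    mvpa_cadence: float = DEFAULT_MVPA_CADENCE,
    min_wear_hours: float = DEFAULT_MIN_WEAR_HOURS,
) -> DayMetrics:
    """Compute :class:`DayMetrics` for one waking day.

    Raises
    ------
    ValueError
        If the day has no recorded wear time.
    """
    wear_h = day.wear_hours
    if wear_h <= 0:
        raise ValueError(f"day {day.date} has no recorded wear time")

    sed_s = sum(
        e.duration_s for e in day.events if e.activity_class is ActivityClass.SEDENTARY
    )
    stand_s = sum(
        e.duration_s for e in day.events if e.activity_class is ActivityClass.STANDING
    )
    step_mvpa_s = sum(
        e.duration_s
        for e in day.events
        if e.activity_class is ActivityClass.STEPPING and e.cadence >= mvpa_cadence
    )
    step_lpa_s = sum(
        e.duration_s
        for e in day.events
        if e.activity_class is ActivityClass.STEPPING and e.cadence < mvpa_cadence
    )

    bouts = sedentary_bouts(day)
    sed_h = sed_s / 3600.0
    fi = len(bouts) / sed_h if sed_h > 0 else 0.0
    prolonged_s = sum(b.duration_s for b in bouts if b.duration_min > PROLONGED_BOUT_MIN)
    prolonged_frac = prolonged_s / sed_s if sed_s > 0 else 0.0

    return DayMetrics(
        sedentary_hours=sed_h,
        fragmentation_index=fi,
        prolonged_bout_fraction=prolonged_frac,
        lpa_hours=(stand_s + step_lpa_s) / 3600.0,
        mvpa_minutes=step_mvpa_s / 60.0,
        pct_waking_sedentary=100.0 * sed_s / (wear_h * 3600.0),
        sleep_hours=24.0 - day.window_hours,
        wear_hours=wear_h,
        valid=wear_h >= min_wear_hours,
    )


def screen_eligibility(
    days: list[DayMetrics],
    guideline_minutes: float = MVPA_GUIDELINE_MIN_PER_WEEK,
    min_valid_days: int = 4,
    weekly_mvpa_mode: str = "rescale",
) -> EligibilityResult:
    """Apply the one-week sedentary-pattern screen to a week of day metrics.

    Only valid days enter the averages.  Weekly MVPA is the sum over valid
    days, rescaled to 7 days when fewer than 7 are valid
    (``weekly_mvpa_mode="rescale"``, the default) or taken as the raw sum
    (``"sum"``).

    Eligible iff mean daily sedentary time >= 9.5 h AND (mean prolonged-bout
    fraction > 0.5 OR weekly MVPA < 150 min).
    """
    if weekly_mvpa_mode not in ("rescale", "sum"):
        raise ValueError(f"unknown weekly_mvpa_mode {weekly_mvpa_mode!r}")
    valid = [d for d in days if d.valid]
    if len(valid) < min_valid_days:
        raise ValueError(
            f"only {len(valid)} valid days; at least {min_valid_days} required for screening"
        )
    mean_sed = sum(d.sedentary_hours for d in valid) / len(valid)
    mean_prolonged = sum(d.prolonged_bout_fraction for d in valid) / len(valid)
    mvpa_week = sum(d.mvpa_minutes for d in valid)
    if weekly_mvpa_mode == "rescale" and len(valid) < 7:
        mvpa_week *= 7.0 / len(valid)

    prolonged_met = mean_prolonged > PROLONGED_FRACTION_THRESHOLD
    guideline_not_met = mvpa_week < guideline_minutes
    eligible = mean_sed >= SEDENTARY_DAILY_THRESHOLD_H and (prolonged_met or guideline_not_met)
    return EligibilityResult(
        mean_daily_sedentary_hours=mean_sed,
        prolonged_criterion_met=prolonged_met,
        mvpa_week_minutes=mvpa_week,
        guideline_not_met=guideline_not_met,
        eligible=eligible,
    )
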