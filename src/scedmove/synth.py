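"""Synthetic posture-event cohorts with the structure the analysis assumes.

The motivating study's raw accelerometry is not public, so this module
generates cohorts that emulate its published statistical structure:

* person-level baseline sedentary time drawn around 11.4 h/day with a
  between-person SD of 1.1 h (the screened, highly sedentary population);
* day-to-day within-person noise around 1.2 h (phase-level SDs in the
  published table run 0.3-2.3 h);
* bout-structured sedentary accumulation with a long right tail (lognormal
  bout lengths), so prolonged >30-min bouts arise as they do in the screened
  population;
* a fragmentation index around 4.1 bouts per sedentary hour (published
  baselines span 2.3-7.2) with its own between/within variability;
* additive intervention effects on daily sedentary hours and fragmentation
  from each participant's randomized baseline duration onward, as a step
  (default) or a linear ramp.

Two layers share one stream of randomness.  The *value layer*
(:func:`generate_cohort_values`) returns participant series of daily
outcome values directly and is what simulation studies (type-I error,
parameter recovery, power) run on.  The *event layer* (:func:`generate_day`,
:func:`generate_cohort`) realizes each day's targets as a posture-event
stream that tiles the waking window exactly and round-trips through the
event I/O and daily-metrics code; it exercises the full pipeline.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (
    DEFAULT_CANDIDATE_DURATIONS,
    DEFAULT_MEASUREMENT_BLOCKS,
    DayRecord,
    DesignSpec,
    ParticipantSeries,
    allocate_baselines,
    measurement_offsets,
)
from .events import ActivityClass, PostureEvent, WakingDay, write_events
from .metrics import DayMetrics


@dataclass
class SyntheticConfig:
    """Generator parameters; defaults emulate the motivating study's cohort."""

    n_per_group: int = 7
    #: person-level baseline daily sedentary time (h): mean and between-person SD
    baseline_sedentary_mean: float = 11.4
    between_person_sd: float = 1.1
    #: day-to-day within-person SD of sedentary hours
    within_person_sd: float = 1.2
    #: person-level baseline fragmentation (bouts per sedentary hour)
    baseline_fragmentation_mean: float = 4.1
    fragmentation_between_sd: float = 1.4
    fragmentation_within_sd: float = 1.0
    #: additive intervention effects (negative sedentary = reduction);
    #: the *_nps variants default to the same value when None
    effect_sedentary_h: float = -1.3
    effect_fragmentation: float = 1.1
    effect_sedentary_h_nps: float | None = None
    effect_fragmentation_nps: float | None = None
    effect_onset: str = "step"  # "step" | "ramp"
    ramp_weeks: int = 5
    #: waking window (h); rise at rise_time, bed rise + window
    waking_window_h: float = 15.5
    rise_time: dt.time = dt.time(7, 30)
    #: daily MVPA minutes distribution (truncated normal at 0)
    mvpa_mean_min: float = 15.0
    mvpa_sd_min: float = 10.0
    mvpa_cadence: float = 115.0
    lpa_cadence: float = 70.0
    #: lognormal sigma of sedentary bout lengths (long right tail)
    bout_sigma: float = 0.9
    allocation_mode: str = "independent"
    candidate_durations: tuple[int, ...] = DEFAULT_CANDIDATE_DURATIONS
    intervention_weeks: int = 15
    followup_days: int = 7
    measurement_blocks: tuple[tuple[int, int], ...] = DEFAULT_MEASUREMENT_BLOCKS
    #: optional dropout to exercise intention-to-treat handling
    dropout_id: str | None = None
    dropout_after_weeks: int = 5
    start_date: dt.date = field(default_factory=lambda: dt.date(2021, 3, 1))
    seed: int = 0

    def design_spec(self, seed: int | None = None) -> DesignSpec:
        participants = [(f"PS-{i + 1}", "PS") for i in range(self.n_per_group)] + [
            (f"NPS-{i + 1}", "NPS") for i in range(self.n_per_group)
        ]
        return DesignSpec(
            participants=participants,
            candidate_durations=self.candidate_durations,
            intervention_weeks=self.intervention_weeks,
            followup_days=self.followup_days,
            measurement_blocks=self.measurement_blocks,
            seed=self.seed if seed is None else seed,
        )


def expected_prolonged_fraction(fragmentation: float, bout_sigma: float) -> float:
    """Analytic share of sedentary time in bouts > 30 min under the
    generator's lognormal bout-length model.

    Bout lengths are lognormal with mean 60/fragmentation minutes and shape
    ``bout_sigma``; the time-weighted share above a cutoff c is
    Phi((mu + sigma^2 - ln c) / sigma).
    """
    if fragmentation <= 0:
        return 1.0
    mean_bout_min = 60.0 / fragmentation
    mu = math.log(mean_bout_min) - bout_sigma**2 / 2.0
    z = (mu + bout_sigma**2 - math.log(30.0)) / bout_sigma
    return 0.5 * (1.0 + math.erf(z / math.sqrt(2.0)))


# ---------------------------------------------------------------------------
# shared target drawing
# ---------------------------------------------------------------------------


def _draw_targets(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[DesignSpec, dict[str, int], dict[str, list[tuple[int, str, dict]]]]:
    """Draw the whole cohort's per-day outcome targets.

    Returns the design, the realized baseline allocation, and per
    participant a list of (offset, phase, targets) where targets holds
    sedentary_h, fragmentation, mvpa_min.
    """
    spec = config.design_spec()
    alloc = allocate_baselines(spec, config.allocation_mode, rng=rng)
    window = config.waking_window_h

    per_participant: dict[str, list[tuple[int, str, dict]]] = {}
    for pid, group in spec.participants:
        b = alloc[pid]
        person_sed = float(
            np.clip(
                rng.normal(config.baseline_sedentary_mean, config.between_person_sd),
                6.0,
                window - 1.0,
            )
        )
        person_frag = float(
            max(0.8, rng.normal(config.baseline_fragmentation_mean, config.fragmentation_between_sd))
        )
        eff_sed = config.effect_sedentary_h
        eff_frag = config.effect_fragmentation
        if group == "NPS":
            if config.effect_sedentary_h_nps is not None:
                eff_sed = config.effect_sedentary_h_nps
            if config.effect_fragmentation_nps is not None:
                eff_frag = config.effect_fragmentation_nps

        schedule = measurement_offsets(
            b, config.intervention_weeks, config.measurement_blocks, config.followup_days
        )
        if config.dropout_id == pid:
            cutoff = b + config.dropout_after_weeks * 7
            schedule = [(off, ph) for off, ph in schedule if off < cutoff]

        days: list[tuple[int, str, dict]] = []
        for off, phase in schedule:
            if off < b:
                mult = 0.0
            elif config.effect_onset == "ramp":
                mult = min(1.0, (off - b + 1) / (config.ramp_weeks * 7.0))
            else:
                mult = 1.0
            sed = person_sed + mult * eff_sed + rng.normal(0.0, config.within_person_sd)
            sed = float(np.clip(sed, 0.5, window))
            frag = person_frag + mult * eff_frag + rng.normal(0.0, config.fragmentation_within_sd)
            frag = float(max(0.3, frag))
            mvpa = float(max(0.0, rng.normal(config.mvpa_mean_min, config.mvpa_sd_min)))
            mvpa = min(mvpa, (window - sed) * 60.0)
            days.append((off, phase, {"sedentary_h": sed, "fragmentation": frag, "mvpa_min": mvpa}))
        per_participant[pid] = days
    return spec, alloc, per_participant


# ---------------------------------------------------------------------------
# value layer
# ---------------------------------------------------------------------------


def _metrics_from_targets(t: dict, config: SyntheticConfig) -> DayMetrics:
    window = config.waking_window_h
    sed, frag, mvpa = t["sedentary_h"], t["fragmentation"], t["mvpa_min"]
    return DayMetrics(
        sedentary_hours=sed,
        fragmentation_index=frag,
        prolonged_bout_fraction=expected_prolonged_fraction(frag, config.bout_sigma),
        lpa_hours=max(0.0, window - sed - mvpa / 60.0),
        mvpa_minutes=mvpa,
        pct_waking_sedentary=100.0 * sed / window,
        sleep_hours=24.0 - window,
        wear_hours=window,
        valid=True,
    )


def generate_cohort_values(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[DesignSpec, dict[str, int], list[ParticipantSeries]]:
    """Generate a cohort at the day-value level (no event streams).

    This is the layer simulation studies run on: each measured day carries
    its drawn outcome values directly, with the event layer's bout model
    entering only through the analytic prolonged-bout fraction.  Fully
    reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    spec, alloc, targets = _draw_targets(config, rng)
    series_list = []
    for pid, group in spec.participants:
        days = [
            DayRecord(
                date=config.start_date + dt.timedelta(days=off),
                offset=off,
                phase=phase,
                metrics=_metrics_from_targets(t, config),
            )
            for off, phase, t in targets[pid]
        ]
        series_list.append(
            ParticipantSeries(id=pid, group=group, baseline_days=alloc[pid], days=days)
        )
    return spec, alloc, series_list


# ---------------------------------------------------------------------------
# event layer
# ---------------------------------------------------------------------------

_MIN_GAP_S = 1.0  # smallest upright gap that separates two sedentary bouts


def generate_day(
    target_sedentary_h: float,
    target_fragmentation: float,
    target_mvpa_min: float,
    window_start: dt.datetime,
    window_h: float,
    rng: np.random.Generator,
    *,
    mvpa_cadence: float = 115.0,
    lpa_cadence: float = 70.0,
    bout_sigma: float = 0.9,
    lpa_step_fraction: float = 0.25,
) -> WakingDay:
    """Realize one day's targets as a posture-event stream.

    Sedentary bout lengths are drawn lognormal (shape ``bout_sigma``) and
    rescaled so the day's sedentary total matches the target exactly; the
    bout count is round(fragmentation x sedentary hours), so the realized
    fragmentation index differs from the target only by that rounding.
    Upright time fills the gaps as standing plus stepping, with the MVPA
    allotment taken at ``mvpa_cadence`` and a share of the remainder as slow
    stepping.  Events tile the window exactly, in time order.

    Raises
    ------
    ValueError
        If the targets are infeasible inside the window (sedentary time
        exceeding the window, MVPA exceeding upright time, or more bouts
        than the upright time can separate).
    """
    W_s = window_h * 3600.0
    S_s = target_sedentary_h * 3600.0
    M_s = target_mvpa_min * 60.0
    if target_sedentary_h < 0 or target_fragmentation < 0 or target_mvpa_min < 0:
        raise ValueError("targets must be non-negative")
    if S_s > W_s + 1e-6:
        raise ValueError(
            f"target sedentary time {target_sedentary_h:.2f} h exceeds the "
            f"{window_h:.2f} h waking window"
        )
    bed = window_start + dt.timedelta(seconds=W_s)
    date = window_start.date()

    # a day sat through entirely is a single all-window bout
    if W_s - S_s < 60.0:
        ev = PostureEvent(window_start, W_s, ActivityClass.SEDENTARY)
        return WakingDay(date=date, rise=window_start, bed=bed, events=[ev])

    U_s = W_s - S_s
    if M_s > U_s + 1e-6:
        raise ValueError(
            f"target MVPA {target_mvpa_min:.1f} min exceeds upright time "
            f"{U_s / 60.0:.1f} min"
        )
    n_bouts = max(1, int(round(target_fragmentation * target_sedentary_h)))
    if (n_bouts - 1) * _MIN_GAP_S > U_s:
        raise ValueError(
            f"{n_bouts} sedentary bouts cannot be separated by "
            f"{U_s / 60.0:.1f} min of upright time"
        )

    # bout lengths: lognormal, rescaled to hit the sedentary total exactly
    raw = rng.lognormal(mean=0.0, sigma=bout_sigma, size=n_bouts)
    bout_s = raw * (S_s / raw.sum())

    # upright slots: n_bouts - 1 interior gaps (each >= _MIN_GAP_S) plus
    # optional leading/trailing upright; remainder split by exponential weights
    n_slots = n_bouts + 1
    base = np.zeros(n_slots)
    base[1:-1] = _MIN_GAP_S
    spare = U_s - base.sum()
    weights = rng.exponential(1.0, size=n_slots)
    slot_s = base + spare * weights / weights.sum()

    # place the MVPA allotment greedily into the largest slots
    mvpa_in_slot = np.zeros(n_slots)
    remaining = M_s
    for idx in np.argsort(slot_s)[::-1]:
        if remaining <= 1e-9:
            break
        take = min(remaining, slot_s[idx])
        mvpa_in_slot[idx] = take
        remaining -= take

    events: list[PostureEvent] = []
    t = window_start

    def add(dur_s: float, cls: ActivityClass, cadence: float = 0.0) -> None:
        nonlocal t
        if dur_s <= 1e-9:
            return
        events.append(PostureEvent(t, dur_s, cls, cadence))
        t += dt.timedelta(seconds=dur_s)

    def add_upright(slot: float, mvpa: float) -> None:
        rest = slot - mvpa
        slow = rest * lpa_step_fraction if rest > 2.0 else 0.0
        add(rest - slow, ActivityClass.STANDING)
        add(slow, ActivityClass.STEPPING, lpa_cadence)
        add(mvpa, ActivityClass.STEPPING, mvpa_cadence)

    for i in range(n_bouts):
        add_upright(slot_s[i], mvpa_in_slot[i])
        add(bout_s[i], ActivityClass.SEDENTARY)
    add_upright(slot_s[-1], mvpa_in_slot[-1])

    return WakingDay(date=date, rise=window_start, bed=bed, events=events)


def generate_cohort(
    config: SyntheticConfig, out_dir: str | Path, seed: int | None = None
) -> dict[str, Path]:
    """Generate a full cohort as files: one posture-event CSV per participant
    (``activpal_events`` dialect), a shared wake diary, and the design YAML
    with the realized baseline allocation.

    Returns a mapping of logical names to written paths (``events/<id>``,
    ``diary``, ``design``).  Reproducible from the seed.
    """
    out_dir = Path(out_dir)
    (out_dir / "events").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    spec, alloc, targets = _draw_targets(config, rng)

    diary_rows = []
    paths: dict[str, Path] = {}
    for pid, _group in spec.participants:
        all_events: list[PostureEvent] = []
        for off, _phase, t in targets[pid]:
            date = config.start_date + dt.timedelta(days=off)
            start = dt.datetime.combine(date, config.rise_time)
            day = generate_day(
                t["sedentary_h"],
                t["fragmentation"],
                t["mvpa_min"],
                start,
                config.waking_window_h,
                rng,
                mvpa_cadence=config.mvpa_cadence,
                lpa_cadence=config.lpa_cadence,
                bout_sigma=config.bout_sigma,
            )
            all_events.extend(day.events)
            bed = start + dt.timedelta(hours=config.waking_window_h)
            diary_rows.append(
                {
                    "participant_id": pid,
                    "date": date.isoformat(),
                    "rise_time": config.rise_time.strftime("%H:%M"),
                    "bed_time": bed.time().strftime("%H:%M"),
                }
            )
        p = out_dir / "events" / f"{pid}.csv"
        write_events(all_events, p, dialect="activpal_events")
        paths[f"events/{pid}"] = p

    diary_path = out_dir / "diary.csv"
    pd.DataFrame(diary_rows).to_csv(diary_path, index=False)
    paths["diary"] = diary_path

    design_path = out_dir / "design.yaml"
    spec.to_yaml(design_path, realized=alloc)
    paths["design"] = design_path
    return paths
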