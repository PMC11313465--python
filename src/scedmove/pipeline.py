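"""End-to-end orchestration: events -> metrics -> tests -> report bundle.

A run takes either a directory of posture-event files plus diary and design
(as produced by real monitors or by :mod:`scedmove.synth`) or a synthetic
configuration, and produces a report bundle: per-day metrics CSV,
randomization-test JSON per outcome and analysis set (all, PS, NPS), a
per-participant PEM table, cohort rollup counts, a replacement analysis
(what improvers replaced sedentary time with), band figures, and a manifest
recording the seed, package version, configuration hash and output hashes.

All randomness flows from the single seed in the configuration; subgroup
analyses reuse the same metric tables, so there is no recomputation drift.
No multiplicity adjustment is applied across outcomes (a note to that
effect is written into the report).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .bands import baseline_band, render_series
from .design import DesignSpec, ParticipantSeries, label_phases
from .events import read_diary, read_events, split_waking_days
from .metrics import DEFAULT_MIN_WEAR_HOURS, DEFAULT_MVPA_CADENCE, day_metrics
from .pem import (
    DEFAULT_IMPROVEMENT_THRESHOLD,
    PEMResult,
    improvement_rollup,
    pem,
    round_half_away,
)
from .randtest import group_test
from .synth import SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)

DEFAULT_OUTCOMES = ("sedentary_hours", "fragmentation_index")
ANALYSIS_SETS = ("all", "PS", "NPS")


@dataclass
class RunConfig:
    """Configuration for one end-to-end run."""

    output_dir: str
    input_dir: str | None = None  # events/ + diary.csv + design.yaml
    synthetic: SyntheticConfig | None = None
    outcomes: tuple[str, ...] = DEFAULT_OUTCOMES
    analysis_sets: tuple[str, ...] = ANALYSIS_SETS
    pem_threshold: float = DEFAULT_IMPROVEMENT_THRESHOLD
    mvpa_cadence: float = DEFAULT_MVPA_CADENCE
    min_wear_hours: float = DEFAULT_MIN_WEAR_HOURS
    n_mc: int = 20_000
    render_figures: bool = True
    diary_fallback: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.input_dir is None) == (self.synthetic is None):
            raise ValueError("exactly one of input_dir or synthetic must be set")


def load_series(
    input_dir: str | Path,
    mvpa_cadence: float = DEFAULT_MVPA_CADENCE,
    min_wear_hours: float = DEFAULT_MIN_WEAR_HOURS,
    diary_fallback: bool = False,
) -> tuple[DesignSpec, dict[str, int], list[ParticipantSeries]]:
    """Read an input bundle (events/<id>.csv, diary.csv, design.yaml) and
    build phase-labelled participant series."""
    input_dir = Path(input_dir)
    spec, realized = DesignSpec.from_yaml(input_dir / "design.yaml")
    if realized is None:
        raise ValueError("design.yaml lacks the realized baseline_days allocation")
    series_list = []
    for pid, group in spec.participants:
        events = read_events(input_dir / "events" / f"{pid}.csv", dialect="activpal_events")
        diary = read_diary(input_dir / "diary.csv", participant_id=pid)
        days = split_waking_days(events, diary, fallback=diary_fallback)
        metrics_days = [
            (d.date, day_metrics(d, mvpa_cadence=mvpa_cadence, min_wear_hours=min_wear_hours))
            for d in days
        ]
        b = realized[pid]
        series_list.append(
            label_phases(
                metrics_days,
                baseline_days=b,
                intervention_end_offset=b + spec.intervention_weeks * 7,
                participant_id=pid,
                group=group,
            )
        )
    return spec, realized, series_list


def metrics_table(series_list: list[ParticipantSeries]) -> pd.DataFrame:
    """Tidy per-day metrics table for the whole cohort."""
    rows = []
    for s in series_list:
        for d in s.days:
            m = d.metrics
            rows.append(
                {
                    "participant_id": s.id,
                    "group": s.group,
                    "date": d.date.isoformat(),
                    "offset": d.offset,
                    "phase": d.phase,
                    "sedentary_hours": m.sedentary_hours,
                    "fragmentation_index": m.fragmentation_index,
                    "prolonged_bout_fraction": m.prolonged_bout_fraction,
                    "lpa_hours": m.lpa_hours,
                    "mvpa_minutes": m.mvpa_minutes,
                    "pct_waking_sedentary": m.pct_waking_sedentary,
                    "sleep_hours": m.sleep_hours,
                    "wear_hours": m.wear_hours,
                    "valid": m.valid,
                }
            )
    return pd.DataFrame(rows)


def pem_table(results: list[PEMResult]) -> pd.DataFrame:
    """Report-style PEM table, one row per participant x outcome, values
    rounded to one decimal (half away from zero)."""
    rows = []
    for r in results:
        rows.append(
            {
                "participant_id": r.participant_id,
                "group": r.group,
                "outcome": r.outcome_name,
                "pem_pct": round_half_away(r.pem, 1),
                "category": r.category,
                "mean_a": round_half_away(r.mean_a, 1),
                "sd_a": round_half_away(r.sd_a, 1),
                "mean_ba": round_half_away(r.mean_ba, 1),
                "sd_ba": round_half_away(r.sd_ba, 1),
                "difference": round_half_away(r.difference, 1),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ReplacementResult:
    """What sedentary-time improvers replaced their sitting with."""

    n_improvers: int
    pct_both: float
    pct_lpa_only: float
    pct_mvpa_only: float
    pct_neither: float


def replacement_analysis(
    sed_results: list[PEMResult],
    lpa_results: list[PEMResult],
    mvpa_results: list[PEMResult],
    threshold: float = DEFAULT_IMPROVEMENT_THRESHOLD,
) -> ReplacementResult:
    """Among participants whose sedentary-time PEM exceeds the threshold,
    the shares (in % of improvers) who also improved on both LPA and MVPA,
    on LPA only, on MVPA only, or on neither."""
    lpa_by = {r.participant_id: r for r in lpa_results}
    mvpa_by = {r.participant_id: r for r in mvpa_results}
    improvers = [r.participant_id for r in sed_results if r.pem > threshold]
    if not improvers:
        logger.warning("no sedentary-time improvers; replacement analysis is empty")
        return ReplacementResult(0, float("nan"), float("nan"), float("nan"), float("nan"))
    n_both = n_lpa = n_mvpa = 0
    for pid in improvers:
        lpa_up = lpa_by[pid].pem > threshold
        mvpa_up = mvpa_by[pid].pem > threshold
        if lpa_up and mvpa_up:
            n_both += 1
        elif lpa_up:
            n_lpa += 1
        elif mvpa_up:
            n_mvpa += 1
    n = len(improvers)
    return ReplacementResult(
        n_improvers=n,
        pct_both=100.0 * n_both / n,
        pct_lpa_only=100.0 * n_lpa / n,
        pct_mvpa_only=100.0 * n_mvpa / n,
        pct_neither=100.0 * (n - n_both - n_lpa - n_mvpa) / n,
    )


def _subset(series_list: list[ParticipantSeries], analysis_set: str) -> list[ParticipantSeries]:
    if analysis_set == "all":
        return series_list
    return [s for s in series_list if s.group == analysis_set]


def _config_hash(config: RunConfig) -> str:
    doc = dataclasses.asdict(config)
    return hashlib.sha256(json.dumps(doc, sort_keys=True, default=str).encode()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute a full analysis run; returns the manifest dictionary.

    Stages: materialize/load inputs, per-day metrics, randomization tests
    per outcome and analysis set, PEM table and rollup, replacement
    analysis, band figures.  A stage failure aborts with the stage named,
    retaining outputs written so far.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        if config.synthetic is not None:
            data_dir = out / "data"
            generate_cohort(config.synthetic, data_dir, seed=config.seed)
        else:
            data_dir = Path(config.input_dir)
        spec, realized, series_list = load_series(
            data_dir,
            mvpa_cadence=config.mvpa_cadence,
            min_wear_hours=config.min_wear_hours,
            diary_fallback=config.diary_fallback,
        )

        stage = "metrics"
        mtab = metrics_table(series_list)
        mtab.to_csv(out / "day_metrics.csv", index=False)

        stage = "randomization_test"
        test_records = []
        for analysis_set in config.analysis_sets:
            subset = _subset(series_list, analysis_set)
            for outcome in config.outcomes:
                res = group_test(
                    subset, outcome, mode="auto", n_mc=config.n_mc, seed=config.seed
                )
                test_records.append(
                    {
                        "analysis_set": analysis_set,
                        "outcome": res.outcome_name,
                        "statistic": res.statistic_observed,
                        "p_two_tailed": res.p_two_tailed,
                        "n_assignments": res.n_assignments,
                        "n_as_extreme": res.n_as_extreme,
                        "mode": res.mode,
                        "n_mc": res.n_mc,
                        "seed": res.seed,
                    }
                )
        (out / "randomization_tests.json").write_text(
            json.dumps(
                {
                    "note": "No multiplicity adjustment is applied across outcomes.",
                    "results": test_records,
                },
                indent=2,
            )
        )

        stage = "pem"
        pem_results: dict[str, list[PEMResult]] = {}
        for outcome in set(config.outcomes) | {"lpa_hours", "mvpa_minutes"}:
            pem_results[outcome] = [pem(s, outcome) for s in series_list]
        primary = [r for o in config.outcomes for r in pem_results[o]]
        pem_table(primary).to_csv(out / "pem_table.csv", index=False)
        rollup = improvement_rollup(primary, threshold=config.pem_threshold)
        repl = replacement_analysis(
            pem_results.get("sedentary_hours", []),
            pem_results["lpa_hours"],
            pem_results["mvpa_minutes"],
            threshold=config.pem_threshold,
        )
        (out / "rollup.json").write_text(
            json.dumps(
                {
                    "threshold": rollup.threshold,
                    "n_participants": rollup.n_participants,
                    "at_least_one": rollup.at_least_one,
                    "both": rollup.both,
                    "per_group": {g: list(v) for g, v in rollup.per_group.items()},
                    "per_outcome": {
                        o: {
                            "n_improvers": s.n_improvers,
                            "mean_difference": s.mean_difference,
                            "sd_difference": s.sd_difference,
                            "min_difference": s.min_difference,
                            "max_difference": s.max_difference,
                        }
                        for o, s in rollup.per_outcome.items()
                    },
                    "replacement": dataclasses.asdict(repl),
                },
                indent=2,
            )
        )

        stage = "figures"
        fig_paths: list[Path] = []
        if config.render_figures:
            for s in series_list:
                for outcome in config.outcomes:
                    band = baseline_band(s, outcome)
                    fig_paths.extend(render_series(s, outcome, band, out / "figures"))

        stage = "manifest"
        hashed = {}
        for p in sorted(out.rglob("*")):
            if (
                p.is_file()
                and p.suffix in (".csv", ".json", ".svg", ".yaml")
                and p.name != "manifest.json"
            ):
                hashed[str(p.relative_to(out))] = hashlib.sha256(p.read_bytes()).hexdigest()
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "config_hash": _config_hash(config),
            "outputs": hashed,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
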