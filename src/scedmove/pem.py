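"""Percentage-exceeding-the-median (PEM) effect sizes and phase summaries.

PEM is a non-parametric single-case effect size suited to noisy baselines:
the share of intervention-and-after days (phases B and A') whose outcome is
strictly better than the baseline (phase A) median.  A day exactly equal to
the median does not count as an improvement — "exceeding" is strict, which
matters with discrete or repeated values.

Categories: PEM > 90 high; 70-90 moderate; 60-70 mild; 50-60 questionable;
< 50 no effect.  Interval-boundary values are assigned to the higher-named
bin (90 -> moderate, 70 -> moderate, 60 -> mild, 50 -> questionable); the
bin edges are exposed so this convention can be changed.

Phase summaries use the sample SD (n-1) and an improvement-signed
difference: for a lower-is-better outcome (sedentary hours) the difference
is mean(A) - mean(B+A'), so positive means improvement; for higher-is-better
(fragmentation index, LPA, MVPA) it is mean(B+A') - mean(A).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .design import ParticipantSeries

#: "high" requires strictly more than this PEM percentage.
HIGH_EDGE = 90.0
#: (lower edge, category) pairs scanned top-down; a value on an edge goes to
#: the higher-named bin (70 -> moderate, 60 -> mild, 50 -> questionable).
CATEGORY_EDGES = (
    (70.0, "moderate"),
    (60.0, "mild"),
    (50.0, "questionable"),
)

#: Improvement direction per built-in outcome.
OUTCOME_DIRECTIONS = {
    "sedentary_hours": "lower_is_better",
    "pct_waking_sedentary": "lower_is_better",
    "prolonged_bout_fraction": "lower_is_better",
    "fragmentation_index": "higher_is_better",
    "lpa_hours": "higher_is_better",
    "mvpa_minutes": "higher_is_better",
}

DEFAULT_IMPROVEMENT_THRESHOLD = 60.0
POST_PHASES = ("B", "A'")


@dataclass
class PEMResult:
    """Per-participant, per-outcome PEM with Table-style phase statistics."""

    participant_id: str
    group: str
    outcome_name: str
    direction: str
    baseline_median: float
    pem: float
    category: str
    mean_a: float
    sd_a: float
    mean_ba: float
    sd_ba: float
    difference: float  # improvement-signed

    @classmethod
    def from_summary(
        cls,
        participant_id: str,
        group: str,
        outcome_name: str,
        direction: str,
        pem: float,
        mean_a: float,
        sd_a: float,
        mean_ba: float,
        sd_ba: float,
        difference: float | None = None,
    ) -> "PEMResult":
        """Build a result from published summary statistics (no raw days)."""
        if difference is None:
            difference = (
                mean_a - mean_ba if direction == "lower_is_better" else mean_ba - mean_a
            )
        return cls(
            participant_id=participant_id,
            group=group,
            outcome_name=outcome_name,
            direction=direction,
            baseline_median=math.nan,
            pem=pem,
            category=classify_pem(pem),
            mean_a=mean_a,
            sd_a=sd_a,
            mean_ba=mean_ba,
            sd_ba=sd_ba,
            difference=difference,
        )


def classify_pem(pem: float) -> str:
    """Map a PEM percentage to its effect category."""
    if not 0.0 <= pem <= 100.0:
        raise ValueError(f"PEM must be in [0, 100], got {pem}")
    if pem > HIGH_EDGE:
        return "high"
    for edge, name in CATEGORY_EDGES:
        if pem >= edge:
            return name
    return "none"


def pem(
    series: ParticipantSeries,
    outcome: str,
    direction: str | None = None,
    post_phases: Sequence[str] = POST_PHASES,
) -> PEMResult:
    """Compute the PEM effect size for one participant and outcome.

    Improvement is strictly beyond the baseline median in the outcome's
    improvement direction; the median over an even count of days uses the
    midpoint convention (``numpy.median``).
    """
    if direction is None:
        try:
            direction = OUTCOME_DIRECTIONS[outcome]
        except KeyError:
            raise ValueError(
                f"no default improvement direction for outcome {outcome!r}; pass one"
            ) from None
    if direction not in ("lower_is_better", "higher_is_better"):
        raise ValueError(f"unknown direction {direction!r}")

    a_vals = series.values(outcome, phases=("A",))
    post_vals = series.values(outcome, phases=tuple(post_phases))
    if a_vals.size == 0:
        raise ValueError(f"participant {series.id}: no valid baseline (A) days")
    if post_vals.size == 0:
        raise ValueError(f"participant {series.id}: no valid post ({'+'.join(post_phases)}) days")

    med = float(np.median(a_vals))
    if direction == "lower_is_better":
        n_improved = int((post_vals < med).sum())
    else:
        n_improved = int((post_vals > med).sum())
    pem_pct = 100.0 * n_improved / post_vals.size

    mean_a = float(a_vals.mean())
    sd_a = float(a_vals.std(ddof=1)) if a_vals.size > 1 else 0.0
    mean_ba = float(post_vals.mean())
    sd_ba = float(post_vals.std(ddof=1)) if post_vals.size > 1 else 0.0
    diff = mean_a - mean_ba if direction == "lower_is_better" else mean_ba - mean_a

    return PEMResult(
        participant_id=series.id,
        group=series.group,
        outcome_name=outcome,
        direction=direction,
        baseline_median=med,
        pem=pem_pct,
        category=classify_pem(pem_pct),
        mean_a=mean_a,
        sd_a=sd_a,
        mean_ba=mean_ba,
        sd_ba=sd_ba,
        difference=diff,
    )


@dataclass
class OutcomeImproverStats:
    """Summary of improvement-signed differences among a PEM-defined
    improver set for one outcome."""

    outcome_name: str
    n_improvers: int
    differences: list[float]
    mean_difference: float
    sd_difference: float
    min_difference: float
    max_difference: float


@dataclass
class RollupResult:
    """Cohort-level counts of PEM-defined improvement across two outcomes."""

    threshold: float
    n_participants: int
    at_least_one: int
    both: int
    per_group: dict[str, tuple[int, int]]  # group -> (at_least_one, both)
    per_outcome: dict[str, OutcomeImproverStats]


def improvement_rollup(
    results: Sequence[PEMResult],
    threshold: float = DEFAULT_IMPROVEMENT_THRESHOLD,
) -> RollupResult:
    """Cohort rollup: who improved (PEM strictly above ``threshold``) on at
    least one / both outcomes, overall and per group, plus the mean, SD and
    range of improvement-signed differences among each outcome's improvers.

    Every participant must have a result for every outcome present.
    """
    outcomes = sorted({r.outcome_name for r in results})
    by_pid: dict[str, dict[str, PEMResult]] = {}
    group_of: dict[str, str] = {}
    for r in results:
        by_pid.setdefault(r.participant_id, {})[r.outcome_name] = r
        group_of[r.participant_id] = r.group
    for pid, d in by_pid.items():
        missing = set(outcomes) - set(d)
        if missing:
            raise ValueError(f"participant {pid} is missing outcomes {sorted(missing)}")

    at_least_one = both = 0
    per_group: dict[str, list[int]] = {}
    for pid, d in by_pid.items():
        improved = [d[o].pem > threshold for o in outcomes]
        g = per_group.setdefault(group_of[pid], [0, 0])
        if any(improved):
            at_least_one += 1
            g[0] += 1
        if len(outcomes) > 1 and all(improved):
            both += 1
            g[1] += 1

    per_outcome: dict[str, OutcomeImproverStats] = {}
    for o in outcomes:
        diffs = [d[o].difference for d in by_pid.values() if d[o].pem > threshold]
        arr = np.asarray(diffs, dtype=float)
        per_outcome[o] = OutcomeImproverStats(
            outcome_name=o,
            n_improvers=len(diffs),
            differences=diffs,
            mean_difference=float(arr.mean()) if diffs else math.nan,
            sd_difference=float(arr.std(ddof=1)) if len(diffs) > 1 else math.nan,
            min_difference=float(arr.min()) if diffs else math.nan,
            max_difference=float(arr.max()) if diffs else math.nan,
        )

    return RollupResult(
        threshold=threshold,
        n_participants=len(by_pid),
        at_least_one=at_least_one,
        both=both,
        per_group={g: (v[0], v[1]) for g, v in per_group.items()},
        per_outcome=per_outcome,
    )


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention used in report tables."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor
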