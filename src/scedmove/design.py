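"""Randomized multiple-baseline design: allocation, phase labels, permutation space.

In a multiple-baseline single-case design, every participant is measured
repeatedly through a baseline phase (A), an intervention phase (B) and a
post-intervention phase (A'); the *length of the baseline* is randomized
per participant among a small set of candidate durations.  Staggering the
intervention start this way is what lets a randomization test separate an
intervention effect from secular time trends.

The default design randomizes each participant independently and uniformly
over candidate baseline durations of 4, 6, 8, 10, 12 or 14 days, runs the
intervention for 15 weeks, and measures daily outcomes in the baseline
block plus 7-day blocks at intervention weeks 1, 8 and 15 and a follow-up
week.  The permutation space of the associated randomization test is, in
the classical construction, the set of distinct rearrangements of the
*realized* multiset of baseline durations across participants
(``mode="within_set"``); the full product space over all candidates is
available as ``mode="product"``.
"""

from __future__ import annotations

import datetime as dt
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import yaml
from sympy.utilities.iterables import multiset_permutations

from .metrics import DayMetrics

DEFAULT_CANDIDATE_DURATIONS = (4, 6, 8, 10, 12, 14)
DEFAULT_MEASUREMENT_BLOCKS = ((1, 7), (8, 7), (15, 7))
GROUPS = ("PS", "NPS")  # with / without participatory support


@dataclass
class DesignSpec:
    """Static description of a randomized multiple-baseline study."""

    participants: list[tuple[str, str]]  # (id, group)
    candidate_durations: tuple[int, ...] = DEFAULT_CANDIDATE_DURATIONS
    intervention_weeks: int = 15
    followup_days: int = 7
    #: (intervention week, block length in days) measurement blocks in phase B
    measurement_blocks: tuple[tuple[int, int], ...] = DEFAULT_MEASUREMENT_BLOCKS
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.candidate_durations or any(d < 1 for d in self.candidate_durations):
            raise ValueError("candidate_durations must be non-empty, all >= 1")
        groups = {g for _, g in self.participants}
        unknown = groups - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels {sorted(unknown)}; expected {GROUPS}")

    @property
    def ids(self) -> list[str]:
        return [pid for pid, _ in self.participants]

    def group_of(self, pid: str) -> str:
        return dict(self.participants)[pid]

    def to_yaml(self, path, realized: dict[str, int] | None = None) -> None:
        doc = {
            "participants": [{"id": pid, "group": g} for pid, g in self.participants],
            "candidate_durations": list(self.candidate_durations),
            "intervention_weeks": self.intervention_weeks,
            "followup_days": self.followup_days,
            "measurement_blocks": [list(b) for b in self.measurement_blocks],
            "seed": self.seed,
        }
        if realized is not None:
            doc["baseline_days"] = dict(realized)
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> tuple["DesignSpec", dict[str, int] | None]:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        spec = cls(
            participants=[(p["id"], p["group"]) for p in doc["participants"]],
            candidate_durations=tuple(doc["candidate_durations"]),
            intervention_weeks=doc.get("intervention_weeks", 15),
            followup_days=doc.get("followup_days", 7),
            measurement_blocks=tuple(
                tuple(b) for b in doc.get("measurement_blocks", DEFAULT_MEASUREMENT_BLOCKS)
            ),
            seed=doc.get("seed", 0),
        )
        realized = doc.get("baseline_days")
        return spec, ({str(k): int(v) for k, v in realized.items()} if realized else None)


@dataclass
class DayRecord:
    """One measured participant-day with its calendar offset and phase label."""

    date: dt.date
    offset: int  # days since the participant's first measured day
    phase: str  # "A", "B" or "A'"
    metrics: DayMetrics


@dataclass
class ParticipantSeries:
    """Ordered measured days of one participant, with design metadata."""

    id: str
    group: str
    baseline_days: int
    days: list[DayRecord] = field(default_factory=list)

    def valid_days(self) -> list[DayRecord]:
        return [d for d in self.days if d.metrics.valid]

    def values(self, outcome: str, phases: Sequence[str] | None = None) -> np.ndarray:
        """Valid-day values of one outcome, optionally restricted to phases."""
        recs = self.valid_days()
        if phases is not None:
            recs = [d for d in recs if d.phase in phases]
        return np.array([getattr(d.metrics, outcome) for d in recs], dtype=float)


# ---------------------------------------------------------------------------
# allocation
# ---------------------------------------------------------------------------


def allocate_baselines(
    spec: DesignSpec,
    mode: str = "independent",
    rng: np.random.Generator | None = None,
) -> dict[str, int]:
    """Randomly assign a baseline duration to every participant.

    ``"independent"`` draws each participant's duration uniformly and
    independently from the candidates (matches how the study randomized).
    ``"balanced"`` deals the candidate set out like a deck — the candidates
    are tiled to cover the cohort and shuffled — so with six participants
    and six candidates every duration occurs exactly once, the setting the
    classical randomization-test construction assumes.
    """
    if mode not in ("independent", "balanced"):
        raise ValueError(f"unknown allocation mode {mode!r}")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    cands = np.asarray(spec.candidate_durations)
    n = len(spec.participants)
    if mode == "independent":
        drawn = rng.choice(cands, size=n, replace=True)
    else:
        reps = math.ceil(n / len(cands))
        deck = np.tile(cands, reps)[:n]
        drawn = rng.permutation(deck)
    return {pid: int(d) for (pid, _), d in zip(spec.participants, drawn)}


# ---------------------------------------------------------------------------
# measurement schedule and phase labelling
# ---------------------------------------------------------------------------


def measurement_offsets(
    baseline_days: int,
    intervention_weeks: int = 15,
    measurement_blocks: tuple[tuple[int, int], ...] = DEFAULT_MEASUREMENT_BLOCKS,
    followup_days: int = 7,
) -> list[tuple[int, str]]:
    """Calendar-day offsets (from the participant's first measured day) on
    which outcomes are measured, with their phase labels.

    Phase A covers offsets ``0 .. baseline_days-1``; phase-B measurement
    happens in 7-day blocks starting at the given intervention weeks; phase
    A' is a follow-up block right after the intervention ends.
    """
    out = [(off, "A") for off in range(baseline_days)]
    for week, length in measurement_blocks:
        start = baseline_days + (week - 1) * 7
        out.extend((start + i, "B") for i in range(length))
    b_end = baseline_days + intervention_weeks * 7
    out.extend((b_end + i, "A'") for i in range(followup_days))
    return out


def phase_of_offset(offset: int, baseline_days: int, intervention_end_offset: int) -> str:
    if offset < baseline_days:
        return "A"
    if offset < intervention_end_offset:
        return "B"
    return "A'"


def label_phases(
    metrics_days: list[tuple[dt.date, DayMetrics]],
    baseline_days: int,
    intervention_end_offset: int,
    participant_id: str = "",
    group: str = "PS",
) -> ParticipantSeries:
    """Assemble a :class:`ParticipantSeries` by phase-labelling measured days.

    Offsets are calendar days since the first measured date, so gaps in the
    measurement schedule keep their calendar position.  Invalid days keep
    their place in the series but are excluded from analysis sets by the
    consumers (``valid_days``).
    """
    if not metrics_days:
        raise ValueError("no measured days")
    metrics_days = sorted(metrics_days, key=lambda t: t[0])
    first = metrics_days[0][0]
    offsets = [(d - first).days for d, _ in metrics_days]
    if baseline_days >= offsets[-1] + 1:
        raise ValueError(
            f"baseline of {baseline_days} days covers all {offsets[-1] + 1} measured days; "
            "no intervention data remain"
        )
    days = [
        DayRecord(date, off, phase_of_offset(off, baseline_days, intervention_end_offset), m)
        for (date, m), off in zip(metrics_days, offsets)
    ]
    return ParticipantSeries(id=participant_id, group=group, baseline_days=baseline_days, days=days)


# ---------------------------------------------------------------------------
# permutation space
# ---------------------------------------------------------------------------


def count_assignments(realized: Sequence[int], mode: str, n_candidates: int | None = None) -> int:
    """Number of distinct assignments without materializing them."""
    n = len(realized)
    if mode == "within_set":
        counts = Counter(realized)
        total = math.factorial(n)
        for c in counts.values():
            total //= math.factorial(c)
        return total
    if mode == "product":
        if n_candidates is None:
            raise ValueError("product mode needs the candidate count")
        return n_candidates**n
    raise ValueError(f"unknown permutation mode {mode!r}")


def iter_assignments(
    realized: Sequence[int],
    mode: str,
    candidates: Sequence[int] | None = None,
) -> Iterator[tuple[int, ...]]:
    """Iterate over the permutation space, each distinct assignment once.

    ``within_set`` yields every distinct rearrangement of the realized
    multiset of durations (the classical staggered-start construction);
    ``product`` yields the full Cartesian product over candidates.
    """
    if mode == "within_set":
        for perm in multiset_permutations(sorted(realized)):
            yield tuple(perm)
    elif mode == "product":
        if candidates is None:
            raise ValueError("product mode needs the candidate set")
        import itertools

        yield from itertools.product(candidates, repeat=len(realized))
    else:
        raise ValueError(f"unknown permutation mode {mode!r}")


def permutation_space(
    spec: DesignSpec,
    realized: dict[str, int],
    mode: str = "within_set",
) -> tuple[int, Iterable[tuple[int, ...]]]:
    """Size of, and iterator over, the randomization-test assignment space.

    Assignments are tuples of baseline durations in the order of
    ``spec.participants``.  The count is computed in closed form; the
    iterator is lazy, so large spaces are never materialized.
    """
    durations = [realized[pid] for pid in spec.ids]
    n = count_assignments(durations, mode, n_candidates=len(spec.candidate_durations))
    it = iter_assignments(durations, mode, candidates=spec.candidate_durations)
    return n, it
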