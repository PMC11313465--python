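"""Randomization test for intervention effect in a multiple-baseline design.

The test statistic is the unweighted mean, across participants, of each
participant's (post minus pre) difference in daily-outcome means when the
series is split at a hypothetical intervention start.  Under the null
hypothesis of no intervention effect, the realized assignment of baseline
durations is exchangeable with every other assignment in the design's
permutation space, so the two-tailed p-value is the share of assignments
whose statistic is at least as extreme (in absolute value) as the observed
one — with the observed assignment always counted, which makes the test
exact (p is never 0 and the type-I error is at most alpha).

Exact enumeration is used while the space is small (<= ``max_exact``
assignments); beyond that, assignments are sampled (Monte Carlo) with the
observed assignment included once.  Dropouts simply contribute whatever
valid days they have on both sides of each split (intention to treat).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .design import DesignSpec, ParticipantSeries, count_assignments, iter_assignments

logger = logging.getLogger(__name__)

DEFAULT_MAX_EXACT = 1_000_000
DEFAULT_N_MC = 20_000
#: Relative slack for |T| comparisons, guarding against float noise in ties.
_TIE_EPS = 1e-12


@dataclass
class RandomizationTestResult:
    """Result of a group-level randomization test on one outcome."""

    outcome_name: str
    statistic_observed: float
    n_assignments: int
    n_as_extreme: int
    p_two_tailed: float
    mode: str  # "exact" | "monte_carlo"
    n_mc: int | None = None
    seed: int | None = None


def participant_effect(
    series: ParticipantSeries,
    outcome: str,
    hypothetical_baseline_days: int,
) -> float:
    """Post-minus-pre mean difference for one hypothetical intervention start.

    Valid days with calendar offset below ``hypothetical_baseline_days``
    form the pre period; the rest form the post period.  Raises if either
    side is empty (such an assignment is not admissible for this series).
    """
    recs = series.valid_days()
    pre = [getattr(d.metrics, outcome) for d in recs if d.offset < hypothetical_baseline_days]
    post = [getattr(d.metrics, outcome) for d in recs if d.offset >= hypothetical_baseline_days]
    if not pre or not post:
        side = "pre" if not pre else "post"
        raise ValueError(
            f"participant {series.id}: no valid {side}-period days for a "
            f"hypothetical start at day {hypothetical_baseline_days}"
        )
    return float(np.mean(post) - np.mean(pre))


def _effect_matrix(
    series_list: list[ParticipantSeries],
    outcome: str,
    durations: list[int],
) -> np.ndarray:
    """effects[i, j] = participant i's effect under candidate duration j.

    A combination that leaves a participant with an empty pre or post period
    (possible for dropouts with few measured days) is marked NaN; assignments
    containing one are excluded from the permutation space with a warning.
    """
    eff = np.empty((len(series_list), len(durations)))
    for i, s in enumerate(series_list):
        recs = s.valid_days()
        offs = np.array([d.offset for d in recs])
        vals = np.array([getattr(d.metrics, outcome) for d in recs], dtype=float)
        order = np.argsort(offs, kind="stable")
        offs, vals = offs[order], vals[order]
        csum = np.concatenate([[0.0], np.cumsum(vals)])
        for j, h in enumerate(durations):
            k = int(np.searchsorted(offs, h))
            if k == 0 or k == len(vals):
                logger.warning(
                    "participant %s: hypothetical start at day %d leaves an empty "
                    "side; assignments using it are excluded from the space", s.id, h,
                )
                eff[i, j] = np.nan
            else:
                pre_mean = csum[k] / k
                post_mean = (csum[-1] - csum[k]) / (len(vals) - k)
                eff[i, j] = post_mean - pre_mean
    return eff


def group_test(
    series_list: list[ParticipantSeries],
    outcome: str,
    mode: str = "auto",
    n_mc: int = DEFAULT_N_MC,
    seed: int | None = None,
    max_exact: int = DEFAULT_MAX_EXACT,
    space: str = "within_set",
) -> RandomizationTestResult:
    """Two-tailed randomization test of an intervention effect at group level.

    ``mode="auto"`` enumerates the permutation space exactly when it has at
    most ``max_exact`` assignments and otherwise samples ``n_mc`` random
    assignments (the observed one counted once).  The statistic is the mean
    of per-participant post-minus-pre differences.
    """
    if len(series_list) < 2:
        raise ValueError("group test needs at least 2 participants")
    realized = [s.baseline_days for s in series_list]
    uniq = sorted(set(realized))
    col_of = {d: j for j, d in enumerate(uniq)}
    eff = _effect_matrix(series_list, outcome, uniq)
    rows = np.arange(len(series_list))

    t_obs = float(eff[rows, [col_of[d] for d in realized]].mean())
    if np.isnan(t_obs):
        raise ValueError(
            "the realized assignment itself leaves a participant with an empty "
            "pre or post period; the series cannot be tested"
        )
    n_total = count_assignments(realized, space)

    if n_total == 1:
        logger.warning("degenerate permutation space (1 assignment); p = 1")
        return RandomizationTestResult(outcome, t_obs, 1, 1, 1.0, "exact")

    threshold = abs(t_obs) * (1.0 - _TIE_EPS) - _TIE_EPS
    if mode == "exact" or (mode == "auto" and n_total <= max_exact):
        n_extreme = 0
        n_valid = 0

        def tally(cols: list[list[int]]) -> None:
            nonlocal n_extreme, n_valid
            stats = eff[rows, np.asarray(cols)].mean(axis=1)
            ok = ~np.isnan(stats)
            n_valid += int(ok.sum())
            n_extreme += int((np.abs(stats[ok]) >= threshold).sum())

        chunk: list[list[int]] = []
        for assign in iter_assignments(realized, space):
            chunk.append([col_of[d] for d in assign])
            if len(chunk) == 100_000:
                tally(chunk)
                chunk = []
        if chunk:
            tally(chunk)
        p = n_extreme / n_valid
        return RandomizationTestResult(outcome, t_obs, n_valid, n_extreme, p, "exact")

    if mode not in ("auto", "monte_carlo"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    realized_cols = np.asarray([col_of[d] for d in realized])
    n_extreme = 1  # the observed assignment
    n_valid = 0
    done = 0
    while done < n_mc:
        m = min(50_000, n_mc - done)
        keys = rng.random((m, len(realized)))
        perms = realized_cols[np.argsort(keys, axis=1)]
        stats = eff[rows, perms].mean(axis=1)
        ok = ~np.isnan(stats)
        n_valid += int(ok.sum())
        n_extreme += int((np.abs(stats[ok]) >= threshold).sum())
        done += m
    p = n_extreme / (n_valid + 1)
    return RandomizationTestResult(
        outcome, t_obs, n_valid + 1, n_extreme, p, "monte_carlo", n_mc=n_mc, seed=seed
    )


def min_attainable_p(
    spec: DesignSpec,
    realized: dict[str, int],
    mode: str = "within_set",
) -> float:
    """Smallest two-tailed p the design can produce (observed uniquely most
    extreme): one over the number of distinct assignments."""
    durations = [realized[pid] for pid in spec.ids]
    return 1.0 / count_assignments(durations, mode, n_candidates=len(spec.candidate_durations))
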