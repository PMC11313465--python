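"""Published per-participant summary of the motivating case series.

The pipeline was built to analyze a randomized multiple-baseline study of
14 highly sedentary community-dwelling stroke survivors, half of whom
received participatory support (PS) from a member of their social network
and half of whom did not (NPS).  The study's raw accelerometry is not
publicly available, but its per-participant report table is: PEM and phase
mean (SD) for daily sedentary time (hours, lower is better) and the
sedentary fragmentation index (bouts per sedentary hour, higher is better),
with improvement-signed differences, printed to one decimal.

These summary rows serve as a reference input for cohort-level rollups and
as calibration targets for the synthetic-data generator; they are summary
statistics only — no participant-day data are included or reconstructable.
"""

from __future__ import annotations

import pandas as pd

from .pem import PEMResult

# group, participant, PEM_sed, meanA_sed, sdA_sed, meanBA_sed, sdBA_sed, diff_sed,
#                      PEM_frag, meanA_frag, sdA_frag, meanBA_frag, sdBA_frag, diff_frag
_ROWS = [
    ("PS", "PS-1", 68.6, 10.3, 1.6, 10.1, 1.3, 0.2, 64.7, 3.9, 1.1, 4.9, 1.9, 1.0),
    ("PS", "PS-2", 56.8, 11.8, 0.6, 11.7, 1.0, 0.1, 76.3, 2.8, 0.4, 3.4, 0.7, 0.6),
    ("PS", "PS-3", 60.8, 10.1, 0.9, 10.0, 1.0, 0.1, 58.8, 7.2, 1.6, 7.5, 1.8, 0.3),
    ("PS", "PS-4", 100.0, 12.7, 1.1, 7.5, 2.0, 5.2, 87.0, 4.8, 1.1, 6.8, 2.1, 2.0),
    ("PS", "PS-5", 73.1, 11.4, 0.9, 10.0, 2.0, 1.4, 69.7, 2.6, 0.7, 3.5, 1.9, 0.9),
    ("PS", "PS-6", 70.8, 11.2, 1.9, 9.8, 2.1, 1.4, 89.6, 2.8, 1.3, 4.7, 1.8, 1.9),
    ("PS", "PS-7", 87.0, 12.4, 0.7, 11.1, 1.3, 1.3, 87.0, 3.5, 1.1, 4.2, 0.8, 0.7),
    ("NPS", "NPS-1", 87.0, 13.7, 0.9, 12.0, 1.2, 1.7, 46.0, 4.1, 0.7, 4.1, 1.1, 0.0),
    ("NPS", "NPS-2", 83.2, 12.0, 2.3, 10.6, 1.6, 1.4, 71.4, 2.3, 0.5, 3.3, 1.1, 1.0),
    ("NPS", "NPS-3", 46.5, 11.0, 1.2, 11.0, 1.7, 0.0, 52.5, 4.3, 1.0, 4.4, 1.5, 0.1),
    ("NPS", "NPS-4", 64.8, 11.0, 1.1, 10.9, 1.0, 0.1, 23.8, 4.0, 1.0, 3.3, 0.7, -0.7),
    ("NPS", "NPS-5", 67.6, 10.0, 1.7, 9.2, 2.2, 0.8, 54.3, 5.6, 0.9, 5.9, 2.2, 0.3),
    ("NPS", "NPS-6", 22.2, 10.9, 1.4, 11.0, 0.9, -0.1, 58.3, 6.0, 1.8, 5.7, 1.2, -0.3),
    ("NPS", "NPS-7", 69.9, 10.4, 1.7, 9.2, 2.2, 1.2, 83.5, 3.4, 0.3, 4.1, 0.8, 0.7),
]

_COLUMNS = [
    "group", "participant",
    "pem_sed", "mean_a_sed", "sd_a_sed", "mean_ba_sed", "sd_ba_sed", "diff_sed",
    "pem_frag", "mean_a_frag", "sd_a_frag", "mean_ba_frag", "sd_ba_frag", "diff_frag",
]


def reference_cohort() -> pd.DataFrame:
    """The published 14-participant summary table as a tidy DataFrame."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS)


def reference_pem_results() -> list[PEMResult]:
    """The published summary rows as :class:`PEMResult` objects, two per
    participant (sedentary hours, fragmentation index)."""
    out: list[PEMResult] = []
    for row in _ROWS:
        (g, pid,
         pem_s, ma_s, sa_s, mb_s, sb_s, d_s,
         pem_f, ma_f, sa_f, mb_f, sb_f, d_f) = row
        out.append(
            PEMResult.from_summary(
                pid, g, "sedentary_hours", "lower_is_better",
                pem_s, ma_s, sa_s, mb_s, sb_s, difference=d_s,
            )
        )
        out.append(
            PEMResult.from_summary(
                pid, g, "fragmentation_index", "higher_is_better",
                pem_f, ma_f, sa_f, mb_f, sb_f, difference=d_f,
            )
        )
    return out
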