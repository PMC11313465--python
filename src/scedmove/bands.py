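"""Visual-analysis artifacts: baseline mean / 2-SD bands and series figures.

Single-case data are judged visually for changes in level, trend,
variability, overlap and consistency.  To anchor that judgment, each
participant's series is drawn with the baseline (phase A) mean and a band
at mean +/- 2 sample SDs extended across all phases; post days beyond the
band on the improvement side are counted.  The descriptors themselves are
emitted as numbers (phase means, per-phase OLS slopes, the outside-band
count) — the human judgment stays human.

Figures are exported as SVG (byte-deterministic for fixed input) and PNG,
with the exact plotted table alongside as CSV so every drawn point is
auditable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .design import ParticipantSeries
from .pem import OUTCOME_DIRECTIONS, POST_PHASES

# fixed hash salt + no embedded date -> reproducible SVG bytes
matplotlib.rcParams["svg.hashsalt"] = "scedmove"


@dataclass
class BandSummary:
    """Baseline mean and 2-SD band for one participant and outcome."""

    baseline_mean: float
    baseline_sd: float
    upper: float
    lower: float
    n_post_outside_band_in_improvement_direction: int


def baseline_band(
    series: ParticipantSeries,
    outcome: str,
    direction: str | None = None,
) -> BandSummary:
    """Baseline mean +/- 2 sample SDs, and the count of post (B and A') days
    strictly beyond the band on the improvement side.

    A post day exactly on the band edge is *not* outside (strict
    inequality), so a zero-width band from a constant baseline flags any
    different post value.
    """
    if direction is None:
        direction = OUTCOME_DIRECTIONS.get(outcome)
        if direction is None:
            raise ValueError(f"no default improvement direction for {outcome!r}")
    a_vals = series.values(outcome, phases=("A",))
    if a_vals.size < 2:
        raise ValueError(
            f"participant {series.id}: need >= 2 valid baseline days for a band, "
            f"got {a_vals.size}"
        )
    mean = float(a_vals.mean())
    sd = float(a_vals.std(ddof=1))
    upper, lower = mean + 2 * sd, mean - 2 * sd
    post = series.values(outcome, phases=POST_PHASES)
    if direction == "lower_is_better":
        n_out = int((post < lower).sum())
    else:
        n_out = int((post > upper).sum())
    return BandSummary(mean, sd, upper, lower, n_out)


def plot_data_table(series: ParticipantSeries, outcome: str) -> pd.DataFrame:
    """The analysis-set days exactly as drawn: offset, phase, value."""
    recs = series.valid_days()
    return pd.DataFrame(
        {
            "offset": [d.offset for d in recs],
            "date": [d.date for d in recs],
            "phase": [d.phase for d in recs],
            outcome: [getattr(d.metrics, outcome) for d in recs],
        }
    )


def phase_slopes(series: ParticipantSeries, outcome: str) -> dict[str, float]:
    """OLS slope of outcome on day offset within each phase (trend summary)."""
    out: dict[str, float] = {}
    tab = plot_data_table(series, outcome)
    for phase, sub in tab.groupby("phase"):
        if len(sub) >= 2 and sub["offset"].nunique() > 1:
            out[phase] = float(np.polyfit(sub["offset"], sub[outcome], 1)[0])
        else:
            out[phase] = float("nan")
    return out


def render_series(
    series: ParticipantSeries,
    outcome: str,
    band: BandSummary,
    out_dir: str | Path,
    formats: tuple[str, ...] = ("svg", "png"),
) -> list[Path]:
    """Render one participant-outcome panel and its plot-data CSV.

    Points are plotted at calendar day offsets with no interpolation across
    missing days or phase boundaries; vertical lines mark intervention start
    and end, a solid line the baseline mean, dashed lines the 2-SD band.
    Returns the written file paths (CSV first).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tab = plot_data_table(series, outcome)
    if tab.empty:
        raise ValueError(f"participant {series.id}: nothing to plot for {outcome}")
    stem = f"{series.id}_{outcome}"
    paths = [out_dir / f"{stem}.csv"]
    tab.to_csv(paths[0], index=False)

    fig, ax = plt.subplots(figsize=(8, 3.2))
    for phase, marker in (("A", "o"), ("B", "s"), ("A'", "^")):
        sub = tab[tab["phase"] == phase]
        ax.plot(sub["offset"], sub[outcome], marker, ms=4, ls="-", lw=0.8, label=f"Phase {phase}")
    b_offsets = tab.loc[tab["phase"] == "B", "offset"]
    if not b_offsets.empty:
        ax.axvline(series.baseline_days - 0.5, color="black", lw=1.2)
        after_b = tab.loc[tab["phase"] == "A'", "offset"]
        end = (after_b.min() if not after_b.empty else b_offsets.max() + 1) - 0.5
        ax.axvline(end, color="black", lw=1.2)
    ax.axhline(band.baseline_mean, color="black", lw=1.0)
    ax.axhline(band.upper, color="red", lw=1.0, ls="--")
    ax.axhline(band.lower, color="red", lw=1.0, ls="--")
    ax.set_xlabel("study day")
    ax.set_ylabel(outcome.replace("_", " "))
    ax.set_title(f"{series.id} ({series.group})")
    ax.legend(loc="best", fontsize=7)
    fig.tight_layout()
    for fmt in formats:
        p = out_dir / f"{stem}.{fmt}"
        kwargs = {"metadata": {"Date": None}} if fmt == "svg" else {}
        fig.savefig(p, format=fmt, **kwargs)
        paths.append(p)
    plt.close(fig)
    return paths
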