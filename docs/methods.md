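# Methods

`scedmove` analyzes randomized multiple-baseline single-case studies of
movement behavior measured with thigh-worn posture monitors. This note
records the models, conventions and numerical choices the package commits
to, and what its synthetic cohorts do and do not establish about real data.

## From posture events to daily outcomes

Monitors of the ActivPAL class export one row per posture *event* — a
maximal run of sitting/lying ("sedentary"), standing or stepping, with a
start time, a duration in seconds and a cumulative step count. The package
treats the event stream as ground truth and performs no signal processing.
Waking windows come from participant diaries (rise and bed time per date;
bed times at or before the rise time are read as past midnight). Events
spanning a window edge are split and only the in-window part kept, so
clipping conserves in-window time exactly. For dates without a diary entry
an optional fallback treats the longest sedentary event overlapping
00:00–06:00 as the night's sleep and windows the day between consecutive
sleep events; diaries are always authoritative when present and every
fallback use is logged. All timestamps are naive local clock times and all
arithmetic uses recorded durations, so daylight-saving shifts cannot corrupt
daily totals.

Daily outcomes per waking day:

- **Sedentary hours** — summed sedentary event time.
- **Fragmentation index (FI)** — sedentary bout count divided by sedentary
  hours (bouts per sedentary hour). A *bout* is a maximal run of sedentary
  events with zero in-window gap; any upright event or gap terminates it,
  with no merging tolerance (event streams are already device-smoothed, so
  a recorded 1-s upright event is a real posture change). An FI rise of 1.1
  at 10 h of daily sitting is ≈ 11 additional interruptions. The FI is
  defined here explicitly because field usage varies; this is the
  breaks-per-sedentary-hour convention.
- **Prolonged-bout fraction** — share of sedentary time in bouts strictly
  longer than 30 min.
- **MVPA minutes / LPA hours** — posture-class monitors carry no energy
  expenditure, so moderate-to-vigorous activity is proxied by stepping at
  cadence ≥ 100 steps/min (configurable); all other upright time is light
  activity. The three outcome classes partition wear time exactly on
  gap-free days.

A day is *valid* with ≥ 10 h of recorded in-window wear (configurable; no
published threshold exists for this design, and diaried waking windows of
~15.5 h make 10 h a conservative floor). The eligibility screen reproduces
the highly-sedentary inclusion rule: mean daily sedentary time ≥ 9.5 h AND
(mean prolonged-bout fraction > 0.5 OR weekly MVPA < 150 min), over one
week with ≥ 4 valid days; weekly MVPA is the valid-day sum rescaled to 7
days when the week is incomplete (a raw-sum mode is provided).

## Design and randomization test

Each participant's baseline length is randomized among candidate durations
(default 4, 6, 8, 10, 12 or 14 days), either independently and uniformly
(default, matching how such studies randomize) or "balanced" (the candidate
set dealt out like a deck, the setting the classical permutation argument
assumes). Measurement covers the baseline block and, by default, 7-day
blocks at intervention weeks 1, 8 and 15 plus a 7-day post-intervention
follow-up; the schedule is configuration, not an assumption.

The test statistic is the unweighted mean over participants of
(post-mean − pre-mean) of the daily outcome, splitting each series at the
hypothetical start implied by an assignment of baseline durations; "post"
is phases B and A′ jointly (configurable to B only). The permutation space
is, by default, the set of distinct rearrangements of the *realized*
multiset of durations across participants ("within_set"); the full product
space over candidates is available. Two-tailed p = share of admissible
assignments with |statistic| ≥ |observed|, observed included, which makes
the test exact-level. Exact enumeration is used up to 10⁶ assignments
(evaluated in chunks from a lazy iterator); beyond that, assignments are
sampled with replacement and the observed one is counted once, with the
seed recorded. |·| comparisons use a 10⁻¹² relative guard so exact ties
count as extreme rather than falling to float noise.

Dropouts are analyzed by intention to treat: all their valid days enter
every split. A dropout with a short baseline can lack any measured day
beyond a late hypothetical start, leaving an empty post side; such
assignments are excluded from the permutation space with a logged warning
(the test conditions on admissibility), and the realized assignment must
itself be admissible. The minimal attainable p is 1 over the number of
admissible assignments — 1/720 for six participants with six distinct
durations, which is why six per group suffices for α = 0.05 subgroup tests.

## Effect sizes and visual analysis

PEM (percentage exceeding the median) is the share of valid B ∪ A′ days
strictly better than the valid-phase-A median, in the outcome's improvement
direction (lower for sedentary hours, higher for FI, LPA, MVPA). Days equal
to the median do not count — "exceeding" is strict, which matters with
discrete data. Even-count medians use the midpoint convention. Categories:
> 90 high, 70–90 moderate, 60–70 mild, 50–60 questionable, < 50 none;
boundary values go to the higher-named bin (90 → moderate, 70 → moderate,
60 → mild, 50 → questionable) since interval notation is ambiguous there;
the edges are module constants. Phase summaries use sample SDs (n − 1) and
improvement-signed differences (mean A − mean B∪A′ for lower-is-better
outcomes, reversed otherwise); report tables round one decimal, half away
from zero. Cohort rollups count participants with PEM strictly above a
threshold (default 60) on at least one and on both primary outcomes, plus
mean/SD/range of improvers' differences, and the replacement analysis
classifies sedentary-time improvers by whether LPA, MVPA or both also
improved.

Visual analysis is supported, not automated: each participant-outcome panel
shows the series at calendar day offsets (no interpolation across gaps or
phases), intervention start/stop lines, the baseline mean and dashed
mean ± 2 SD bands (sample SD, consistent with the effect-size module).
A post day exactly on a band edge is not outside it. Level/trend/overlap
descriptors are emitted as numbers (phase means, per-phase OLS slopes,
outside-band counts); the plotted table is exported as CSV next to the SVG
and PNG so every drawn point is auditable, and SVGs are byte-deterministic
for fixed input.

## Synthetic cohorts

The generator emulates the published structure of the motivating cohort of
highly sedentary stroke survivors: person-level baseline sedentary means
N(11.4, 1.1²) h, day-level noise N(0, 1.2²) h truncated to the waking
window; person-level baseline FI N(4.1, 1.4²) bouts/h (floored at 0.8) with
day-level noise SD 1.0; daily MVPA truncated-normal (mean 15, SD 10 min);
a fixed 15.5 h waking window. The fragmentation level/spread and the
within-person SDs are taken from the published per-participant phase-A
columns (means 2.3–7.2, SDs 0.3–2.3 across phases). Intervention effects
are additive from each participant's allocated start — defaults −1.3 h
sedentary and +1.1 bouts/h, the published average changes — as a step
(default, matching the two-phase statistic) or a linear ramp over 5 weeks;
the two groups can receive different effects, and one dropout can be
injected to exercise intention-to-treat handling.

Two layers share one random stream. The *value layer* emits daily outcome
values directly and is what the simulation checks run on: with 6
participants × 6 balanced durations and zero effect, the exact test's
rejection rate at α = 0.05 over 2000 replicates sits inside [0.035, 0.065];
with the 14-participant design and the default effects, the group statistic
recovers −1.3 h and +1.1 bouts/h to within 0.15 averaged over 200
replicates with > 80% power. The *event layer* realizes each day's targets
as an event stream: lognormal bout lengths (σ = 0.9, producing the long
right tail and hence > 30-min bouts) rescaled so sedentary time matches the
target exactly; bout count round(FI × sedentary hours), so realized FI is
exact up to that rounding (≤ 0.5/sedentary-hours); upright gaps (≥ 1 s
between bouts) split into standing, slow stepping and the exact MVPA
allotment at cadence 115. Events tile the window exactly, and the file
round-trip through event I/O and daily metrics conserves all targets, which
is tested.

What passing these checks does *not* show: real accelerometry has autocorrelated
day-to-day behavior, wear-time irregularities, seasonal and weekday
structure, and intervention responses that drift rather than step. The
generator makes none of those claims; it establishes that the statistical
machinery is correct under the stated model, not that the model is a
complete account of free-living behavior.

## Problem sizes and numerical conventions

Exact enumeration switches to Monte Carlo above 10⁶ assignments; default
Monte Carlo size is 20 000 draws. Simulation-based tests use 2000 replicates
(type-I error) and 200 replicates with 1999 Monte-Carlo draws each
(recovery/power), sizes at which the binomial error of the checked rates is
several times smaller than the acceptance bands. Overlapping input events
are repaired by truncating the earlier event (logged); events shorter than
1 µs after clipping are dropped. The manifest hashes all CSV/JSON/SVG/YAML
outputs (PNGs are rendered but excluded from the hash set, as raster
encoders are not guaranteed stable across library builds).
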