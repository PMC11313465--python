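"""Synthetic generator: day realization, cohort structure, file round-trips."""

import datetime as dt

import numpy as np
import pytest

from scedmove.events import ActivityClass
from scedmove.metrics import day_metrics, sedentary_bouts
from scedmove.pipeline import load_series
from scedmove.synth import (
    SyntheticConfig,
    expected_prolonged_fraction,
    generate_cohort,
    generate_cohort_values,
    generate_day,
)

T0 = dt.datetime(2021, 3, 1, 7, 30)


class TestGenerateDay:
    def test_bout_count_and_total(self):
        rng = np.random.default_rng(1)
        day = generate_day(10.0, 1.0, 15.0, T0, 15.0, rng)
        bouts = sedentary_bouts(day)
        assert len(bouts) == 10
        assert sum(b.duration_min for b in bouts) == pytest.approx(600.0, abs=1.0)

    def test_metrics_recover_targets(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            S = rng.uniform(8, 12)
            F = rng.uniform(2.3, 7.2)
            M = rng.uniform(0, 30)
            m = day_metrics(generate_day(S, F, M, T0, 15.5, rng))
            assert m.sedentary_hours == pytest.approx(S, abs=1 / 60)
            assert abs(m.fragmentation_index - F) / F < 0.15
            assert m.mvpa_minutes == pytest.approx(M, abs=1e-6)

    def test_events_tile_window_exactly(self):
        rng = np.random.default_rng(3)
        day = generate_day(10.0, 4.0, 20.0, T0, 15.5, rng)
        assert day.events[0].start == day.rise
        assert abs((day.events[-1].end - day.bed).total_seconds()) < 1e-4
        for a, b in zip(day.events, day.events[1:]):
            assert abs((b.start - a.end).total_seconds()) < 1e-6

    def test_all_day_sitting_is_single_bout(self):
        rng = np.random.default_rng(4)
        day = generate_day(15.5, 3.0, 0.0, T0, 15.5, rng)
        (bout,) = sedentary_bouts(day)
        assert bout.duration_min == pytest.approx(15.5 * 60)
        assert day_metrics(day).fragmentation_index == pytest.approx(1 / 15.5)

    def test_infeasible_targets_error(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="exceeds the"):
            generate_day(16.0, 3.0, 0.0, T0, 15.5, rng)
        with pytest.raises(ValueError, match="MVPA"):
            generate_day(15.0, 3.0, 100.0, T0, 15.5, rng)
        with pytest.raises(ValueError, match="bouts"):
            # 385 bouts need 384 separating gaps but only 6 upright minutes exist
            generate_day(15.4, 25.0, 0.0, T0, 15.5, rng)

    def test_prolonged_fraction_model_monotone(self):
        # more fragmentation -> shorter bouts -> less prolonged time
        vals = [expected_prolonged_fraction(f, 0.9) for f in (1.0, 2.0, 4.0, 8.0)]
        assert vals == sorted(vals, reverse=True)
        assert 0.0 < vals[-1] < vals[0] < 1.0


class TestCohortValues:
    def test_reproducible_from_seed(self):
        cfg = SyntheticConfig(n_per_group=2, seed=11)
        _, alloc1, s1 = generate_cohort_values(cfg)
        _, alloc2, s2 = generate_cohort_values(cfg)
        assert alloc1 == alloc2
        for a, b in zip(s1, s2):
            assert np.array_equal(a.values("sedentary_hours"), b.values("sedentary_hours"))

    def test_baseline_level_matches_screened_population(self):
        """Cohort phase-A sedentary mean lands near 11.4 h (between-person SD
        1.1 over 14 participants gives a standard error of ~0.3)."""
        cfg = SyntheticConfig(effect_sedentary_h=0.0, effect_fragmentation=0.0)
        means = []
        for seed in range(1, 11):
            _, _, series = generate_cohort_values(cfg, seed=seed)
            means.append(np.mean([s.values("sedentary_hours", ("A",)).mean() for s in series]))
        assert 11.1 <= np.mean(means) <= 11.7

    def test_step_effect_applied_from_baseline_end(self):
        cfg = SyntheticConfig(n_per_group=2, within_person_sd=0.0,
                              fragmentation_within_sd=0.0, effect_sedentary_h=-2.0, seed=5)
        _, _, series = generate_cohort_values(cfg)
        for s in series:
            pre = s.values("sedentary_hours", ("A",))
            post = s.values("sedentary_hours", ("B", "A'"))
            assert post.mean() - pre.mean() == pytest.approx(-2.0, abs=1e-9)

    def test_group_specific_effects(self):
        cfg = SyntheticConfig(n_per_group=2, within_person_sd=0.0,
                              effect_sedentary_h=-2.0, effect_sedentary_h_nps=0.0, seed=6)
        _, _, series = generate_cohort_values(cfg)
        for s in series:
            delta = s.values("sedentary_hours", ("B",)).mean() - s.values(
                "sedentary_hours", ("A",)
            ).mean()
            assert delta == pytest.approx(-2.0 if s.group == "PS" else 0.0, abs=1e-9)


class TestCohortFiles:
    def test_round_trip_conserves_day_metrics(self, demo_bundle):
        """Metrics computed from the written event files match the value
        layer drawn from the same seed (the event layer only adds bout-count
        rounding)."""
        bundle, cfg = demo_bundle
        _, alloc_v, series_v = generate_cohort_values(cfg)
        spec, alloc_f, series_f = load_series(bundle)
        assert alloc_f == alloc_v
        for sv, sf in zip(series_v, series_f):
            assert sv.id == sf.id and len(sv.days) == len(sf.days)
            sed_v = sv.values("sedentary_hours")
            sed_f = sf.values("sedentary_hours")
            assert np.allclose(sed_v, sed_f, atol=2 / 60)
            # bout count is round(FI x sedentary hours), so realized FI can
            # differ from the target by at most 0.5 bouts per sedentary hour-day
            fi_v = sv.values("fragmentation_index")
            fi_f = sf.values("fragmentation_index")
            assert np.all(np.abs(fi_f - fi_v) <= 0.5 / sed_v + 1e-6)
            assert np.allclose(sv.values("mvpa_minutes"), sf.values("mvpa_minutes"), atol=0.1)

    def test_phases_preserved_through_files(self, demo_bundle):
        bundle, cfg = demo_bundle
        _, _, series = load_series(bundle)
        for s in series:
            phases = [d.phase for d in s.days]
            assert phases[: s.baseline_days] == ["A"] * s.baseline_days
            assert phases.count("A'") == cfg.followup_days

    def test_dropout_truncates_series(self, tmp_path):
        cfg = SyntheticConfig(n_per_group=2, dropout_id="PS-2", dropout_after_weeks=5, seed=9)
        generate_cohort(cfg, tmp_path / "b")
        _, _, series = load_series(tmp_path / "b")
        dropout = next(s for s in series if s.id == "PS-2")
        other = next(s for s in series if s.id == "PS-1")
        assert max(d.offset for d in dropout.days) < dropout.baseline_days + 5 * 7
        assert len(dropout.days) < len(other.days)
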