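import numpy as np
import pytest

from rarecareer import (
    CareerPlan,
    SimulationConfig,
    draw_career_plan,
    jittered_prevalence,
    new_patient_count,
    sample_case_count,
    simulate_condition_career,
    simulate_cohort,
)
from rarecareer.config import ATTRITION_ALSO, BINOMIAL, EXPECTED_BRANCH
from rarecareer.prevalence import Condition

from conftest import single_condition_list


def make_config(**kwargs):
    base = dict(
        n_clinicians=3, years=12, panel_size=300, min_job_changes=1,
        max_job_changes=4, attrition_rate=0.1, jitter_fraction=0.15, seed=1,
    )
    base.update(kwargs)
    return SimulationConfig(**base)


class TestCareerPlan:
    def test_no_changes(self, rng):
        cfg = make_config(min_job_changes=0, max_job_changes=0)
        plan = draw_career_plan(cfg, 1, rng)
        assert plan.job_change_years == frozenset()

    def test_change_every_year_after_first(self, rng):
        cfg = make_config(years=5, min_job_changes=4, max_job_changes=4)
        plan = draw_career_plan(cfg, 1, rng)
        assert plan.job_change_years == frozenset({2, 3, 4, 5})

    def test_class_scenario_bounds(self, rng):
        cfg = SimulationConfig(n_clinicians=97, years=30, panel_size=1500,
                               min_job_changes=2, max_job_changes=10, seed=1)
        for i in range(1, 50):
            plan = draw_career_plan(cfg, i, rng)
            assert 2 <= len(plan.job_change_years) <= 10
            assert all(2 <= y <= 30 for y in plan.job_change_years)


class TestJitter:
    def test_zero_jitter_is_identity(self, rng):
        assert jittered_prevalence(0.37, 0.0, rng) == 0.37

    def test_fifteen_percent_bound(self, rng):
        draws = [jittered_prevalence(0.01, 0.15, rng) for _ in range(2000)]
        assert all(0.0085 <= d <= 0.0115 for d in draws)

    def test_zero_mean_perturbation(self):
        rng = np.random.default_rng(123)
        draws = np.array([jittered_prevalence(0.01, 0.15, rng) for _ in range(100_000)])
        # uniform on +/-15% of 0.01: sd = 0.15*0.01/sqrt(3)
        se = 0.15 * 0.01 / np.sqrt(3) / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.01) < 3 * se

    def test_invalid_prevalence_rejected(self, rng):
        with pytest.raises(ValueError):
            jittered_prevalence(1.5, 0.1, rng)


class TestNewPatientCount:
    def test_first_year_full_panel(self):
        cfg = make_config(panel_size=1500)
        plan = CareerPlan(1, frozenset({5}))
        assert new_patient_count(plan, 1, cfg) == 1500

    def test_change_year_full_panel(self):
        cfg = make_config(panel_size=2000, years=12)
        plan = CareerPlan(1, frozenset({5}))
        assert new_patient_count(plan, 5, cfg) == 2000

    def test_attrition_year_rounded_fraction(self):
        cfg = make_config(panel_size=1500, attrition_rate=0.10)
        plan = CareerPlan(1, frozenset())
        assert new_patient_count(plan, 3, cfg) == 150

    def test_rounding_half_away_from_zero(self):
        cfg = make_config(panel_size=25, attrition_rate=0.10)  # 2.5 -> 3
        plan = CareerPlan(1, frozenset())
        assert new_patient_count(plan, 3, cfg) == 3

    def test_year_out_of_range(self):
        cfg = make_config(years=12)
        plan = CareerPlan(1, frozenset())
        with pytest.raises(ValueError):
            new_patient_count(plan, 13, cfg)


class TestSampleCaseCount:
    @pytest.mark.parametrize("mode", [BINOMIAL, EXPECTED_BRANCH])
    def test_degenerate_prevalences(self, mode, rng):
        assert sample_case_count(50, 0.0, mode, rng) == 0
        assert sample_case_count(50, 1.0, mode, rng) == 50

    @pytest.mark.parametrize("mode", [BINOMIAL, EXPECTED_BRANCH])
    def test_one_case_per_year_at_threshold_prevalence(self, mode):
        # panel 2000 at prevalence 1/2000: mean one case per year
        rng = np.random.default_rng(11)
        draws = np.array([sample_case_count(2000, 1 / 2000, mode, rng)
                          for _ in range(10_000)])
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        # expected_branch is exactly 1 when lambda = 1, hence se may be 0
        assert abs(draws.mean() - 1.0) <= 3 * se

    def test_expected_branch_support_and_mean(self):
        # lambda = 2.4: only floor or floor+1 possible, mean preserved
        rng = np.random.default_rng(5)
        draws = np.array([sample_case_count(24, 0.1, EXPECTED_BRANCH, rng)
                          for _ in range(20_000)])
        assert set(np.unique(draws)) <= {2, 3}
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - 2.4) < 3 * se

    def test_expected_branch_below_one_is_bernoulli(self):
        rng = np.random.default_rng(5)
        draws = np.array([sample_case_count(5, 0.1, EXPECTED_BRANCH, rng)
                          for _ in range(5_000)])
        assert set(np.unique(draws)) <= {0, 1}

    def test_negative_exposure_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_case_count(-1, 0.1, BINOMIAL, rng)


class TestConditionCareer:
    def test_zero_prevalence_all_zero(self, rng):
        cfg = make_config()
        plan = CareerPlan(1, frozenset({4}))
        cond = Condition(1, 0.0, "spontaneous")
        counts, new = simulate_condition_career(cond, plan, cfg, rng)
        assert not counts.any() and not new.any()

    def test_spontaneous_counts_equal_new_counts(self, rng):
        cfg = make_config(jitter_fraction=0.0)
        plan = CareerPlan(1, frozenset({4}))
        cond = Condition(1, 0.05, "spontaneous")
        counts, new = simulate_condition_career(cond, plan, cfg, rng)
        assert (counts == new).all()

    def test_congenital_frozen_without_new_patients(self, rng):
        # no job changes, no attrition: caseload constant after year 1
        cfg = make_config(min_job_changes=0, max_job_changes=0, attrition_rate=0.0)
        plan = CareerPlan(1, frozenset())
        cond = Condition(1, 0.2, "congenital")
        counts, new = simulate_condition_career(cond, plan, cfg, rng)
        assert (counts == counts[0]).all()
        assert not new[1:].any()

    def test_congenital_resets_at_job_change(self):
        cfg = make_config(years=20, panel_size=500, attrition_rate=0.05,
                          jitter_fraction=0.0)
        plan = CareerPlan(1, frozenset({10}))
        cond = Condition(1, 0.3, "congenital")
        rng = np.random.default_rng(3)
        counts, new = simulate_condition_career(cond, plan, cfg, rng)
        # reset at the change year: caseload equals that year's fresh draw
        assert counts[9] == new[9]
        # non-decreasing along each run between changes
        assert (np.diff(counts[:9]) >= 0).all()
        assert (np.diff(counts[9:]) >= 0).all()

    def test_congenital_new_counts_bounded_by_new_patients(self):
        cfg = make_config(years=20, panel_size=500, attrition_rate=0.1)
        plan = CareerPlan(1, frozenset({7, 13}))
        cond = Condition(1, 0.5, "congenital")
        rng = np.random.default_rng(4)
        counts, new = simulate_condition_career(cond, plan, cfg, rng)
        for y in range(1, 21):
            assert new[y - 1] <= new_patient_count(plan, y, cfg)

    def test_attrition_also_mode_can_shed_cases(self):
        cfg = make_config(years=30, panel_size=200, attrition_rate=0.3,
                          min_job_changes=0, max_job_changes=0,
                          congenital_loss=ATTRITION_ALSO, jitter_fraction=0.0)
        plan = CareerPlan(1, frozenset())
        cond = Condition(1, 0.3, "congenital")
        rng = np.random.default_rng(8)
        counts, _ = simulate_condition_career(cond, plan, cfg, rng)
        assert (np.diff(counts) < 0).any()


class TestCohort:
    def test_zero_prevalence_cube_is_empty(self):
        cfg = SimulationConfig(n_clinicians=1, years=1, panel_size=10,
                               min_job_changes=0, max_job_changes=0, seed=0)
        cube = simulate_cohort(cfg, single_condition_list(0.0))
        assert not cube.counts.any()

    def test_seed_determinism_bit_identical(self, small_config, small_list):
        a = simulate_cohort(small_config, small_list)
        b = simulate_cohort(small_config, small_list)
        assert (a.counts == b.counts).all()
        assert (a.new_counts == b.new_counts).all()

    def test_earlier_clinicians_stable_under_cohort_growth(self, small_config, small_list):
        import dataclasses

        bigger = dataclasses.replace(small_config, n_clinicians=small_config.n_clinicians + 4)
        a = simulate_cohort(small_config, small_list)
        b = simulate_cohort(bigger, small_list)
        assert (a.counts == b.counts[: small_config.n_clinicians]).all()

    def test_counts_bounded_by_panel(self, small_cube, small_config):
        assert small_cube.counts.max() <= small_config.panel_size
        assert (small_cube.counts >= 0).all()

    def test_spontaneous_counts_equal_new(self, small_cube, small_list):
        mask = ~small_list.congenital_mask
        assert (small_cube.counts[:, :, mask] == small_cube.new_counts[:, :, mask]).all()

    def test_every_career_sees_a_rare_condition(self):
        # expected rare-case load per career is far above 1, so every
        # clinician should encounter at least one low-prevalence condition
        from rarecareer import build_disease_list

        cfg = SimulationConfig(n_clinicians=20, years=40, panel_size=1500,
                               min_job_changes=2, max_job_changes=10, seed=6)
        cube = simulate_cohort(cfg, build_disease_list(seed=6))
        rare = cube.new_counts[:, :, 200:].sum(axis=(1, 2))
        assert (rare >= 1).all()

    def test_long_frame_round_trips_totals(self, small_cube):
        df = small_cube.to_long_frame()
        assert df["cases"].sum() == small_cube.counts.sum()
        assert df["new_cases"].sum() == small_cube.new_counts.sum()
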