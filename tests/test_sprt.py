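import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rasprt.risk import build_model_sequence
from rasprt.simulate import OutlierInjection, simulate_frame
from rasprt.sprt import (
    SprtConfig,
    case_weight,
    compute_boundaries,
    run_all,
    run_surveillance,
    update_statistic,
)

from conftest import ConstantModels, stream_frame


class TestBoundaries:
    def test_default_configuration_closed_form(self):
        b = compute_boundaries(SprtConfig(alpha=0.05, beta=0.10, odds_ratio=2.0))
        assert b.h1 == pytest.approx(4.169925001442, abs=1e-9)
        assert b.h0 == pytest.approx(-3.247927513444, abs=1e-9)
        assert b.h0 < 0 < b.h1

    def test_equal_error_rates_give_symmetric_limits(self):
        b = compute_boundaries(SprtConfig(alpha=0.05, beta=0.05, odds_ratio=1.5))
        assert b.h1 - abs(b.h0) == pytest.approx(0.0, abs=1e-12)

    def test_unit_odds_ratio_is_rejected(self):
        with pytest.raises(ValueError, match="odds_ratio"):
            SprtConfig(odds_ratio=1.0)

    @given(
        alpha=st.floats(0.005, 0.45),
        beta=st.floats(0.005, 0.45),
        odds_ratio=st.floats(1.05, 10.0),
    )
    def test_limits_bracket_zero_for_any_valid_config(self, alpha, beta, odds_ratio):
        b = compute_boundaries(SprtConfig(alpha=alpha, beta=beta, odds_ratio=odds_ratio))
        assert b.h0 < 0 < b.h1


class TestCaseWeight:
    @pytest.mark.parametrize(
        "p, odds_ratio, expected",
        [
            (0.0, 2.0, 0.0),
            (0.5, 2.0, math.log(1.5) / math.log(2.0)),   # ~0.584963
            (0.02, 2.0, math.log(1.02) / math.log(2.0)),  # ~0.028569
        ],
    )
    def test_direct_evaluation(self, p, odds_ratio, expected):
        assert case_weight(p, odds_ratio) == pytest.approx(expected, abs=1e-9)

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            case_weight(1.0, 2.0)
        with pytest.raises(ValueError):
            case_weight(-0.1, 2.0)

    @given(p=st.floats(0.0, 0.999), odds_ratio=st.floats(1.01, 20.0))
    def test_weight_dominates_probability(self, p, odds_ratio):
        s = case_weight(p, odds_ratio)
        assert 0.0 <= s < 1.0
        assert s >= p - 1e-12
        if 0.0 < p:
            assert s > p  # strict inside the interval (concavity of ln)


class TestUpdateStatistic:
    def test_death_and_survival_increments(self):
        s = case_weight(0.02, 2.0)
        assert update_statistic(0.0, 1, 0.02, 2.0) == pytest.approx(1 - s, abs=1e-9)
        assert update_statistic(0.0, 0, 0.02, 2.0) == pytest.approx(-s, abs=1e-9)
        assert update_statistic(0.0, 1, 0.02, 2.0) == pytest.approx(0.971431, abs=1e-6)

    def test_three_consecutive_deaths_accumulate(self):
        t = 0.0
        for _ in range(3):
            t = update_statistic(t, 1, 0.02, 2.0)
        assert t == pytest.approx(2.914292, abs=1e-6)

    def test_drift_sign_under_null_and_alternative(self):
        # exact expectations (no simulation): E[O - s] = p - s(p) under the
        # null and p1 - s(p) under the alternative, p1 = OR*p/(1-p+OR*p)
        odds_ratio = 2.0
        for p in np.linspace(0.001, 0.5, 200):
            s = case_weight(p, odds_ratio)
            p1 = odds_ratio * p / (1 - p + odds_ratio * p)
            assert p - s < 0
            assert p1 - s > 0


class TestWaldOracle:
    @staticmethod
    def wald_llr_sum(outcomes, probs, odds_ratio):
        """Independent oracle: textbook Wald log-likelihood-ratio sum."""
        total = 0.0
        for o, p in zip(outcomes, probs):
            p1 = odds_ratio * p / (1 - p + odds_ratio * p)
            total += o * math.log(p1 / p) + (1 - o) * math.log((1 - p1) / (1 - p))
        return total

    def test_statistic_times_log_or_equals_wald_llr(self):
        rng = np.random.default_rng(404)
        odds_ratio = 2.0
        for _ in range(20):
            n = 500
            probs = rng.uniform(0.005, 0.4, size=n)
            outcomes = (rng.random(n) < probs).astype(int)
            t = 0.0
            for o, p in zip(outcomes, probs):
                t = update_statistic(t, int(o), float(p), odds_ratio)
            oracle = self.wald_llr_sum(outcomes, probs, odds_ratio)
            assert abs(t * math.log(odds_ratio) - oracle) < 1e-9 * (n / 1000)


class TestRunSurveillance:
    def test_empty_stream_produces_inert_trajectory(self):
        traj = run_surveillance(stream_frame([]), ConstantModels(0.02), SprtConfig())
        assert traj.steps == [] and not traj.alerted and traj.final_value == 0.0

    def test_death_stream_crosses_upper_boundary_at_step_five(self):
        # increment per death at p=0.02 is ~0.971431; ceil(4.169925/0.971431) = 5
        traj = run_surveillance(stream_frame([1] * 10), ConstantModels(0.02), SprtConfig())
        assert traj.alerted
        assert traj.crossings[0] == (4, "h1")

    def test_survival_stream_accepts_null_at_step_six_without_alert(self):
        # decrement per survivor at p=0.5 is ~0.584963; ceil(3.247928/0.584963) = 6
        traj = run_surveillance(stream_frame([0] * 10), ConstantModels(0.5), SprtConfig())
        assert not traj.alerted
        assert traj.crossings[0] == (5, "h0")
        # post-crossing reset: the next step starts from zero again
        assert traj.steps[6].cumulative == pytest.approx(traj.steps[0].increment)

    def test_absorb_policy_stops_at_first_crossing(self):
        config = SprtConfig(post_crossing_policy="absorb")
        traj = run_surveillance(stream_frame([1] * 10), ConstantModels(0.02), config)
        assert traj.alerted and len(traj.steps) == 5

    def test_cases_without_model_month_are_skipped_and_logged(self):
        class OneMonthModels:
            def __init__(self, p):
                self.model = ConstantModels(p).model

            def get(self, month):
                return self.model if str(month) == "2004-02" else None

        frame = stream_frame([0] * 40)  # spans February and March 2004
        traj = run_surveillance(frame, OneMonthModels(0.5), SprtConfig())
        assert len(traj.steps) + len(traj.skipped_case_ids) == 40
        assert len(traj.skipped_case_ids) == 11  # the March cases

    def test_cumulative_is_running_sum_of_increments(self):
        rng = np.random.default_rng(7)
        traj = run_surveillance(
            stream_frame((rng.random(200) < 0.3).astype(int)),
            ConstantModels(0.3), SprtConfig(),
        )
        running = 0.0
        for step in traj.steps:
            if traj.crossings and any(i == step.index - 1 for i, _ in traj.crossings):
                running = 0.0
            running += step.increment
            assert step.cumulative == pytest.approx(running, abs=1e-12)


@pytest.fixture(scope="module")
def two_year_run():
    from rasprt.registry import ReportingPeriod
    from rasprt.simulate import GenerationSegment, SimulationScenario

    hospitals = tuple(f"H{i:02d}" for i in range(1, 5))
    periods = (
        ReportingPeriod("CY2005", dt.date(2005, 1, 1), dt.date(2005, 12, 31)),
        ReportingPeriod("FY2006", dt.date(2005, 10, 1), dt.date(2006, 9, 30)),
    )
    segments = (
        GenerationSegment("2005A", dt.date(2005, 1, 1), dt.date(2005, 9, 30), 1800, hospitals, 0.02),
        GenerationSegment("2005Q4", dt.date(2005, 10, 1), dt.date(2005, 12, 31), 600, hospitals, 0.02),
        GenerationSegment("2006A", dt.date(2006, 1, 1), dt.date(2006, 9, 30), 1800, hospitals, 0.02),
    )
    scenario = SimulationScenario(periods=periods, segments=segments, seed=55)
    frame = simulate_frame(scenario)
    models = build_model_sequence(frame, scenario.schema)
    trajectories = run_all(frame, periods, models, SprtConfig())
    return scenario, frame, trajectories


class TestRunAll:
    def test_one_trajectory_per_hospital_period(self, two_year_run):
        _, _, trajectories = two_year_run
        assert set(trajectories) == {
            (h, lab) for h in ("H01", "H02", "H03", "H04") for lab in ("CY2005", "FY2006")
        }

    def test_overlap_case_contributes_to_exactly_two_trajectories(self, two_year_run):
        _, frame, trajectories = two_year_run
        case = frame.loc[frame["procedure_date"] == "2005-11-01"].iloc[0]
        holding = [
            key for key, traj in trajectories.items()
            if any(s.case_id == case["case_id"] for s in traj.steps)
        ]
        assert sorted(key[1] for key in holding) == ["CY2005", "FY2006"]
        assert all(key[0] == case["hospital_id"] for key in holding)

    def test_each_period_chart_restarts_at_zero(self, two_year_run):
        # no evidence leaks across the annual reset
        _, _, trajectories = two_year_run
        for traj in trajectories.values():
            if traj.steps:
                assert traj.steps[0].cumulative == pytest.approx(traj.steps[0].increment)

    def test_reset_policy_none_gives_one_continuous_chart(self, two_year_run):
        scenario, frame, _ = two_year_run
        models = build_model_sequence(frame, scenario.schema)
        config = SprtConfig(reset_policy="none")
        trajectories = run_all(frame, scenario.periods, models, config)
        assert set(key[1] for key in trajectories) == {"ALL"}


def test_injected_outlier_alerts_in_seeded_run():
    # one hospital elevated to OR 3 with 600 cases/year at ~2% baseline alerts
    from conftest import single_year_scenario

    scenario = single_year_scenario(cases_per_hospital=600, seed=808).with_injections(
        [OutlierInjection("H05", "CY2004", 3.0)]
    )
    frame = simulate_frame(scenario)
    models = build_model_sequence(frame, scenario.schema)
    trajectories = run_all(frame, scenario.periods, models, SprtConfig())
    assert trajectories[("H05", "CY2004")].alerted
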