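"""Markov cohort engine: annualization, transitions, traces, scenarios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from prsecon.fixtures import scenario_fixtures
from prsecon.markov import (
    END_AGE,
    ENTRY_AGE,
    CohortTrace,
    HealthState,
    ScenarioProfile,
    StratumArm,
    TransitionTable,
    annualize_risk,
    build_transition_table,
    project_scenario_delta,
    run_cohort_trace,
    summarize_trace,
    trace_to_frame,
)

N_CYCLES = END_AGE - ENTRY_AGE


class TestAnnualizeRisk:
    def test_ten_year_incidence(self):
        assert annualize_risk(0.12, 10) == pytest.approx(1 - 0.88 ** 0.1, abs=1e-15)

    def test_zero_risk_and_identity(self):
        assert annualize_risk(0.0, 10) == 0.0
        assert annualize_risk(0.37, 1) == pytest.approx(0.37, abs=1e-15)

    @given(
        p=hst.floats(min_value=0, max_value=0.999),
        years=hst.integers(min_value=1, max_value=80),
    )
    @settings(max_examples=200, deadline=None)
    def test_compounding_recovers_cumulative_risk(self, p, years):
        a = annualize_risk(p, years)
        assert 1 - (1 - a) ** years == pytest.approx(p, abs=1e-12)

    def test_certain_event_rejected(self):
        with pytest.raises(ValueError):
            annualize_risk(1.0, 10)


class TestStratumArm:
    @pytest.mark.parametrize(
        "stratum,arm,intervention,statin",
        [
            ("top2", "prs_guided", True, True),
            ("next18", "prs_guided", True, False),
            ("bottom80", "prs_guided", False, False),
            ("top2", "standard", False, False),
        ],
    )
    def test_intervention_flags(self, stratum, arm, intervention, statin):
        sa = StratumArm(stratum=stratum, arm=arm)
        assert sa.intervention_active is intervention
        assert sa.statin_active is statin
        if statin:
            assert intervention  # statin implies intervention

    def test_unknown_stratum_rejected(self):
        with pytest.raises(ValueError):
            StratumArm(stratum="top5", arm="standard")


class TestBuildTransitionTable:
    def test_no_event_risk_before_forty(self, base_params):
        t = build_transition_table(base_params, StratumArm("top2", "standard"))
        pre40 = t.ages() < 40
        assert np.all(t.p_nonfatal_event[pre40] == 0)
        assert np.all(t.p_fatal_event[pre40] == 0)

    def test_high_risk_hazard_and_fatal_split_at_45(self, base_params):
        # CAD-only table so the hazard is directly the annualized 12%/10y
        cad_only = base_params.replace_values(stroke_incidence_10y_top20=0.0)
        t = build_transition_table(cad_only, StratumArm("next18", "standard"))
        i = 45 - ENTRY_AGE
        a = annualize_risk(0.12, 10)
        total = t.p_nonfatal_event[i] + t.p_fatal_event[i]
        assert total == pytest.approx(a, abs=1e-12)
        assert t.p_fatal_event[i] == pytest.approx(0.20 * a, abs=1e-12)

    def test_intervention_scales_hazard_by_one_minus_rrr(self, base_params):
        cad_only = base_params.replace_values(stroke_incidence_10y_top20=0.0)
        std = build_transition_table(cad_only, StratumArm("next18", "standard"))
        trt = build_transition_table(cad_only, StratumArm("next18", "prs_guided"))
        i = 45 - ENTRY_AGE
        ratio = (trt.p_nonfatal_event[i] + trt.p_fatal_event[i]) / (
            std.p_nonfatal_event[i] + std.p_fatal_event[i]
        )
        assert ratio == pytest.approx(0.70, abs=1e-12)

    def test_bottom_stratum_has_lower_risk(self, base_params):
        hi = build_transition_table(base_params, StratumArm("next18", "standard"))
        lo = build_transition_table(base_params, StratumArm("bottom80", "standard"))
        i = 50 - ENTRY_AGE
        assert lo.p_fatal_event[i] < hi.p_fatal_event[i]

    def test_probabilities_escaping_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            TransitionTable(
                stratum_arm=StratumArm("top2", "standard"),
                entry_age=10,
                end_age=12,
                p_nonfatal_event=np.array([0.8, 0.8]),
                p_fatal_event=np.array([0.3, 0.3]),
                p_noncv_death=np.array([0.0, 0.0]),
            )


def _zero_table():
    n = N_CYCLES
    return TransitionTable(
        stratum_arm=StratumArm("bottom80", "standard"),
        entry_age=ENTRY_AGE,
        end_age=END_AGE,
        p_nonfatal_event=np.zeros(n),
        p_fatal_event=np.zeros(n),
        p_noncv_death=np.zeros(n),
    )


class TestRunCohortTrace:
    def test_no_events_means_everyone_stays_event_free(self):
        trace = run_cohort_trace(_zero_table())
        assert np.all(trace.occupancy[:, HealthState.EVENT_FREE] == 1.0)

    def test_immediate_background_death_absorbs_everyone(self):
        n = N_CYCLES
        p_nc = np.zeros(n)
        p_nc[0] = 1.0
        table = TransitionTable(
            stratum_arm=StratumArm("bottom80", "standard"),
            entry_age=ENTRY_AGE,
            end_age=END_AGE,
            p_nonfatal_event=np.zeros(n),
            p_fatal_event=np.zeros(n),
            p_noncv_death=p_nc,
        )
        trace = run_cohort_trace(table)
        assert np.all(trace.occupancy[1:, HealthState.NONCV_DEATH] == 1.0)

    def test_cumulative_cad_incidence_recovers_ten_year_risk(self, base_params):
        # CAD-only hazard, no competing mortality: cumulative incidence over
        # ages 40-50 must invert the annualization back to exactly 12%.
        cad_only = base_params.replace_values(stroke_incidence_10y_top20=0.0)
        t = build_transition_table(cad_only, StratumArm("next18", "standard"))
        trace = run_cohort_trace(t)
        ef_at_50 = trace.occupancy[50 - ENTRY_AGE, HealthState.EVENT_FREE]
        assert 1.0 - ef_at_50 == pytest.approx(0.12, abs=1e-9)

    def test_mass_conservation_over_all_cycles(self, base_params):
        for stratum in ("top2", "next18", "bottom80"):
            for arm in ("standard", "prs_guided"):
                t = build_transition_table(base_params, StratumArm(stratum, arm))
                trace = run_cohort_trace(t)
                sums = trace.occupancy.sum(axis=1)
                assert np.all(np.abs(sums - 1.0) <= 1e-9)

    def test_death_states_never_lose_mass(self, base_params):
        t = build_transition_table(base_params, StratumArm("next18", "standard"))
        trace = run_cohort_trace(t)
        dead = trace.occupancy[:, [HealthState.CV_DEATH, HealthState.NONCV_DEATH]]
        assert np.all(np.diff(dead, axis=0) >= -1e-12)
        assert np.all(np.diff(trace.alive()) <= 1e-12)  # survival non-increasing

    def test_three_cycle_trace_matches_hand_matrix_multiplication(self):
        # Independent oracle: explicit per-cycle transition matrices applied
        # to the start vector by plain matrix multiplication.
        pnf = np.array([0.1, 0.2, 0.05])
        pf = np.array([0.05, 0.1, 0.02])
        pnc = np.array([0.02, 0.03, 0.01])
        table = TransitionTable(
            stratum_arm=StratumArm("top2", "standard"),
            entry_age=10,
            end_age=13,
            p_nonfatal_event=pnf,
            p_fatal_event=pf,
            p_noncv_death=pnc,
        )
        trace = run_cohort_trace(table)
        v = np.array([1.0, 0.0, 0.0, 0.0])
        for t in range(3):
            m = np.array(
                [
                    [1 - pnf[t] - pf[t] - pnc[t], pnf[t], pf[t], pnc[t]],
                    [0.0, 1 - pnc[t], 0.0, pnc[t]],
                    [0.0, 0.0, 1.0, 0.0],
                    [0.0, 0.0, 0.0, 1.0],
                ]
            )
            v = v @ m
            np.testing.assert_allclose(trace.occupancy[t + 1], v, atol=1e-15)


class TestSummarizeTrace:
    def test_zero_mortality_full_utilities_undiscounted(self, base_params):
        trace = run_cohort_trace(_zero_table())
        ones = base_params.replace_values(
            utility_10_40=1.0, utility_40_60=1.0, utility_60plus=1.0
        )
        s = summarize_trace(trace, ones, discount_rate=0.0)
        assert s.life_expectancy == pytest.approx(80.0, abs=1e-12)
        assert s.discounted_qalys == pytest.approx(70.0, abs=1e-9)

    def test_banded_utilities_sum_over_age_bands(self, base_params):
        # 30y x 0.95 + 20y x 0.92 + 20y x 0.85 = 63.9
        trace = run_cohort_trace(_zero_table())
        s = summarize_trace(trace, base_params, discount_rate=0.0)
        assert s.discounted_qalys == pytest.approx(63.9, abs=1e-9)

    def test_discounting_strictly_reduces_qalys(self, base_params):
        trace = run_cohort_trace(_zero_table())
        q0 = summarize_trace(trace, base_params, discount_rate=0.0).discounted_qalys
        q3 = summarize_trace(trace, base_params, discount_rate=0.03).discounted_qalys
        q5 = summarize_trace(trace, base_params, discount_rate=0.05).discounted_qalys
        assert q5 < q3 < q0

    def test_qalys_never_exceed_life_years(self, base_params):
        t = build_transition_table(base_params, StratumArm("next18", "standard"))
        trace = run_cohort_trace(t)
        s = summarize_trace(trace, base_params)
        assert s.discounted_qalys <= s.discounted_life_years

    def test_trace_export_has_one_row_per_cycle_boundary(self, base_params):
        t = build_transition_table(base_params, StratumArm("top2", "prs_guided"))
        frame = trace_to_frame(run_cohort_trace(t), base_params)
        assert len(frame) == N_CYCLES + 1
        assert frame["age"].iloc[0] == ENTRY_AGE
        assert frame["age"].iloc[-1] == END_AGE
        assert frame["cum_discounted_qaly"].is_monotonic_increasing


class TestScenarioDeltas:
    def test_prevention_gains_match_published_differences(self):
        fx = scenario_fixtures()
        delta = project_scenario_delta(
            fx["high_prs_no_prevention"].profile,
            fx["high_prs_with_prevention"].profile,
        )
        assert delta.life_expectancy_gain == pytest.approx(7.0)
        assert delta.qaly_gain == pytest.approx(13.3)

    def test_fatal_mi_fold_versus_low_prs_is_five(self):
        fx = scenario_fixtures()
        delta = project_scenario_delta(
            fx["high_prs_no_prevention"].profile, fx["low_prs"].profile
        )
        assert delta.fatal_mi_fold == pytest.approx(5.0)

    def test_identical_profiles_give_zero_deltas(self):
        p = ScenarioProfile(
            life_expectancy=80, qalys=65, mi_risk=10, stroke_risk=5, fatal_mi=2
        )
        d = project_scenario_delta(p, p)
        assert d.life_expectancy_gain == 0
        assert d.qaly_gain == 0
        assert d.mi_risk_fold == 1.0

    def test_profile_invariants(self):
        with pytest.raises(ValueError):
            ScenarioProfile(
                life_expectancy=80, qalys=65, mi_risk=5, stroke_risk=5, fatal_mi=10
            )
        with pytest.raises(ValueError):
            ScenarioProfile(
                life_expectancy=60, qalys=65, mi_risk=5, stroke_risk=5, fatal_mi=2
            )
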