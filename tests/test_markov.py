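"""Decision tree + Markov cohort engine."""

import dataclasses
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perioecon import (
    RewardSpec,
    annual_to_multi_year_prob,
    arm_expected_values,
    build_transition_matrix,
    discount_factor,
    run_cohort_trace,
)
from perioecon.markov import (
    LOST_NO_REHAB,
    LOST_REHAB,
    MAINTENANCE,
    Stratum,
    TransitionMatrix,
    build_rewards,
    run_stratum,
)
from perioecon.synthetic import microsimulate_arm


class TestTransitionMatrix:
    def test_no_loss_limit(self):
        m = build_transition_matrix(0.0, 0.09).entries
        assert m[MAINTENANCE].tolist() == [1.0, 0.0, 0.0]

    def test_base_case_products(self):
        # p_loss = 2.16 x 0.003, split by the no-rehabilitation probability
        m = build_transition_matrix(0.00648, 0.09).entries
        assert m[MAINTENANCE] == pytest.approx([0.99352, 0.0005832, 0.0058968], abs=1e-15)
        assert m.sum(axis=1) == pytest.approx([1.0, 1.0, 1.0], abs=1e-15)

    def test_certain_loss_never_rehabilitated(self):
        m = build_transition_matrix(1.0, 1.0).entries
        assert m[MAINTENANCE].tolist() == [0.0, 1.0, 0.0]

    def test_lost_states_absorbing(self):
        m = build_transition_matrix(0.3, 0.5).entries
        assert m[LOST_NO_REHAB].tolist() == [0.0, 1.0, 0.0]
        assert m[LOST_REHAB].tolist() == [0.0, 0.0, 1.0]

    def test_invalid_probabilities_rejected(self):
        with pytest.raises(ValueError):
            build_transition_matrix(1.2, 0.09)
        with pytest.raises(ValueError):
            build_transition_matrix(0.5, -0.1)

    def test_non_absorbing_rows_rejected(self):
        bad = np.array([[0.9, 0.05, 0.05], [0.1, 0.9, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(ValueError, match="absorbing"):
            TransitionMatrix(bad)

    def test_stratum_combinations(self):
        for status, arm in itertools.product(("FORMER", "CURRENT"), ("SCT", "NO_SCT")):
            Stratum(status, arm)
        with pytest.raises(ValueError):
            Stratum("NEVER", "SCT")


class TestDiscounting:
    @pytest.mark.parametrize(
        "rate, t, expected",
        [(0.05, 0, 1.0), (0.0, 17, 1.0), (0.05, 2, 1 / 1.1025)],
    )
    def test_values(self, rate, t, expected):
        assert discount_factor(rate, t) == pytest.approx(expected, abs=1e-12)

    def test_rate_floor(self):
        with pytest.raises(ValueError):
            discount_factor(-1.0, 1)


def _rewards(upfront=0.0, per_cycle_cost=0.0, event_nr=0.0, event_r=0.0,
             u_maint=0.93, u_first=0.86, u_nr=0.61, u_r=0.69):
    return RewardSpec(
        upfront_cost=upfront,
        per_cycle_cost=np.full(3, per_cycle_cost),
        per_event_cost=np.array([0.0, event_nr, event_r]),
        per_cycle_utility=np.array([u_maint, u_nr, u_r]),
        first_cycle_maintenance_utility=u_first,
        per_cycle_effect=np.array([1.0, 0.0, 0.0]),
    )


class TestCohortTrace:
    def test_annuity_no_discounting(self):
        m = build_transition_matrix(0.0, 0.09)
        trace = run_cohort_trace(m, _rewards(upfront=50.0, per_cycle_cost=100.0), 10, 0.0)
        assert trace.expected_cost == pytest.approx(50.0 + 100.0 * 10, abs=1e-9)
        assert trace.expected_effect == pytest.approx(10.0, abs=1e-12)

    @pytest.mark.parametrize("rate", [0.0, 0.03, 0.05, 0.07])
    def test_annuity_closed_form(self, rate):
        # with p_loss = 0 the cost is upfront + c * sum of discount factors
        m = build_transition_matrix(0.0, 0.09)
        T, c, upfront = 3, 100.0, 40.0
        trace = run_cohort_trace(m, _rewards(upfront=upfront, per_cycle_cost=c), T, rate)
        annuity = sum((1 + rate) ** -t for t in range(1, T + 1))
        assert trace.expected_cost == pytest.approx(upfront + c * annuity, abs=1e-9)

    def test_annuity_worked_value(self):
        m = build_transition_matrix(0.0, 0.09)
        trace = run_cohort_trace(m, _rewards(upfront=7.0, per_cycle_cost=100.0), 3, 0.05)
        assert trace.expected_cost == pytest.approx(7.0 + 272.3248, abs=5e-5)

    def test_two_cycle_exhaustive_path_enumeration(self):
        # oracle: enumerate every 2-step path and accrue rewards by hand
        p_loss, p_nr, rate = 0.1, 0.09, 0.0
        rw = _rewards(upfront=20.0, per_cycle_cost=10.0, event_nr=34.31, event_r=349.92)
        m = build_transition_matrix(p_loss, p_nr)
        trace = run_cohort_trace(m, rw, 2, rate)

        paths = {  # (state after cycle 1, state after cycle 2): probability
            ("M", "M"): (1 - p_loss) * (1 - p_loss),
            ("M", "NR"): (1 - p_loss) * p_loss * p_nr,
            ("M", "R"): (1 - p_loss) * p_loss * (1 - p_nr),
            ("NR", "NR"): p_loss * p_nr,
            ("R", "R"): p_loss * (1 - p_nr),
        }
        assert sum(paths.values()) == pytest.approx(1.0, abs=1e-15)
        util = {"M": 0.93, "NR": 0.61, "R": 0.69}
        event = {"NR": 34.31, "R": 349.92}
        cost = rw.upfront_cost
        effect = 0.0
        qaly = 0.0
        for (s1, s2), prob in paths.items():
            c = 10.0 * 2  # per-cycle cost accrues in every state
            if s1 != "M":
                c += event[s1]
            elif s2 != "M":
                c += event[s2]
            cost += prob * c
            effect += prob * ((s1 == "M") + (s2 == "M"))
            qaly += prob * ((0.86 if s1 == "M" else util[s1]) + util[s2])
        assert trace.expected_cost == pytest.approx(cost, abs=1e-12)
        assert trace.expected_effect == pytest.approx(effect, abs=1e-12)
        assert trace.expected_qaly == pytest.approx(qaly, abs=1e-12)

    def test_zero_horizon_keeps_only_upfront(self):
        m = build_transition_matrix(0.1, 0.09)
        trace = run_cohort_trace(m, _rewards(upfront=5.0, per_cycle_cost=10.0), 0, 0.05)
        assert trace.expected_cost == 5.0
        assert trace.expected_effect == 0.0

    @settings(derandomize=True, deadline=None, max_examples=50)
    @given(
        p_loss=st.floats(min_value=0.0, max_value=1.0),
        p_nr=st.floats(min_value=0.0, max_value=1.0),
        rate=st.floats(min_value=0.0, max_value=0.2),
        T=st.integers(min_value=1, max_value=40),
    )
    def test_occupancy_conservation_and_absorption(self, p_loss, p_nr, rate, T):
        m = build_transition_matrix(p_loss, p_nr)
        trace = run_cohort_trace(m, _rewards(per_cycle_cost=1.0), T, rate)
        assert trace.occupancy.sum(axis=1) == pytest.approx(np.ones(T + 1), abs=1e-10)
        assert (trace.occupancy >= -1e-15).all()
        # cumulative loss equals the compounded multi-year probability
        if p_loss < 1.0:
            lost = trace.occupancy[T, LOST_NO_REHAB] + trace.occupancy[T, LOST_REHAB]
            assert lost == pytest.approx(annual_to_multi_year_prob(p_loss, T), abs=1e-12)

    def test_discount_monotonicity(self):
        m = build_transition_matrix(0.01, 0.09)
        rw = _rewards(per_cycle_cost=100.0, event_nr=30.0, event_r=300.0)
        totals = [
            run_cohort_trace(m, rw, 30, r).expected_cost for r in (0.0, 0.03, 0.07)
        ]
        assert totals[0] > totals[1] > totals[2]

    def test_half_cycle_correction_shrinks_gap_to_continuous(self):
        # hcc approximates mid-cycle accrual: totals sit between the
        # end-of-cycle value and its continuous-time counterpart
        m = build_transition_matrix(0.0, 0.09)
        rw = _rewards(per_cycle_cost=100.0)
        plain = run_cohort_trace(m, rw, 30, 0.05).expected_cost
        hcc = run_cohort_trace(m, rw, 30, 0.05, half_cycle_correction=True).expected_cost
        assert hcc == pytest.approx(plain * 1.05**0.5, rel=1e-12)

    def test_effects_can_be_left_undiscounted(self):
        m = build_transition_matrix(0.0, 0.09)
        rw = _rewards(per_cycle_cost=100.0)
        trace = run_cohort_trace(m, rw, 10, 0.05, discount_effects=False)
        assert trace.expected_effect == pytest.approx(10.0, abs=1e-12)
        assert trace.expected_cost < 100.0 * 10  # costs stay discounted


class TestArmRollback:
    def test_degenerate_quit_probability(self, base_inputs):
        # p_quit = 1 in the SCT arm collapses onto the FORMER stratum
        inputs = dataclasses.replace(base_inputs, p_quit_sct=1.0)
        arm = arm_expected_values(inputs, "SCT")
        former = run_stratum(inputs, "FORMER")
        upfront = inputs.cost_periodontal + inputs.cost_sct
        assert arm.expected_cost == pytest.approx(upfront + former.expected_cost, abs=1e-9)
        assert arm.expected_effect == pytest.approx(former.expected_effect, abs=1e-12)
        assert arm.expected_qaly == pytest.approx(former.expected_qaly, abs=1e-12)

    def test_comparators_collapse_without_quitting(self, base_inputs):
        inputs = dataclasses.replace(
            base_inputs, p_quit_sct=0.0, p_quit_no_sct=0.0, cost_sct=0.0
        )
        a = arm_expected_values(inputs, "SCT")
        b = arm_expected_values(inputs, "NO_SCT")
        assert a.expected_cost == pytest.approx(b.expected_cost, abs=1e-12)
        assert a.expected_effect == pytest.approx(b.expected_effect, abs=1e-12)

    def test_base_case_dominance_direction_at_zero_discount(self, base_inputs_r0):
        sct = arm_expected_values(base_inputs_r0, "SCT")
        nosct = arm_expected_values(base_inputs_r0, "NO_SCT")
        assert sct.expected_cost < nosct.expected_cost
        assert sct.expected_effect > nosct.expected_effect
        assert sct.expected_qaly > nosct.expected_qaly

    def test_qaly_and_effect_bounds(self, base_inputs):
        for arm in ("SCT", "NO_SCT"):
            res = arm_expected_values(base_inputs, arm)
            assert res.expected_qaly <= base_inputs.horizon_cycles * 0.93
            assert res.expected_effect <= base_inputs.horizon_cycles

    def test_accepts_full_parameter_set(self, basecase, base_inputs):
        assert arm_expected_values(basecase, "SCT") == arm_expected_values(
            base_inputs, "SCT"
        )

    def test_microsim_agreement_base_case(self, base_inputs):
        # cohort expectations within 4 SE of individual-level sample means
        for arm in ("SCT", "NO_SCT"):
            cohort = arm_expected_values(base_inputs, arm)
            micro = microsimulate_arm(base_inputs, arm, 50_000, seed=42)
            assert abs(cohort.expected_cost - micro.mean_cost) < 4 * micro.se_cost
            assert abs(cohort.expected_effect - micro.mean_effect) < 4 * micro.se_effect
            assert abs(cohort.expected_qaly - micro.mean_qaly) < 4 * micro.se_qaly
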