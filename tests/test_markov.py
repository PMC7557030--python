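"""Markov engine: transition structure, cohort propagation, accrual, ICER."""

import numpy as np
import pytest

from hlcea.markov import (
    ArmResult,
    CohortTrace,
    HealthState,
    accumulate_outcomes,
    build_transition_row,
    compute_icer,
    discount_factor,
    evaluate_arm,
    run_cohort,
)
from hlcea.parameters import ArmParameters, SharedParameters

from conftest import exponential_fit, random_arm, random_shared

S = HealthState


def make_arm(p_prog=0.08, q_cr=0.01, q_pr=0.05, p_rpa=0.12, q_sp=0.15, **kw):
    defaults = dict(
        name="toy",
        p_adverse_event=0.3,
        p_discontinuation=0.1,
        p_mortality_on_treatment=0.02,
        drug_cost=1000.0,
    )
    defaults.update(kw)
    return ArmParameters(
        fits={
            "progression_cr": exponential_fit(p_prog),
            "mortality_cr": exponential_fit(q_cr),
            "mortality_progression": exponential_fit(q_pr),
            "progression_post_asct": exponential_fit(p_rpa),
            "mortality_second_progression": exponential_fit(q_sp),
        },
        **defaults,
    )


def make_shared(**kw):
    defaults = dict(
        p_asct_eligible=0.8,
        p_asct_success=0.5,
        cost_pet=1877.0,
        cost_adverse_event=12036.0,
        cost_asct=67723.0,
        cost_salvage=140800.0,
        u_treatment=0.71,
        u_complete_remission=0.91,
        u_adverse_event=0.59,
        u_progressive_disease=0.38,
    )
    defaults.update(kw)
    return SharedParameters(**defaults)


class TestTransitionRows:
    def test_death_is_absorbing(self):
        row = build_transition_row(S.DEATH, make_arm(), make_shared(), 5)
        assert np.array_equal(row, [0, 0, 0, 0, 0, 1])

    def test_zero_risk_treatment_sends_everyone_to_remission(self):
        arm = make_arm(p_prog=0.0, p_mortality_on_treatment=0.0, p_discontinuation=0.0)
        row = build_transition_row(S.TREATMENT, arm, make_shared(), 0)
        assert row[S.COMPLETE_REMISSION] == pytest.approx(1.0)

    def test_remission_competing_risks_death_first(self):
        """q = 0.05 then p = 0.1 on survivors: (1-q)(1-p), (1-q)p, q."""
        arm = make_arm(p_prog=0.1, q_cr=0.05)
        row = build_transition_row(S.COMPLETE_REMISSION, arm, make_shared(), 3)
        expected = np.zeros(6)
        expected[S.COMPLETE_REMISSION] = 0.95 * 0.9
        expected[S.PROGRESSION_RELAPSE] = 0.95 * 0.1
        expected[S.DEATH] = 0.05
        assert row == pytest.approx(expected)

    def test_relapse_state_resolves_via_transplant_triage(self):
        arm = make_arm(q_pr=0.05)
        row = build_transition_row(S.PROGRESSION_RELAPSE, arm, make_shared(), 0)
        assert row[S.REMISSION_POST_ASCT] == pytest.approx(0.95 * 0.4)
        assert row[S.SECOND_PROGRESSION] == pytest.approx(0.95 * 0.6)
        assert row[S.DEATH] == pytest.approx(0.05)

    @pytest.mark.parametrize("state", list(S))
    def test_rows_are_distributions_on_allowed_edges(self, state):
        allowed = {
            S.TREATMENT: {S.COMPLETE_REMISSION, S.PROGRESSION_RELAPSE, S.DEATH},
            S.COMPLETE_REMISSION: {
                S.COMPLETE_REMISSION, S.PROGRESSION_RELAPSE, S.DEATH,
            },
            S.PROGRESSION_RELAPSE: {
                S.PROGRESSION_RELAPSE, S.REMISSION_POST_ASCT,
                S.SECOND_PROGRESSION, S.DEATH,
            },
            S.REMISSION_POST_ASCT: {
                S.REMISSION_POST_ASCT, S.SECOND_PROGRESSION, S.DEATH,
            },
            S.SECOND_PROGRESSION: {S.SECOND_PROGRESSION, S.DEATH},
            S.DEATH: {S.DEATH},
        }
        rng = np.random.default_rng(17)
        for _ in range(20):
            row = build_transition_row(
                state, random_arm(rng), random_shared(rng), int(rng.integers(0, 30))
            )
            assert row.sum() == pytest.approx(1.0, abs=1e-12)
            for target in S:
                if target not in allowed[state]:
                    assert row[target] == 0.0


class TestCohortPropagation:
    def test_immediate_death_leaves_only_first_cycle_qalys(self):
        arm = make_arm(p_mortality_on_treatment=1.0)
        shared = make_shared()
        trace = run_cohort(arm, shared)
        assert np.all(trace.occupancy[1:, S.DEATH] == 1.0)
        assert trace.cycle_qaly[0] > 0
        assert np.all(trace.cycle_qaly[1:] == 0.0)

    def test_matches_matrix_power_oracle_for_constant_matrices(self):
        """With shape-1 fits every row is residence-free, so the collapsed
        process is an ordinary Markov chain: compare against plain repeated
        matrix-vector products."""
        arm, shared = make_arm(), make_shared()
        M = np.array([build_transition_row(s, arm, shared, 0) for s in S])
        v = np.zeros(6)
        v[S.TREATMENT] = 1.0
        trace = run_cohort(arm, shared)
        for m in range(shared.n_cycles + 1):
            assert np.max(np.abs(trace.occupancy[m] - v)) < 1e-12
            v = v @ M

    def test_occupancy_rows_sum_to_one_for_random_parameters(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            trace = run_cohort(random_arm(rng), random_shared(rng))
            assert np.max(np.abs(trace.occupancy.sum(axis=1) - 1.0)) < 1e-9

    def test_death_occupancy_never_decreases(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            trace = run_cohort(random_arm(rng), random_shared(rng))
            assert np.all(np.diff(trace.occupancy[:, S.DEATH]) >= -1e-12)

    def test_raising_mortality_never_raises_qalys(self):
        rng = np.random.default_rng(31)
        shared = make_shared()
        for _ in range(100):
            q = float(rng.uniform(0, 0.5))
            arm_lo = make_arm(p_mortality_on_treatment=q)
            arm_hi = make_arm(p_mortality_on_treatment=min(1.0, q + rng.uniform(0, 0.5)))
            assert (
                evaluate_arm(arm_hi, shared).qalys
                <= evaluate_arm(arm_lo, shared).qalys + 1e-12
            )


class TestDiscounting:
    def test_discount_factor_values(self):
        assert discount_factor(0.015, 0.0) == 1.0
        assert discount_factor(0.015, 1.0) == pytest.approx(1 / 1.015)
        assert discount_factor(0.0, 7.3) == 1.0

    def test_half_year_consistency(self):
        assert discount_factor(0.015, 1.0) == pytest.approx(
            discount_factor(0.015, 0.5) ** 2
        )

    def test_zero_rate_strictly_increases_totals(self):
        arm = make_arm()
        undisc = evaluate_arm(arm, make_shared(discount_rate=0.0))
        disc = evaluate_arm(arm, make_shared(discount_rate=0.015))
        assert undisc.cost > disc.cost
        assert undisc.qalys > disc.qalys


class TestAccrual:
    def _trace_all_in(self, state, n_cycles=30):
        occ = np.zeros((n_cycles + 1, 6))
        occ[:, state] = 1.0
        zeros = np.zeros(n_cycles + 1)
        return CohortTrace(occ, np.zeros_like(occ), zeros, zeros, zeros, zeros)

    def test_full_remission_undiscounted_qalys(self):
        """30 cycles fully in remission at utility 0.91: 30 x 0.5 x 0.91."""
        trace = self._trace_all_in(S.COMPLETE_REMISSION)
        res = accumulate_outcomes(
            trace, make_arm(drug_cost=0.0), make_shared(discount_rate=0.0)
        )
        assert res.qalys == pytest.approx(30 * 0.5 * 0.91)

    def test_all_dead_trace_accrues_nothing(self):
        trace = self._trace_all_in(S.DEATH)
        res = accumulate_outcomes(trace, make_arm(), make_shared())
        assert res.qalys == 0.0
        assert res.cost == 0.0  # no one on treatment at start, no entries

    def test_two_cycle_hand_computation(self):
        """Hand-built 2-cycle trace: spreadsheet-style accrual check."""
        occ = np.array([
            [1.0, 0.0, 0.0, 0.0, 0.0, 0.0],
            [0.0, 0.8, 0.1, 0.0, 0.0, 0.1],
            [0.0, 0.7, 0.0, 0.04, 0.07, 0.19],
        ])
        entries = np.zeros_like(occ)
        entries[1] = [0, 0.8, 0.1, 0, 0, 0.1]
        entries[2] = [0, 0, 0, 0.04, 0.07, 0.09]
        zeros = np.zeros(3)
        trace = CohortTrace(occ, entries, zeros, zeros, zeros, zeros)
        arm = make_arm(drug_cost=1000.0, p_adverse_event=0.3)
        shared = make_shared(
            discount_rate=0.0, cycle_length_months=6.0, horizon_years=1.0
        )
        res = accumulate_outcomes(trace, arm, shared)
        u_tx = 0.3 * 0.59 + 0.7 * 0.71
        exp_qaly = 0.5 * u_tx + 0.5 * (0.8 * 0.91 + 0.1 * 0.38)
        exp_cost = (
            1000.0 + 0.3 * 12036.0          # regimen + expected AE management
            + 1877.0                        # PET at end of cycle 1
            + 0.1 * 0.8 * 67723.0           # transplant for relapse entries
            + 0.07 * 140800.0               # salvage on second-progression entry
        )
        assert res.qalys == pytest.approx(exp_qaly)
        assert res.cost == pytest.approx(exp_cost)

    def test_half_cycle_correction_averages_occupancy(self):
        arm, shared = make_arm(), make_shared(half_cycle_correction=True)
        plain = evaluate_arm(arm, make_shared())
        corrected = evaluate_arm(arm, shared)
        # mortality means end-of-cycle occupancy is worse: HCC lowers QALYs
        assert corrected.qalys < plain.qalys


class TestICER:
    def test_published_reference_case_arithmetic(self):
        """Incremental cost/effect/ICER from the per-arm reference values."""
        res = compute_icer(ArmResult(218_854.0, 9.16), ArmResult(411_190.0, 9.62))
        assert res.delta_cost == pytest.approx(192_336.0)
        assert res.delta_qalys == pytest.approx(0.46)
        assert res.icer == pytest.approx(418_122.0, rel=1e-3)
        assert res.label == "icer"

    def test_dominance_labels(self):
        base = ArmResult(100.0, 1.0)
        assert compute_icer(base, ArmResult(99.0, 1.1)).label == "dominant"
        assert compute_icer(base, ArmResult(105.0, 0.9)).label == "dominated"
        sw = compute_icer(base, ArmResult(90.0, 0.9))
        assert sw.label == "southwest"
        assert sw.icer == pytest.approx(100.0)

    def test_zero_effect_increment_is_undefined(self):
        res = compute_icer(ArmResult(100.0, 1.0), ArmResult(105.0, 1.0))
        assert res.label == "undefined"
        assert res.icer is None
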