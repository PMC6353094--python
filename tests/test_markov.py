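"""Cohort engine: matrices, discounting, accrual conventions, microsim oracle."""
import numpy as np
import pytest

from endopain import (
    LifeTable,
    build_matrix,
    discount_factor,
    make_arm_parameters,
    microsim_oracle,
    run_cohort,
)


def variant(ps, *, discount=None, initial=None, life=None, hcc=None):
    """Copy of the default parameter set with selected settings replaced."""
    model_updates = {}
    if discount is not None:
        model_updates["annual_discount_rate"] = discount
    if initial is not None:
        model_updates["initial_distribution"] = initial
    if hcc is not None:
        model_updates["half_cycle_correction"] = hcc
    updates = {}
    if model_updates:
        updates["model"] = ps.model.model_copy(update=model_updates)
    if life is not None:
        updates["life_table"] = life
    return ps.model_copy(update=updates)


def zero_life(ps):
    ages = tuple(range(ps.model.start_age, ps.model.end_age + 1))
    return LifeTable(ages=ages, q_annual=tuple(0.0 for _ in ages))


ALL_SEVERE = {"no_pain": 0.0, "mild": 0.0, "moderate": 0.0, "severe": 1.0}
ALL_NO_PAIN = {"no_pain": 1.0, "mild": 0.0, "moderate": 0.0, "severe": 0.0}
ALL_MILD = {"no_pain": 0.0, "mild": 1.0, "moderate": 0.0, "severe": 0.0}


class TestTransitionMatrix:
    def test_nht_no_pain_row_without_mortality(self, ps):
        M = build_matrix(make_arm_parameters(ps, "nht"), 0.0)
        np.testing.assert_allclose(M[0], [0.997, 0.003, 0.0, 0.0, 0.0])

    def test_oc_severe_row_without_mortality(self, ps):
        M = build_matrix(make_arm_parameters(ps, "oc"), 0.0)
        np.testing.assert_allclose(M[3], [0.0, 0.0, 0.004, 0.996, 0.0])

    def test_certain_death_sends_all_alive_mass_to_dead(self, ps):
        M = build_matrix(make_arm_parameters(ps, "nht"), 1.0)
        np.testing.assert_allclose(M[:4, 4], 1.0)
        np.testing.assert_allclose(M[:4, :4], 0.0)

    def test_dead_row_is_absorbing_and_rows_stochastic(self, ps):
        M = build_matrix(make_arm_parameters(ps, "oc"), 0.0013)
        np.testing.assert_allclose(M[4], [0, 0, 0, 0, 1.0])
        np.testing.assert_allclose(M.sum(axis=1), 1.0, atol=1e-12)
        assert ((M >= 0) & (M <= 1)).all()


class TestDiscounting:
    def test_closed_forms(self):
        assert discount_factor(0, 0.035) == 1.0
        assert discount_factor(12, 0.035) == pytest.approx(1 / 1.035)
        assert discount_factor(123, 0.0) == 1.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            discount_factor(12, -0.01)


class TestCohortClosedForms:
    def test_all_severe_static_cohort_qalys(self, ps):
        """No transitions, mortality or discounting: 18 years at utility 0.573."""
        v = variant(ps, discount=0.0, initial=ALL_SEVERE, life=zero_life(ps))
        params = make_arm_parameters(v, "nht", alive_matrix=np.eye(4))
        _, res = run_cohort(v.model, params, v.life_table)
        assert res.qalys == pytest.approx(18 * 0.573, rel=1e-12)

    def test_pain_free_cohort_incurs_no_treatment_cost(self, ps):
        """Treatment costs accrue only in pain states, so a cohort that never
        leaves 'no pain' costs nothing in either arm."""
        v = variant(ps, discount=0.0, initial=ALL_NO_PAIN, life=zero_life(ps))
        for arm in ("nht", "oc"):
            params = make_arm_parameters(v, arm, alive_matrix=np.eye(4))
            _, res = run_cohort(v.model, params, v.life_table)
            assert res.cost == 0.0

    def test_all_mild_static_nht_cost(self, ps):
        """Mild state: amortised GP (26.67/3) plus half-max paracetamol (2.31)."""
        v = variant(ps, discount=0.0, initial=ALL_MILD, life=zero_life(ps))
        params = make_arm_parameters(v, "nht", alive_matrix=np.eye(4))
        _, res = run_cohort(v.model, params, v.life_table)
        assert res.cost == pytest.approx(216 * (26.67 / 3 + 2.31), rel=1e-12)

    def test_oc_drug_cost_spread_over_pack_cycles(self, ps):
        v = variant(ps, discount=0.0, initial=ALL_MILD, life=zero_life(ps))
        params = make_arm_parameters(v, "oc", alive_matrix=np.eye(4))
        _, res = run_cohort(v.model, params, v.life_table)
        expected = 216 * (26.67 / 6 + 2.82 / 3 + 2.31)
        assert res.cost == pytest.approx(expected, rel=1e-12)


class TestTraceInvariants:
    @pytest.mark.parametrize("arm", ["nht", "oc"])
    def test_occupancy_conservation_and_monotone_death(self, ps, arm):
        trace, _ = run_cohort(ps.model, make_arm_parameters(ps, arm), ps.life_table)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)
        dead = trace.occupancy[:, 4]
        assert (np.diff(dead) >= -1e-15).all()

    def test_alive_mass_is_survival_product(self, ps):
        """Pain transitions conserve alive mass, so alive fraction at cycle t
        equals the product of monthly survival probabilities."""
        trace, _ = run_cohort(ps.model, make_arm_parameters(ps, "nht"), ps.life_table)
        q_m = np.array(
            [ps.life_table.monthly_q(int(a)) for a in trace.ages]
        )
        survival = np.cumprod(1 - q_m)
        np.testing.assert_allclose(
            trace.occupancy[1:, :4].sum(axis=1), survival, atol=1e-12
        )

    def test_discounted_not_above_undiscounted(self, ps):
        for arm in ("nht", "oc"):
            _, res = run_cohort(ps.model, make_arm_parameters(ps, arm), ps.life_table)
            assert res.cost <= res.cost_undiscounted
            assert res.qalys <= res.qalys_undiscounted

    def test_half_cycle_correction_between_endpoint_conventions(self, ps):
        """Trapezoid accrual lies between start- and end-of-cycle accrual."""
        trace, res = run_cohort(ps.model, make_arm_parameters(ps, "nht"), ps.life_table)
        u = make_arm_parameters(ps, "nht").utilities / 12.0
        start = (trace.occupancy[:-1, :4] @ u) @ trace.discount
        end = (trace.occupancy[1:, :4] @ u) @ trace.discount
        assert min(start, end) <= res.qalys <= max(start, end)


class TestMonotonicity:
    def test_higher_utility_weakly_increases_qalys(self, ps):
        base = make_arm_parameters(ps, "nht")
        bumped = make_arm_parameters(
            ps, "nht", utilities=base.utilities + np.array([0, 0.05, 0, 0])
        )
        _, r0 = run_cohort(ps.model, base, ps.life_table)
        _, r1 = run_cohort(ps.model, bumped, ps.life_table)
        assert r1.qalys >= r0.qalys

    def test_higher_discount_rate_decreases_totals(self, ps):
        v = variant(ps, discount=0.07)
        _, r0 = run_cohort(ps.model, make_arm_parameters(ps, "nht"), ps.life_table)
        _, r1 = run_cohort(v.model, make_arm_parameters(v, "nht"), v.life_table)
        assert r1.qalys < r0.qalys and r1.cost < r0.cost


class TestMicrosimOracle:
    def test_static_severe_cohort_is_deterministic(self, ps):
        v = variant(ps, discount=0.0, initial=ALL_SEVERE, life=zero_life(ps))
        params = make_arm_parameters(v, "nht", alive_matrix=np.eye(4))
        res = microsim_oracle(v.model, params, v.life_table, n_patients=100, seed=0)
        assert res.qalys == pytest.approx(18 * 0.573, rel=1e-12)
        assert res.qalys_se == 0.0

    def test_seed_gives_bit_identical_reruns(self, ps):
        params = make_arm_parameters(ps, "oc")
        a = microsim_oracle(ps.model, params, ps.life_table, 2000, seed=42)
        b = microsim_oracle(ps.model, params, ps.life_table, 2000, seed=42)
        assert (a.cost, a.qalys) == (b.cost, b.qalys)

    @pytest.mark.parametrize("arm", ["nht", "oc"])
    def test_cohort_totals_within_monte_carlo_error(self, ps, arm):
        params = make_arm_parameters(ps, arm)
        _, cohort = run_cohort(ps.model, params, ps.life_table)
        sim = microsim_oracle(ps.model, params, ps.life_table, 30_000, seed=7)
        assert abs(cohort.cost - sim.cost) < 3.5 * sim.cost_se
        assert abs(cohort.qalys - sim.qalys) < 3.5 * sim.qalys_se

    def test_lumped_gp_agreement(self, ps):
        v = ps.model_copy(update={"costs": ps.costs.model_copy(update={"gp_lumped": True})})
        params = make_arm_parameters(v, "nht")
        _, cohort = run_cohort(v.model, params, v.life_table)
        sim = microsim_oracle(v.model, params, v.life_table, 30_000, seed=11)
        assert abs(cohort.cost - sim.cost) < 3.5 * sim.cost_se
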