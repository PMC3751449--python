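"""Cohort engine: transitions, rewards, lifetime runs and weighting."""

import dataclasses

import numpy as np
import pytest

import quitcea as qc
from quitcea.markov_engine import Arm, CohortState
from quitcea.params_io import ValidationError

from conftest import base_config, flat_epi_frame, make_epi


def make_inputs(epi, **overrides):
    cfg = base_config()
    cfg.update(overrides)
    return qc.load_parameters(cfg, epi)


def zero_mortality_inputs(ages, horizon, prev=0.0, **overrides):
    epi = make_epi(flat_epi_frame(list(ages), m_gen=0.0, prev=prev))
    return make_inputs(
        epi,
        start_ages=[ages[0]],
        age_weights=[1.0],
        horizon_age=float(horizon),
        **overrides,
    )


class TestQuitSchedule:
    def test_first_cycle_intervention(self, base_inputs):
        p = qc.quit_prob_schedule(Arm.INTERVENTION, 1, base_inputs.quit)
        assert p == pytest.approx(0.1078, abs=1e-10)

    def test_first_cycle_control(self, base_inputs):
        assert qc.quit_prob_schedule(Arm.CONTROL, 1, base_inputs.quit) == 0.049

    @pytest.mark.parametrize("arm", [Arm.CONTROL, Arm.INTERVENTION])
    def test_background_rate_thereafter(self, base_inputs, arm):
        p = qc.quit_prob_schedule(arm, 5, base_inputs.quit)
        assert p == pytest.approx(0.0100505, abs=1e-7)


class TestCycleTransition:
    def test_all_dead_is_absorbing(self):
        state = CohortState(0, 0, 0, 1.0)
        out = qc.cycle_transition(state, (0.1, 0.1), 0.5, (0.21, 0.30))
        assert out == CohortState(0, 0, 0, 1.0)

    def test_first_cycle_quitting(self):
        out = qc.cycle_transition(
            CohortState(1.0, 0, 0, 0), (0.0, 0.0), 0.1078, (0.21, 0.30)
        )
        assert out.smoker == pytest.approx(0.8922)
        assert out.former_recent == pytest.approx(0.1078)
        assert out.former_long == 0.0

    def test_relapse_arithmetic(self):
        """21% of recent quitters relapse; survivors advance."""
        out = qc.cycle_transition(
            CohortState(0.0, 0.1078, 0.0, 0.0), (0.0, 0.0), 0.0, (0.21, 0.0)
        )
        assert out.smoker == pytest.approx(0.1078 * 0.21, abs=1e-10)
        assert out.former_long == pytest.approx(0.1078 * 0.79, abs=1e-10)

    def test_one_off_lifetime_relapse_compounds(self):
        out = qc.cycle_transition(
            CohortState(0.0, 1.0, 0.0, 0.0), (0.0, 0.0), 0.0, (0.21, 0.30)
        )
        assert out.former_long == pytest.approx(0.79 * 0.70, abs=1e-12)
        assert out.smoker == pytest.approx(1 - 0.79 * 0.70, abs=1e-12)

    def test_occupancy_conserved_with_mortality(self):
        state = CohortState(0.5, 0.2, 0.2, 0.1)
        out = qc.cycle_transition(state, (0.03, 0.02), 0.05, (0.21, 0.30))
        assert out.total == pytest.approx(1.0, abs=1e-12)
        assert out.dead >= state.dead


class TestCycleRewards:
    @staticmethod
    def _rates(q_s=None, q_f=None):
        from quitcea.epi_derivation import AgeRates

        zero = {d: 0.0 for d in qc.DISEASES}
        return AgeRates(0.0, 0.0, q_s or dict(zero), q_f or dict(zero))

    def test_all_dead_earns_nothing(self, base_inputs):
        c, ly, qaly = qc.cycle_rewards(
            CohortState(0, 0, 0, 1.0), self._rates(), base_inputs.utilities,
            base_inputs.costs, 1, base_inputs.econ,
        )
        assert (c, ly, qaly) == (0.0, 0.0, 0.0)

    def test_disease_free_smoker_half_year(self, base_inputs):
        c, ly, qaly = qc.cycle_rewards(
            CohortState(1.0, 0, 0, 0), self._rates(), base_inputs.utilities,
            base_inputs.costs, 1, base_inputs.econ,
        )
        assert c == 0.0
        assert ly == pytest.approx(0.5)
        assert qaly == pytest.approx(0.375)  # 0.5 * 0.75, discount factor 1 at t=1

    def test_lung_cancer_event_cost_and_utility(self, base_inputs):
        q_s = {d: 0.0 for d in qc.DISEASES}
        q_s["lung_cancer"] = 0.01
        c, ly, qaly = qc.cycle_rewards(
            CohortState(1.0, 0, 0, 0), self._rates(q_s=q_s), base_inputs.utilities,
            base_inputs.costs, 1, base_inputs.econ,
        )
        assert c == pytest.approx(0.01 * 0.5 * 5921, abs=1e-9)
        assert qaly == pytest.approx(0.5 * (0.99 * 0.75 + 0.01 * 0.58), abs=1e-12)

    def test_discounting_indexed_at_cycle_start(self, base_inputs):
        state = CohortState(1.0, 0, 0, 0)
        args = (state, self._rates(), base_inputs.utilities, base_inputs.costs)
        _, ly1, _ = qc.cycle_rewards(*args, 1, base_inputs.econ)
        _, ly3, _ = qc.cycle_rewards(*args, 3, base_inputs.econ)
        assert ly3 / ly1 == pytest.approx(1.035 ** -1.0, abs=1e-12)

    def test_disease_probabilities_summing_above_one_rejected(self, base_inputs):
        q_s = {d: 0.3 for d in qc.DISEASES}
        with pytest.raises(ValidationError, match="smoker"):
            qc.cycle_rewards(
                CohortState(1.0, 0, 0, 0), self._rates(q_s=q_s),
                base_inputs.utilities, base_inputs.costs, 1, base_inputs.econ,
            )


class TestRunCohort:
    def test_zero_mortality_zero_discount_ly_closed_form(self):
        inputs = zero_mortality_inputs(
            range(30, 32), 31,
            discount_rate_cost=0.0, discount_rate_effect=0.0,
            control_quit_6m=0.0, rr_quit=1.0, rr_quit_ci_low=1.0,
            rr_quit_ci_high=1.0, background_quit_annual=0.0,
        )
        _, out = qc.run_cohort(inputs, Arm.CONTROL, 30, "male")
        assert out.life_years == pytest.approx(1000.0, abs=1e-9)  # 1 LY per person

    def test_certain_death_first_cycle(self):
        epi = make_epi(flat_epi_frame(range(30, 32), m_gen=1.0, prev=0.0, rr_death=(1.0, 1.0)))
        inputs = make_inputs(epi, start_ages=[30], age_weights=[1.0], horizon_age=31.0)
        _, out = qc.run_cohort(inputs, Arm.INTERVENTION, 30, "male")
        assert out.life_years == pytest.approx(500.0)
        assert out.total_cost == pytest.approx(16.12 * 1000)

    def test_quitters_6m_equals_first_cycle_quit_prob(self, base_inputs):
        """At age 24 the 6-month mortality mass is tiny, so the quitter count
        matches the schedule to that tolerance."""
        traj, out = qc.run_cohort(base_inputs, Arm.INTERVENTION, 24, "male")
        m6 = qc.derive_status_rates(base_inputs.epi).at(24, "male").m_smoker
        assert out.quitters_6m / 1000 == pytest.approx(0.1078, abs=m6)
        assert traj.quit_6m == pytest.approx(0.1078 * (1 - m6), abs=1e-12)

    def test_geometric_series_discounting(self):
        """Flat rewards: discounted LY total equals the closed form."""
        inputs = zero_mortality_inputs(
            range(40, 45), 44,
            control_quit_6m=0.0, rr_quit=1.0, rr_quit_ci_low=1.0,
            rr_quit_ci_high=1.0, background_quit_annual=0.0,
        )
        _, out = qc.run_cohort(inputs, Arm.CONTROL, 40, "female")
        v = 1.035 ** -0.5
        n = 8  # cycles
        expected = 0.5 * (1 - v**n) / (1 - v)
        assert out.life_years / 1000 == pytest.approx(expected, abs=1e-12)
        assert out.life_years_undisc / 1000 == pytest.approx(0.5 * n, abs=1e-12)

    def test_zero_discount_equates_discounted_and_undiscounted(self, default_epi):
        inputs = make_inputs(
            default_epi, discount_rate_cost=0.0, discount_rate_effect=0.0
        )
        _, out = qc.run_cohort(inputs, Arm.INTERVENTION, 35, "female")
        assert out.total_cost == pytest.approx(out.total_cost_undisc, rel=1e-12)
        assert out.life_years == pytest.approx(out.life_years_undisc, rel=1e-12)
        assert out.qalys == pytest.approx(out.qalys_undisc, rel=1e-12)

    def test_conservation_and_monotone_death_every_cycle(self, base_inputs):
        for arm in (Arm.CONTROL, Arm.INTERVENTION):
            for stratum in base_inputs.mix:
                traj, _ = qc.run_cohort(
                    base_inputs, arm, stratum.start_age, stratum.gender
                )
                totals = np.array([s.total for s in traj.states])
                dead = np.array([s.dead for s in traj.states])
                assert np.abs(totals - 1.0).max() < 1e-12
                assert (np.diff(dead) >= -1e-15).all()
                # trajectory spans start age to horizon
                n_cycles = int((100 - stratum.start_age) * 2)
                assert len(traj.states) == n_cycles + 1

    def test_intervention_dominates_control(self, base_inputs):
        """More former smokers at every cycle, and at least as many QALYs."""
        ti, oi = qc.run_cohort(base_inputs, Arm.INTERVENTION, 35, "male")
        tc, oc = qc.run_cohort(base_inputs, Arm.CONTROL, 35, "male")
        fi = np.array([s.former for s in ti.states])
        fc = np.array([s.former for s in tc.states])
        assert (fi >= fc - 1e-12).all()
        assert oi.qalys >= oc.qalys
        assert oi.quitters_6m > oc.quitters_6m

    def test_spread_relapse_mode_matches_one_off_in_the_long_run(self, base_inputs):
        """Spreading the lifetime relapse over 10 years leaves the same
        survivor fraction, so late-cycle occupancy converges."""
        spread = dataclasses.replace(base_inputs, relapse_mode="spread")
        t1, _ = qc.run_cohort(base_inputs, Arm.INTERVENTION, 48, "male")
        t2, _ = qc.run_cohort(spread, Arm.INTERVENTION, 48, "male")
        late1 = t1.states[60].former
        late2 = t2.states[60].former
        assert late2 == pytest.approx(late1, rel=0.05)
        totals = np.array([s.total for s in t2.states])
        assert np.abs(totals - 1.0).max() < 1e-12

    def test_start_age_beyond_horizon_rejected(self, base_inputs):
        with pytest.raises(ValidationError):
            qc.run_cohort(base_inputs, Arm.CONTROL, 100, "male")


class TestRunWeighted:
    def test_single_stratum_mix_equals_cohort(self, default_epi):
        inputs = make_inputs(
            default_epi, start_ages=[35], age_weights=[1.0],
            male_weight=1.0, female_weight=0.0,
        )
        _, single = qc.run_cohort(inputs, Arm.INTERVENTION, 35, "male")
        weighted = qc.run_weighted(inputs, Arm.INTERVENTION)
        assert weighted.total_cost == pytest.approx(single.total_cost, rel=1e-12)
        assert weighted.qalys == pytest.approx(single.qalys, rel=1e-12)

    def test_two_strata_linear_combination(self, default_epi):
        inputs = make_inputs(
            default_epi, start_ages=[24, 48], age_weights=[0.3, 0.7],
            male_weight=1.0, female_weight=0.0,
        )
        _, a = qc.run_cohort(inputs, Arm.CONTROL, 24, "male")
        _, b = qc.run_cohort(inputs, Arm.CONTROL, 48, "male")
        w = qc.run_weighted(inputs, Arm.CONTROL)
        assert w.total_cost == pytest.approx(0.3 * a.total_cost + 0.7 * b.total_cost, rel=1e-12)
        assert w.life_years == pytest.approx(0.3 * a.life_years + 0.7 * b.life_years, rel=1e-12)
        assert w.quitters_6m == pytest.approx(0.3 * a.quitters_6m + 0.7 * b.quitters_6m, rel=1e-12)

    def test_weighted_equals_manual_six_strata_sum(self, base_inputs, base_arms):
        manual = 0.0
        for s in base_inputs.mix:
            _, o = qc.run_cohort(base_inputs, Arm.INTERVENTION, s.start_age, s.gender)
            manual += s.weight * o.qalys
        assert base_arms[0].qalys == pytest.approx(manual, rel=1e-12)
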