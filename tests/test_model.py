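"""Right-hand side, single-period integration and schedule chaining."""

import numpy as np
import pytest

from thyrotx import (
    DosingPeriod,
    DosingSchedule,
    PatientState,
    SimulationError,
    c_from_dose,
    hyperthyroid_state,
    rhs,
    simulate,
    simulate_schedule,
)
from thyrotx.model import ModelParameters

from conftest import random_positive_params


class TestRhs:
    def test_untreated_start_is_near_equilibrium(self, params, e0):
        """The rounded start (0, 36, 30, 25) sits on the untreated equilibrium
        for the serum compartments; the size equation amplifies the rounding
        of z by k5, so z is checked against the exact equilibrium instead."""
        d = rhs(e0, params, 0.0)
        assert abs(d[0]) < 0.05 and abs(d[1]) < 0.05 and abs(d[3]) < 0.05
        e1 = hyperthyroid_state(params)
        assert e0.as_array() == pytest.approx(e1.as_array(), rel=5e-4)
        # under the unit-growth-rate reading of the size equation all four
        # derivatives vanish to the printed rounding
        d_slow = rhs(e0, params.replace(k5=1.0), 0.0)
        assert np.max(np.abs(d_slow)) < 0.05

    def test_zero_at_exact_equilibrium(self, params):
        e1 = hyperthyroid_state(params)
        assert np.max(np.abs(rhs(e1.as_state(), params, 0.0))) < 1e-9

    def test_no_drug_no_input_means_no_drug_flux(self, params):
        state = PatientState(x=0.0, y=12.0, z=20.0, w=3.0)
        assert rhs(state, params, 0.0)[0] == 0.0

    def test_drug_balance_hand_computed(self, params):
        # s - k1*z*x/(ka+x) - k2*x at (10, 36, 30, 25), s=14.02:
        # 14.02 - 8.374e-3*30*10/10.358068 - 3.3271*10 = -19.4935
        d = rhs(PatientState(10.0, 36.0, 30.0, 25.0), params, 14.02)
        assert d[0] == pytest.approx(-19.4935, abs=5e-4)

    def test_rejects_bad_inputs(self, params):
        with pytest.raises(ValueError):
            PatientState(x=0.0, y=1.0, z=0.0, w=1.0)
        with pytest.raises(ValueError):
            rhs(PatientState(0.0, 1.0, 1.0, 1.0), params, -1.0)

    def test_tiny_negative_components_snap_to_zero(self):
        state = PatientState(x=-1e-12, y=-1e-10, z=1.0, w=-1e-9)
        assert state.x == 0.0 and state.y == 0.0 and state.w == 0.0
        with pytest.raises(ValueError):
            PatientState(x=-1e-6, y=1.0, z=1.0, w=1.0)


class TestSimulate:
    def test_untreated_patient_holds_steady_ten_days(self, params, e0):
        traj = simulate(e0, params, 0.0, 10.0)
        assert traj.final_state.as_array() == pytest.approx(e0.as_array(), rel=5e-3)

    def test_zero_duration_returns_single_point(self, params, e0):
        traj = simulate(e0, params, 0.0, 0.0)
        assert traj.times.shape == (1,)
        assert traj.final_state == e0

    def test_ninety_day_loading_course_overshoots_into_hypothyroidism(self, params):
        start = PatientState(10.0, 36.0, 30.0, 25.0)
        traj = simulate(start, params, c_from_dose(30, 90), 90.0)
        assert traj.final_state.y < 7.0

    def test_terminal_state_continuous_in_duration(self, params, e0):
        a = simulate(e0, params, 5.0, 30.0).final_state
        b = simulate(e0, params, 5.0, 30.0 + 1e-7).final_state
        assert a.as_array() == pytest.approx(b.as_array(), rel=1e-5)

    def test_solver_tolerance_refinement_is_converged(self, params):
        start = PatientState(10.0, 36.0, 30.0, 25.0)
        coarse = simulate(start, params, 14.02, 60.0).final_state.as_array()
        fine = simulate(start, params, 14.02, 60.0, rtol=5e-9, atol=5e-11).final_state.as_array()
        assert coarse == pytest.approx(fine, rel=1e-6)

    def test_forward_invariance_under_random_conditions(self):
        """Non-negativity of drug/hormone/antibody and positivity of size are
        preserved from random starts under random positive parameters."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = random_positive_params(rng, spread=3.0)
            state = PatientState(
                x=float(rng.uniform(0, 10)),
                y=float(rng.uniform(0, 50)),
                z=float(rng.uniform(1, 50)),
                w=float(rng.uniform(0, 30)),
            )
            s = float(rng.uniform(0, 20))
            traj = simulate(state, p, s, 20.0, rtol=1e-6, atol=1e-9)
            assert np.all(traj.values[:, [0, 1, 3]] >= 0.0)
            assert np.all(traj.z > 0.0)

    def test_perturbed_states_return_to_untreated_equilibrium(self, params):
        e1 = hyperthyroid_state(params)
        for sign in (+1, -1):
            start = PatientState.from_array(e1.as_array() * (1 + sign * 0.10))
            traj = simulate(start, params, 0.0, 400.0)
            assert traj.final_state.as_array() == pytest.approx(e1.as_array(), rel=1e-3)


class TestSimulateSchedule:
    def test_zero_duration_period_is_a_no_op(self, params, e0):
        sched = DosingSchedule(periods=(DosingPeriod(30.0, 0.0, 14.02),))
        traj = simulate_schedule(e0, params, sched)
        assert traj.times.shape == (1,)

    def test_empty_schedule_returns_single_point(self, params, e0):
        traj = simulate_schedule(e0, params, DosingSchedule())
        assert traj.times.shape == (1,)
        assert traj.final_state == e0

    def test_chained_periods_match_sequential_runs(self, params):
        start = PatientState(10.0, 36.0, 30.0, 25.0)
        sched = DosingSchedule(
            periods=(DosingPeriod.from_dose(30, 60), DosingPeriod.from_dose(10, 120))
        )
        chained = simulate_schedule(start, params, sched)
        first = simulate(start, params, sched.periods[0].c, 60.0)
        second = simulate(first.final_state, params, sched.periods[1].c, 120.0)
        assert chained.final_state.t == pytest.approx(180.0)
        assert chained.final_state.as_array() == pytest.approx(
            second.final_state.as_array(), rel=1e-12
        )

    def test_loading_plus_maintenance_controls_ft4(self, params):
        start = PatientState(10.0, 36.0, 30.0, 25.0)
        sched = DosingSchedule(
            periods=(DosingPeriod.from_dose(30, 60), DosingPeriod.from_dose(10, 120))
        )
        traj = simulate_schedule(start, params, sched)
        assert 7.0 <= traj.final_state.y <= 18.0

    def test_withdrawal_after_course_relapses(self, params):
        start = PatientState(10.0, 36.0, 30.0, 25.0)
        sched = DosingSchedule(
            periods=(
                DosingPeriod.from_dose(30, 60),
                DosingPeriod.from_dose(10, 120),
                DosingPeriod(0.0, 180.0, 0.001),
            )
        )
        traj = simulate_schedule(start, params, sched)
        after = traj.y[traj.times > 180.0]
        assert np.max(after) > 18.0
        first_day = traj.times[traj.times > 180.0][np.argmax(after > 18.0)]
        assert first_day < 360.0


class TestTrajectory:
    def test_sampling_requires_requested_days(self, params, e0):
        traj = simulate(e0, params, 0.0, 10.0, extra_times=[2.5])
        assert traj.sample([2.5]).shape == (1, 4)
        with pytest.raises(ValueError, match="not sampled"):
            traj.sample([3.7])

    def test_strictly_increasing_times_enforced(self):
        with pytest.raises(ValueError):
            from thyrotx.model import Trajectory

            Trajectory(times=np.array([0.0, 0.0]), values=np.ones((2, 4)))

    def test_failure_reports_simulation_error(self, params, e0):
        with pytest.raises((SimulationError, ValueError)):
            simulate(e0, params, -1.0, 10.0)


def test_parameters_require_positivity():
    with pytest.raises(ValueError):
        ModelParameters(k5=0.0)
    with pytest.raises(ValueError):
        ModelParameters.from_dict({"bogus": 1.0})
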