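"""Tests of the compound-trapping kinetic model against independent oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from p53trap.kinetics import (
    HOUR,
    MINUTE,
    KineticParameters,
    KineticsError,
    Trajectory,
    accumulation_fold,
    calibrate_production_rate,
    derivatives,
    simulate,
    steady_state_closed_form,
    sweep_halflife_dose,
)

LN2 = math.log(2.0)


def reference_derivatives(state, p):
    """Independent re-implementation of the four rate equations, term by term."""
    M_A, M_B, P, MP = state
    dM_A = 0.0
    dM_B = (-p.k_diff * M_B) + (p.k_diff * M_A) + (-p.k_bind * M_B * P) + (p.k_unbind * MP)
    dMP = (p.k_bind * M_B * P) + (-p.k_unbind * MP) + (-MP * LN2 / p.t_half)
    dP = (
        (-p.k_bind * M_B * P)
        + (p.k_unbind * MP)
        + (-P * LN2 / p.t_half)
        + p.r_prod
    )
    return np.array([dM_A, dM_B, dP, dMP])


class TestCalibration:
    def test_printed_inputs(self):
        # 1 uM pool with 24 h half-life needs ~8.0225e-12 M/s production
        rate = calibrate_production_rate(1e-6, 24 * HOUR)
        assert rate == pytest.approx(1e-6 * LN2 / 86400, rel=1e-12)
        assert rate == pytest.approx(8.0225e-12, rel=1e-4)

    def test_zero_protein_zero_production(self):
        assert calibrate_production_rate(0.0, 24 * HOUR) == 0.0

    def test_rate_inverse_in_halflife(self):
        assert calibrate_production_rate(1e-6, 48 * HOUR) == pytest.approx(
            calibrate_production_rate(1e-6, 24 * HOUR) / 2
        )

    def test_nonpositive_halflife_rejected(self):
        with pytest.raises(KineticsError):
            calibrate_production_rate(1e-6, 0.0)

    def test_default_params_use_reference_calibration(self):
        p = KineticParameters()
        assert p.r_prod == pytest.approx(calibrate_production_rate(1e-6, 24 * HOUR))


class TestDerivatives:
    def test_all_zero_state_without_production(self):
        p = KineticParameters(r_prod=0.0)
        assert np.all(derivatives([0, 0, 0, 0], p) == 0)

    def test_extracellular_compartment_is_constant(self):
        p = KineticParameters()
        for state in ([1e-9, 1e-9, 1e-6, 0], [1e-7, 1e-8, 1e-6, 1e-7]):
            assert derivatives(state, p)[0] == 0.0

    @pytest.mark.parametrize(
        "state",
        [
            (1e-9, 1e-9, 1e-6, 0.0),
            (1e-10, 5e-11, 3e-7, 2e-7),
            (0.0, 0.0, 1e-6, 0.0),
        ],
    )
    def test_matches_independent_evaluation(self, state):
        p = KineticParameters(t_half=17 * HOUR)
        np.testing.assert_allclose(
            derivatives(state, p), reference_derivatives(state, p), rtol=1e-14
        )


class TestSimulate:
    def test_no_compound_protein_relaxes_to_balance(self):
        p = KineticParameters(M_A0=0.0, t_half=17 * HOUR)
        traj = simulate(p)
        assert np.all(traj.states[:, 1] < 1e-15)  # M_B never exceeds solver atol
        assert np.all(traj.states[:, 3] < 1e-15)  # MP never exceeds solver atol
        expected_P = p.r_prod * p.t_half / LN2
        assert traj.final_state[2] == pytest.approx(expected_P, rel=1e-6)

    def test_no_binding_no_trapping(self):
        p = KineticParameters(k_bind=0.0, M_A0=1e-9)
        traj = simulate(p)
        assert traj.final_state[1] == pytest.approx(1e-9, rel=1e-6)
        assert traj.final_state[3] == 0.0
        assert accumulation_fold(traj) == pytest.approx(1.0, rel=1e-6)

    def test_initial_state_and_constant_reservoir(self):
        p = KineticParameters(t_half=17 * HOUR, M_A0=1e-10)
        traj = simulate(p)
        np.testing.assert_array_equal(traj.states[0], p.initial_state())
        np.testing.assert_allclose(traj.states[:, 0], p.M_A0, rtol=1e-9)
        assert np.all(np.diff(traj.times) > 0)

    def test_endpoint_matches_closed_form(self):
        p = KineticParameters(t_half=17 * HOUR, M_A0=1e-10)
        final = simulate(p).final_state
        expected = steady_state_closed_form(p)
        np.testing.assert_allclose(final, expected, rtol=1e-3)

    def test_nonnegative_throughout(self):
        p = KineticParameters(t_half=16 * MINUTE, M_A0=1e-7)
        assert np.all(simulate(p).states >= 0)

    def test_residual_derivatives_vanish_at_endpoint(self):
        p = KineticParameters(t_half=1 * HOUR, M_A0=1e-9)
        traj = simulate(p)
        resid = derivatives(traj.final_state, p)[1:]
        scale = max(p.r_prod, p.k_diff * p.M_A0)
        assert np.all(np.abs(resid) < 1e-5 * scale)

    def test_invalid_t_end_rejected(self):
        with pytest.raises(KineticsError):
            simulate(KineticParameters(), t_end=-1.0)


class TestClosedForm:
    def test_no_compound(self):
        p = KineticParameters(M_A0=0.0, t_half=17 * HOUR)
        np.testing.assert_allclose(
            steady_state_closed_form(p),
            [0.0, 0.0, p.r_prod * p.t_half / LN2, 0.0],
        )

    def test_no_binding_diffusion_equilibrium(self):
        p = KineticParameters(k_bind=0.0, M_A0=1e-9, t_half=17 * HOUR)
        np.testing.assert_allclose(
            steady_state_closed_form(p),
            [1e-9, 1e-9, p.r_prod * p.t_half / LN2, 0.0],
        )

    @pytest.mark.parametrize("t_half", [16 * MINUTE, 17 * HOUR])
    def test_cross_oracle_with_integration(self, t_half):
        p = KineticParameters(t_half=t_half, M_A0=1e-10)
        numeric = simulate(p).final_state
        analytic = steady_state_closed_form(p)
        np.testing.assert_allclose(numeric, analytic, rtol=1e-3)

    def test_derivatives_vanish_at_root(self):
        p = KineticParameters(t_half=3 * HOUR, M_A0=1e-8)
        state = steady_state_closed_form(p)
        resid = derivatives(state, p)[1:]
        scale = max(p.r_prod, p.k_diff * p.M_A0)
        assert np.all(np.abs(resid) < 1e-9 * scale)

    def test_reference_halflife_recovers_reference_pool(self):
        # with no compound, t_half = t_half_ref gives P(inf) = P_ss_ref
        p = KineticParameters(M_A0=0.0)
        assert steady_state_closed_form(p)[2] == pytest.approx(1e-6, rel=1e-12)


class TestAccumulation:
    def test_fold_matches_closed_form(self):
        p = KineticParameters(t_half=17 * HOUR, M_A0=1e-10)
        traj = simulate(p)
        ss = steady_state_closed_form(p)
        expected = (ss[1] + ss[3]) / ss[0]
        assert accumulation_fold(traj) == pytest.approx(expected, rel=1e-3)

    def test_longer_halflife_traps_more(self):
        folds = {}
        for t_half in (16 * MINUTE, 17 * HOUR):
            p = KineticParameters(t_half=t_half, M_A0=1e-10)
            folds[t_half] = accumulation_fold(simulate(p))
        assert folds[17 * HOUR] > folds[16 * MINUTE]

    def test_zero_reservoir_rejected(self):
        p = KineticParameters(M_A0=0.0)
        with pytest.raises(KineticsError):
            accumulation_fold(simulate(p))


class TestSweep:
    def test_single_cell_equals_simulate(self):
        p = KineticParameters()
        res = sweep_halflife_dose(p, [17 * HOUR], [1e-10])
        traj = simulate(p.with_(t_half=17 * HOUR, M_A0=1e-10))
        expected = traj.final_state[1] + traj.final_state[3]
        assert res.intracellular_final[0, 0] == pytest.approx(expected, rel=1e-9)
        assert res.accumulation_fold[0, 0] == pytest.approx(expected / 1e-10, rel=1e-9)

    def test_monotone_in_halflife_against_closed_form(self):
        p = KineticParameters()
        half_lives = [16 * MINUTE, 1 * HOUR, 17 * HOUR]
        doses = [1e-11, 1e-9, 1e-7]
        res = sweep_halflife_dose(p, half_lives, doses)
        assert np.all(np.diff(res.intracellular_final, axis=0) >= 0)
        # every cell agrees with the analytic steady state
        for i, th in enumerate(half_lives):
            for j, dose in enumerate(doses):
                ss = steady_state_closed_form(p.with_(t_half=th, M_A0=dose))
                assert res.intracellular_final[i, j] == pytest.approx(
                    ss[1] + ss[3], rel=1e-3
                )

    def test_empty_grid_rejected(self):
        with pytest.raises(KineticsError):
            sweep_halflife_dose(KineticParameters(), [], [1e-10])


class TestClosedFormProperties:
    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        log_t_half=st.floats(math.log10(10 * 60), math.log10(48 * 3600)),
        log_dose=st.floats(-11, -7),
    )
    def test_root_is_admissible_everywhere(self, log_t_half, log_dose):
        p = KineticParameters(t_half=10**log_t_half, M_A0=10**log_dose)
        M_A, M_B, P, MP = steady_state_closed_form(p)
        assert 0 <= MP <= p.r_prod * p.t_half / LN2 * (1 + 1e-9)
        assert M_B >= 0 and P >= 0 and M_A == p.M_A0
        # conservation: free + bound protein equals production/decay balance
        assert P + MP == pytest.approx(p.r_prod * p.t_half / LN2, rel=1e-9)


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(k_diff=-1.0), dict(t_half=0.0), dict(M_A0=-1e-9), dict(t_half_ref=-1.0)],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(KineticsError):
            KineticParameters(**kwargs)

    def test_trajectory_requires_increasing_times(self):
        p = KineticParameters()
        with pytest.raises(ValueError):
            Trajectory(
                times=np.array([0.0, 1.0, 1.0]),
                states=np.zeros((3, 4)),
                params=p,
            )
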