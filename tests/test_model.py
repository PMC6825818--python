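"""Core model: rate matrix, steady state, tracer simulation."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from vitakin import (
    ModelSpec,
    ModelValidationError,
    SteadyStateError,
    compartmental_matrix,
    simulate_tracer,
    solve_steady_state,
)
from vitakin.model import flux_imbalance

from conftest import random_spec, simple_spec

SCHEDULE = np.array([0.125, 5 / 24, 8 / 24, 0.5, 1, 2, 4, 7, 10, 14, 21, 28,
                     35, 42, 49, 56, 70, 84, 114, 144, 200, 260, 310, 365.0])


class TestCompartmentalMatrix:
    def test_all_zero_transfers_give_zero_matrix(self):
        A, comps = compartmental_matrix({(6, 5): 0.0, (5, 6): 0.0})
        assert np.all(A == 0)

    def test_two_pool_subsystem_matches_hand_algebra(self):
        A, comps = compartmental_matrix(
            {(6, 5): 2.0, (5, 6): 0.1, (10, 6): 0.01})
        assert comps == (5, 6)
        np.testing.assert_allclose(A, [[-2.0, 0.1], [2.0, -0.11]])

    def test_column_sums_equal_minus_losses(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            spec = random_spec(rng)
            t = spec.transfer_map()
            t[(4, 2)] = t.pop((4, 3))
            A, comps = compartmental_matrix(t)
            for k, c in enumerate(comps):
                loss = sum(v for (i, j), v in t.items()
                           if j == c and i in (0, 10))
                np.testing.assert_allclose(-A[:, k].sum(), loss, atol=1e-12)

    def test_negative_transfer_rejected(self):
        with pytest.raises(ModelValidationError):
            compartmental_matrix({(6, 5): -1.0})


class TestSteadyState:
    def test_closed_form_single_loss(self):
        ss = solve_steady_state(simple_spec(
            L={(2, 1): 3, (4, 3): 6, (5, 4): 1.5, (6, 5): 2, (7, 5): 0,
               (5, 6): 0.1, (5, 7): 0, (10, 6): 0.01}))
        np.testing.assert_allclose(ss.M[6], 54.5455, rtol=1e-5)
        np.testing.assert_allclose(ss.DR, 0.54545, rtol=1e-4)
        np.testing.assert_allclose(ss.intake_pred, 0.72727, rtol=1e-4)
        np.testing.assert_allclose(ss.TBS, ss.M[6] + ss.M[7])
        np.testing.assert_allclose(ss.days_of_stores, ss.TBS / ss.DR)

    def test_symmetric_exchange_pool7(self):
        ss = solve_steady_state(simple_spec(
            L={(2, 1): 3, (4, 3): 6, (5, 4): 1.5, (6, 5): 2, (7, 5): 0.7,
               (5, 6): 0.1, (5, 7): 0.7, (10, 6): 0.01}, M5=1.0))
        np.testing.assert_allclose(ss.M[7], 1.0)

    def test_absorption_identity(self):
        ss = solve_steady_state(simple_spec())
        np.testing.assert_allclose(ss.DR / ss.intake_pred, 0.75, rtol=1e-12)

    def test_flux_balance_on_random_specs(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            spec = random_spec(rng)
            ss = solve_steady_state(spec)
            for c, imbalance in flux_imbalance(spec, ss).items():
                assert abs(imbalance) <= 1e-9, (c, imbalance)

    def test_pool7_without_return_raises(self):
        with pytest.raises(SteadyStateError):
            solve_steady_state(simple_spec(
                L={(2, 1): 3, (4, 3): 6, (5, 4): 1.5, (6, 5): 2, (7, 5): 1,
                   (5, 6): 0.1, (5, 7): 0.0, (10, 6): 0.01}))

    def test_zero_loss_raises(self):
        with pytest.raises(SteadyStateError):
            solve_steady_state(simple_spec(
                L={(2, 1): 3, (4, 3): 6, (5, 4): 1.5, (6, 5): 2, (7, 5): 1,
                   (5, 6): 0.1, (5, 7): 0.5, (10, 6): 0.0}))

    def test_dual_and_single_loss_same_dr_same_tbs(self):
        # lumping the loss site leaves the steady state masses unchanged
        # when the per-pool balances are preserved
        single = simple_spec()
        ss_s = solve_steady_state(single)
        l107 = 0.3 * ss_s.DR / ss_s.M[7]
        l106 = 0.7 * ss_s.DR / ss_s.M[6]
        L = dict(single.L)
        L[(5, 6)] = single.M5 * L[(6, 5)] / ss_s.M[6] - l106
        L[(5, 7)] = single.M5 * L[(7, 5)] / ss_s.M[7] - l107
        L[(10, 6)] = l106
        L[(10, 7)] = l107
        dual = ModelSpec(L=L, DT3=single.DT3, M5=single.M5, U1=single.U1,
                         loss_sites="6+7")
        ss_d = solve_steady_state(dual)
        np.testing.assert_allclose(ss_d.TBS, ss_s.TBS, rtol=1e-9)
        np.testing.assert_allclose(ss_d.DR, ss_s.DR, rtol=1e-9)


class TestSimulateTracer:
    def test_fd_zero_at_time_zero(self):
        sol = simulate_tracer(simple_spec(), [0.0, 0.5])
        assert sol.fd_plasma[0] == 0.0
        assert sol.fd_plasma[1] > 0

    def test_mass_conservation(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            spec = random_spec(rng)
            sol = simulate_tracer(spec, SCHEDULE)
            np.testing.assert_allclose(sol.total_recovered(), 1.0, atol=1e-8)

    def test_fd_nonnegative_and_decays(self):
        sol = simulate_tracer(simple_spec(), [1.0, 3650.0])
        assert np.all(sol.fd_plasma >= 0)
        assert sol.fd_plasma[1] < 1e-3 * sol.fd_plasma[0]

    def test_two_compartment_reduction_matches_biexponential(self):
        # dose in plasma, exchange 5<->6 only, loss from 6: the solution is
        # the closed-form biexponential of the 2x2 matrix (quadratic roots)
        spec = simple_spec(
            L={(2, 1): 3, (4, 3): 6, (5, 4): 1.5, (6, 5): 2.0, (7, 5): 0.0,
               (5, 6): 0.1, (5, 7): 0.0, (10, 6): 0.01},
            DT3=0.0, M5=1.0)
        t = np.linspace(0.0, 80.0, 17)
        q5 = simulate_tracer(spec, t, dose_compartment=5).q[5]
        a, b, c, d = -2.0, 0.1, 2.0, -0.11
        tr, det = a + d, a * d - b * c
        lam1 = (tr + np.sqrt(tr ** 2 - 4 * det)) / 2
        lam2 = (tr - np.sqrt(tr ** 2 - 4 * det)) / 2
        # q5(t) = ((lam1 - d) e^{lam1 t} - (lam2 - d) e^{lam2 t})/(lam1-lam2)
        expected = ((lam1 - d) * np.exp(lam1 * t)
                    - (lam2 - d) * np.exp(lam2 * t)) / (lam1 - lam2)
        np.testing.assert_allclose(q5, expected, rtol=1e-10, atol=1e-13)

    def test_matches_adaptive_ode_integrator(self):
        # independent oracle: stiff-capable integration in two stages with
        # the delayed input interpolated from the upstream dense output
        rng = np.random.default_rng(19)
        for _ in range(10):
            spec = random_spec(rng)
            sol = simulate_tracer(spec, SCHEDULE)
            a = spec.absorption
            k1 = spec.l(2, 1) / a
            k2 = spec.l(4, 3)
            up = solve_ivp(
                lambda t, y: [-k1 * y[0], spec.l(2, 1) * y[0] - k2 * y[1]],
                (0, 370), [1.0, 0.0], dense_output=True,
                rtol=1e-11, atol=1e-14, method="LSODA")

            def down_rhs(t, y):
                q4, q5, q6, q7 = y
                u = k2 * up.sol(t - spec.DT3)[1] if t >= spec.DT3 else 0.0
                return [
                    u - spec.l(5, 4) * q4,
                    spec.l(5, 4) * q4 + spec.l(5, 6) * q6 + spec.l(5, 7) * q7
                    - (spec.l(6, 5) + spec.l(7, 5)) * q5,
                    spec.l(6, 5) * q5 - (spec.l(5, 6) + spec.l(10, 6)) * q6,
                    spec.l(7, 5) * q5 - spec.l(5, 7) * q7,
                ]

            # max_step keeps the integrator from stepping over the onset of
            # the delayed input while the state is still identically zero
            down = solve_ivp(down_rhs, (0, 370), [0.0] * 4,
                             t_eval=SCHEDULE, rtol=1e-11, atol=1e-14,
                             method="LSODA", max_step=1.0)
            np.testing.assert_allclose(sol.q[5], down.y[1], rtol=2e-6,
                                       atol=1e-12)

    def test_eig_and_expm_backends_agree(self):
        spec = simple_spec()
        f1 = simulate_tracer(spec, SCHEDULE, method="eig").fd_plasma
        f2 = simulate_tracer(spec, SCHEDULE, method="expm").fd_plasma
        np.testing.assert_allclose(f1, f2, rtol=1e-9)

    def test_erlang_delay_approximates_exact(self):
        spec = simple_spec()
        late = SCHEDULE[SCHEDULE >= 1.0]
        exact = simulate_tracer(spec, late).fd_plasma
        erl = simulate_tracer(spec, late, delay="erlang",
                              erlang_stages=100).fd_plasma
        np.testing.assert_allclose(erl, exact, rtol=2e-3)

    def test_delay_shifts_downstream_response(self):
        spec = simple_spec()
        base = simulate_tracer(simple_spec(DT3=0.0), [3.0]).q[5][0]
        shifted = simulate_tracer(spec, [3.0 + spec.DT3]).q[5][0]
        np.testing.assert_allclose(shifted, base, rtol=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ModelValidationError):
            simulate_tracer(simple_spec(), [-1.0])
        with pytest.raises(ModelValidationError):
            simulate_tracer(simple_spec(), [1.0], dose=0.0)
        with pytest.raises(ModelValidationError):
            ModelSpec(L={(2, 1): np.inf, (4, 3): 6, (5, 4): 1, (6, 5): 1,
                         (7, 5): 1, (5, 6): 0.1, (5, 7): 0.1, (10, 6): 0.01},
                      DT3=0.1, M5=1.0)


class TestSpecValidation:
    def test_missing_required_key(self):
        with pytest.raises(ModelValidationError, match="missing"):
            ModelSpec(L={(2, 1): 3.0}, DT3=0.1, M5=1.0)

    @pytest.mark.parametrize("field,value", [
        ("absorption", 0.0), ("absorption", 1.5), ("DT3", -0.1),
        ("M5", 0.0), ("U1", -1.0)])
    def test_invariant_violations(self, field, value):
        with pytest.raises(ModelValidationError):
            simple_spec(**{field: value})
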