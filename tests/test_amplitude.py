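"""Amplitude equations, their exactness, and the reduced descriptions."""

import warnings

import numpy as np
import pytest

import phagedyn as pdn
from phagedyn import amplitude as amp
from phagedyn.model import rhs


@pytest.fixture(scope="module", params=["passive", "active"])
def setup(request):
    sc = pdn.FIXTURES[request.param]()
    return sc, sc.fixed_point, sc.params, pdn.decompose(sc.fixed_point, sc.params)


class TestCoordinateChange:
    def test_fixed_point_has_zero_amplitudes(self, setup):
        _, fp, _, spec = setup
        assert np.allclose(amp.amplitudes_from_state(fp.state, fp, spec.W), 0.0, atol=1e-14)

    def test_eigenvector_displacement_is_pure_mode(self, setup):
        _, fp, _, spec = setup
        state = fp.state.as_array() + 0.37 * spec.v2
        A = amp.amplitudes_from_state(state, fp, spec.W)
        assert np.allclose(A, [0.0, 0.37, 0.0, 0.0], atol=1e-12)

    def test_inoculum_amplitudes_match_linear_solve(self, setup):
        _, fp, _, spec = setup
        u = np.array([0.0, 0.0, 0.001, 0.0])
        A = amp.amplitudes_from_state(fp.state.as_array() + u, fp, spec.W)
        assert np.allclose(A, np.linalg.solve(spec.V, u), atol=1e-14)
        assert A[1] == pytest.approx(spec.W[1, 2] * 0.001, abs=1e-16)

    def test_round_trip_identity(self, setup):
        _, fp, _, spec = setup
        rng = np.random.default_rng(23)
        for _ in range(20):
            x = fp.state.as_array() + rng.normal(scale=0.1, size=4)
            A = amp.amplitudes_from_state(x, fp, spec.W)
            back = amp.state_from_amplitudes(A, fp, spec.V)
            assert np.max(np.abs(back.as_array() - x)) < 1e-10


class TestNonlinearRemainder:
    def test_vanishes_at_fixed_point(self, setup):
        _, fp, params, _ = setup
        assert np.all(amp.nonlinear_G(np.zeros(4), fp, params) == 0.0)

    def test_collapses_without_defense(self):
        params = pdn.ModelParams(beta0=5.0, gamma=0.0, alpha=0.3, Rm=1.0, q=0.2, k1=0.2,
                                 k2=1.0)
        fp = pdn.phage_free_fixed_point(1.0, 0.01, params)
        u = np.array([-0.02, 0.01, 0.005, 0.003])
        G = amp.nonlinear_G(u, fp, params)
        assert G[1] == pytest.approx(params.beta0 * u[2] * u[0], rel=1e-12)
        assert G[3] == pytest.approx(-params.alpha * u[1] * u[3] / params.Rm, rel=1e-12)

    def test_master_identity(self, setup):
        """rhs(fp + u) = J u + G(u) exactly: the decomposition into linear
        part and nonlinear remainder loses nothing."""
        _, fp, params, _ = setup
        J = pdn.jacobian(fp, params)
        rng = np.random.default_rng(29)
        for _ in range(200):
            u = rng.uniform(-0.05, 0.05, size=4)
            u[3] = max(u[3], -fp.state.R * 0.5)  # keep the defended contact rate defined
            full = rhs(fp.state.as_array() + u, params)
            assert np.max(np.abs(full - (J @ u + amp.nonlinear_G(u, fp, params)))) < 1e-12


class TestAmplitudeDynamics:
    def test_rest_state(self, setup):
        _, fp, params, spec = setup
        assert np.allclose(amp.amplitude_rhs(np.zeros(4), spec, fp, params), 0.0, atol=1e-16)

    def test_linear_regime_growth_rate(self, setup):
        _, fp, params, spec = setup
        for eps in (1e-6, 1e-8):
            dA = amp.amplitude_rhs(np.array([0.0, eps, 0.0, 0.0]), spec, fp, params)
            assert dA[1] / eps == pytest.approx(spec.lambda2, rel=1e-4)

    def test_conjugate_to_state_space_integration(self, setup):
        """Euler in amplitude coordinates, mapped back through the eigenbasis,
        reproduces Euler in state space (exact nonlinear change of coordinates)."""
        sc, fp, params, spec = setup
        _, states = pdn.euler_integrate(
            lambda x: rhs(x, params), sc.initial_state, sc.dt, 2.0
        )
        a0 = spec.W @ (sc.initial_state - fp.state.as_array())
        _, A = pdn.euler_integrate(
            lambda a: amp.amplitude_rhs(a, spec, fp, params), a0, sc.dt, 2.0
        )
        back = fp.state.as_array() + A @ spec.V.T
        assert np.max(np.abs(back - states)) < 10 * sc.dt

    def test_transverse_component_decays_at_lambda3(self, setup):
        # in the linear regime A3(t) ~ A3(0) exp(lambda3 t)
        sc, fp, params, spec = setup
        small = pdn.Scenario(
            params=params, fixed_point=fp,
            perturbation=pdn.SystemState(0.0, 0.0, 1e-6, 0.0),
            dt=sc.dt, horizon=1.0, label="linear-regime",
        )
        res = pdn.run_scenario(small)
        a3 = res.trajectory.amplitudes[:, 2]
        expected = a3[0] * np.exp(spec.lambda3 * res.trajectory.times)
        assert np.allclose(a3, expected, rtol=5e-3, atol=1e-12)


class TestOrderParameterApprox:
    def test_zero_at_time_zero(self, setup):
        _, fp, _, spec = setup
        assert np.all(amp.order_parameter_approx(0.0, 0.01, spec, fp) == 0.0)

    def test_rank_one_in_v2(self, setup):
        _, fp, _, spec = setup
        dX = amp.order_parameter_approx(np.linspace(0.0, 5.0, 7), 0.01, spec, fp)
        for row in dX[1:]:
            cross = row / np.linalg.norm(row) - spec.v2 * np.sign(row @ spec.v2)
            assert np.max(np.abs(cross)) < 1e-12

    def test_subcritical_configuration_warns(self):
        params = pdn.ModelParams(beta0=1.0, q=0.1, k1=1.0, k2=1.0)
        fp = pdn.phage_free_fixed_point(1.0, 0.0, params)
        spec = pdn.decompose(fp, params)
        with pytest.warns(UserWarning):
            amp.order_parameter_approx(1.0, 0.01, spec, fp)

    def test_phase_curve_converges_to_order_parameter(self, both_results):
        # the operational content of the phase-curve panels: the displacement
        # aligns with v2 to < 5 degrees for a sustained stretch
        for res in both_results.values():
            assert res.metrics["longest_aligned_window"] >= 1.0


class TestStoppingMechanisms:
    def test_zero_displacement(self, setup):
        _, fp, params, spec = setup
        terms = amp.stopping_terms(np.zeros(4), spec, params, fp)
        assert terms.linear == terms.passive == terms.active == 0.0

    def test_no_defense_no_active_braking(self):
        sc = pdn.passive_scenario()
        spec = pdn.decompose(sc.fixed_point, sc.params)
        u = np.array([-0.01, 0.005, 0.003, 0.0])
        assert amp.stopping_terms(u, spec, sc.params, sc.fixed_point).active == 0.0

    def test_braking_terms_nonnegative_during_outbreak(self, active_result):
        res = active_result
        sc = res.scenario
        for k in range(0, len(res.trajectory.times), 500):
            u = res.trajectory.states[k] - sc.fixed_point.state.as_array()
            terms = amp.stopping_terms(u, res.spectral, sc.params, sc.fixed_point)
            assert terms.passive >= 0.0
            assert terms.active >= 0.0

    def test_quadratic_expansion_is_third_order_accurate(self, setup):
        _, fp, params, spec = setup
        rng = np.random.default_rng(31)
        u0 = rng.normal(size=4)
        u0 /= np.linalg.norm(u0)
        errors = []
        for eps in (1e-2, 1e-3, 1e-4):
            u = eps * u0
            exact = float(spec.W[1] @ amp.nonlinear_G(u, fp, params))
            terms = amp.stopping_terms(u, spec, params, fp)
            errors.append(abs((-terms.passive - terms.active) - exact))
        # cubic decay down to the float-rounding floor (the passive remainder
        # is exactly quadratic, so its error is pure rounding noise)
        for eps, err in zip((1e-2, 1e-3, 1e-4), errors):
            assert err < 100.0 * eps**3
        for prev, nxt in zip(errors, errors[1:]):
            assert nxt <= max(2e-3 * prev, 1e-16)


class TestLinearPredictors:
    def test_self_and_reciprocal_slopes(self, setup):
        _, _, _, spec = setup
        r = amp.predictor_slopes(spec)
        for i in range(4):
            if not np.isnan(r[i, i]):
                assert r[i, i] == 1.0
            for j in range(4):
                if not (np.isnan(r[i, j]) or np.isnan(r[j, i])):
                    assert r[i, j] * r[j, i] == pytest.approx(1.0, rel=1e-12)

    def test_closed_form_slopes_for_phage_predictor(self, setup):
        _, _, params, spec = setup
        r = amp.predictor_slopes(spec)
        lam2, F0 = spec.lambda2, spec.F0
        assert r[0, 2] == pytest.approx(-F0 / (lam2 + params.mu), rel=1e-12)
        assert r[1, 2] == pytest.approx(F0 / (lam2 + params.k1), rel=1e-12)
        if spec.alpha_star > 0:
            assert r[3, 2] == pytest.approx(
                spec.alpha_star * F0 / ((lam2 + params.k1) * lam2), rel=1e-12
            )

    def test_undefined_slope_reported_as_nan(self):
        sc = pdn.passive_scenario()  # alpha = 0 -> v2 has no R component
        spec = pdn.decompose(sc.fixed_point, sc.params)
        r = amp.predictor_slopes(spec)
        assert np.all(np.isnan(r[:, 3]))

    def test_infected_from_phage_intercept_vanishes(self, setup):
        _, fp, _, spec = setup
        a = amp.predictor_intercepts(spec, fp)
        assert a[1, 2] == 0.0

    def test_regression_on_trajectory_recovers_slope(self, both_results):
        # least squares I-vs-P on the order-parameter-dominated window
        for res in both_results.values():
            t, st = res.trajectory.times, res.trajectory.states
            m = (t >= 2.0) & (t <= 4.0)
            slope = np.polyfit(st[m, 2], st[m, 1], 1)[0]
            expected = amp.predictor_slopes(res.spectral)[1, 2]
            assert slope == pytest.approx(expected, rel=0.05)


class TestDoubleExponential:
    def test_exact_at_time_zero(self, setup):
        sc, fp, _, spec = setup
        a0 = spec.W @ (sc.initial_state - fp.state.as_array())
        ip0 = amp.double_exponential(0.0, a0[1], a0[2], spec)
        assert np.allclose(ip0, sc.initial_state[1:3], atol=1e-14)

    def test_single_mode_reduces_to_order_parameter_exponential(self, setup):
        _, _, _, spec = setup
        t = np.linspace(0.0, 3.0, 10)
        ip = amp.double_exponential(t, 0.01, 0.0, spec)
        expected = np.multiply.outer(np.exp(spec.lambda2 * t), spec.V[1:3, 1] * 0.01)
        assert np.allclose(ip, expected, rtol=1e-14)

    def test_two_modes_reconstruct_infected_phage_exactly(self, both_results):
        """v1 and v4 have no (I, P) components, so (A2, A3) alone carry the
        infected/phage dynamics at all times, not just initially."""
        for res in both_results.values():
            spec, traj = res.spectral, res.trajectory
            assert np.all(spec.V[1:3, [0, 3]] == 0.0)
            recon = (
                np.multiply.outer(traj.amplitudes[:, 1], spec.V[1:3, 1])
                + np.multiply.outer(traj.amplitudes[:, 2], spec.V[1:3, 2])
            )
            assert np.max(np.abs(recon - traj.states[:, 1:3])) < 1e-10

    def test_early_accuracy_and_earlier_departure_with_defense(self, both_results):
        passive = both_results["passive"].metrics
        active = both_results["active"].metrics
        t = both_results["passive"].trajectory.times
        early = t <= 2.0
        assert np.all(passive["dexp_rel_err"][early] < 0.10)
        assert active["first_deviation_time"] < passive["first_deviation_time"]
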