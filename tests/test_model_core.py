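import json
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tnaswitch.model_core import (
    DEFAULT_PARAMS,
    DomainError,
    Environment,
    FullModelParams,
    ReducedParams,
    ReducedState,
    integrate,
    reduce_params,
    rho_A,
    rho_G,
    rho_W,
    rho_W_prime,
    rhs_full,
    rhs_reduced,
    trajectory_to_csv,
)
from tnaswitch.steady_state import find_steady_states


class TestRhoG:
    def test_value_one_at_zero_glucose(self, params):
        assert rho_G(0.0, params) == 1.0

    def test_half_saturation(self, params):
        assert rho_G(params.K_G, params) == pytest.approx(0.5, abs=1e-15)

    def test_hand_arithmetic(self, params):
        # K_G=11, n_G=4, G_e=15: 11^4 / (11^4 + 15^4)
        expected = 14641 / (14641 + 50625)
        assert rho_G(15.0, params) == pytest.approx(expected, rel=1e-12)

    def test_negative_glucose_rejected(self, params):
        with pytest.raises(DomainError):
            rho_G(-1.0, params)

    @given(st.floats(min_value=0.0, max_value=1e3), st.floats(min_value=0.0, max_value=1e3))
    @settings(max_examples=50, deadline=None)
    def test_strictly_decreasing_into_unit_interval(self, g1, g2):
        lo, hi = sorted((g1, g2))
        v_lo, v_hi = rho_G(lo), rho_G(hi)
        assert 0.0 < v_hi <= v_lo <= 1.0
        if hi > lo + 1e-3 and hi > 0.1:  # resolvable in double precision
            assert v_hi < v_lo


class TestRhoW:
    def test_zero_at_zero(self, params):
        assert rho_W(0.0, params) == 0.0

    def test_half_saturation(self, params):
        assert rho_W(params.K_W, params) == pytest.approx(0.5, abs=1e-15)

    def test_hand_arithmetic(self, params):
        expected = 30.0**4 / (60.0**4 + 30.0**4)
        assert rho_W(30.0, params) == pytest.approx(expected, rel=1e-12)

    def test_negative_rejected(self, params):
        with pytest.raises(DomainError):
            rho_W(-0.5, params)

    @given(st.floats(min_value=0.0, max_value=1e4), st.floats(min_value=0.0, max_value=1e4))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_into_unit_interval(self, w1, w2):
        lo, hi = sorted((w1, w2))
        v_lo, v_hi = rho_W(lo), rho_W(hi)
        assert 0.0 <= v_lo <= v_hi < 1.0
        if hi > lo + 1e-3 and hi > 0.1:  # resolvable in double precision
            assert v_hi > v_lo

    def test_derivative_matches_finite_difference(self, params):
        w = np.linspace(1.0, 200.0, 40)
        h = 1e-6
        fd = (rho_W(w + h, params) - rho_W(w - h, params)) / (2 * h)
        np.testing.assert_allclose(rho_W_prime(w, params), fd, rtol=1e-5)


class TestRhoA:
    def test_identity_at_origin(self, params):
        assert rho_A(0.0, 0.0, params=params) == 1.0

    def test_global_minimum_location_and_value(self, params):
        # minimum of 1 - (x/K1)^3 exp(-x/K2) sits at x = 3*K2 = 27
        expected = 1.0 - (27.0 / 14.0) ** 3 * math.exp(-3.0)
        assert rho_A(0.0, 27.0, params=params) == pytest.approx(expected, rel=1e-12)
        # neighbours are higher
        assert rho_A(0.0, 26.0, params=params) > expected
        assert rho_A(0.0, 28.0, params=params) > expected

    def test_value_at_we_24(self, params):
        expected = 1.0 - (24.0 / 14.0) ** 3 * math.exp(-24.0 / 9.0)
        assert rho_A(0.0, 24.0, params=params) == pytest.approx(expected, rel=1e-12)

    def test_returns_to_one_far_out(self, params):
        x_far = 40.0 * params.K2
        assert abs(rho_A(0.0, x_far, params=params) - 1.0) < 1e-6

    def test_derivative_changes_sign_once(self, params):
        x = np.linspace(1e-3, 40 * params.K2, 20000)
        vals = rho_A(np.zeros_like(x), x, params=params)
        sign = np.sign(np.diff(vals))
        flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
        assert len(flips) == 1
        x_min = x[flips[0] + 1]
        assert x_min == pytest.approx(3 * params.K2, abs=0.1)

    def test_positive_minimum_with_standard_constants(self, params):
        x = np.linspace(0, 100 * params.K2, 50000)
        assert np.all(rho_A(np.zeros_like(x), x, params=params) > 0)

    def test_negative_value_warns_for_nonstandard_constants(self):
        odd = DEFAULT_PARAMS.with_(K1=1.0, K2=9.0)
        with pytest.warns(RuntimeWarning):
            val = rho_A(0.0, 27.0, params=odd)
        assert val < 0

    def test_activity_decreases_then_increases_along_tryptophan(self, params):
        # at G_e = 0 activity falls over W_e in {0, 6, 12, 24} then rises at 48
        vals = [rho_A(0.0, we, params=params) for we in (0.0, 6.0, 12.0, 24.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert rho_A(0.0, 48.0, params=params) > vals[-1]

    def test_activity_monotone_in_glucose_at_we_24(self, params):
        vals = [rho_A(ge, 24.0, params=params) for ge in (0.0, 3.75, 7.5, 15.0)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_negative_inputs_rejected(self, params):
        with pytest.raises(DomainError):
            rho_A(-1.0, 0.0, params=params)


class TestReduceParams:
    def test_theta_from_consumption_ratio(self):
        full = FullModelParams(
            k_A=1, k_B=0.001, gamma_A=0, gamma_B=0,
            mu=0.01, alpha=0.1, beta=1.5, delta=0.05, epsilon=0.1,
        )
        reduced = reduce_params(full)
        assert reduced.theta == pytest.approx(6.0)
        assert reduced.phi == pytest.approx(150.0)

    def test_psi_unity_when_catabolism_matches_production(self):
        full = FullModelParams(
            k_A=0.4, k_B=0.001, gamma_A=0, gamma_B=0,
            mu=0.01, alpha=0.1, beta=1.5, delta=0.05, epsilon=0.4,
        )
        assert reduce_params(full).psi == pytest.approx(1.0)

    def test_invalid_rates_rejected(self):
        with pytest.raises(DomainError):
            FullModelParams(
                k_A=0, k_B=1, gamma_A=0, gamma_B=0,
                mu=1, alpha=1, beta=1, delta=1, epsilon=1,
            )


class TestRhsReduced:
    def test_origin_fixed_point_without_tryptophan(self, params):
        env = Environment(G_e=5.0, W_e=0.0)
        assert rhs_reduced((0.0, 0.0), env, params) == (0.0, 0.0)

    def test_protein_nullcline_identity(self, params):
        env = Environment(G_e=3.0, W_e=10.0)
        w = 42.0
        p = rho_G(env.G_e, params) * rho_W(w, params)
        dp, _ = rhs_reduced((p, w), env, params)
        assert dp == pytest.approx(0.0, abs=1e-15)

    @pytest.mark.parametrize("ge,we", [(7.5, 48.0), (30.0, 48.0), (0.0, 24.0)])
    def test_vanishes_at_found_steady_states(self, params, ge, we):
        env = Environment(G_e=ge, W_e=we)
        for s in find_steady_states(env, params):
            dp, dw = rhs_reduced((s.p_star, s.w_star), env, params)
            assert abs(dp) < 1e-8
            assert abs(dw) < 1e-6 * max(1.0, we)


class TestRhsFullAndReduction:
    def test_origin_fixed_point(self, params):
        full = FullModelParams(
            k_A=0.01, k_B=0.01, gamma_A=0, gamma_B=0,
            mu=0.01, alpha=0.1, beta=15.0, delta=0.05, epsilon=0.001,
        )
        env = Environment(G_e=0.0, W_e=0.0)
        assert rhs_full((0.0, 0.0, 0.0), env, full, params) == (0.0, 0.0, 0.0)

    def test_reduction_equivalence(self, params):
        # with k_A = k_B = mu the reduction map is exact; gamma = 0
        mu = 0.01
        full = FullModelParams(
            k_A=mu, k_B=mu, gamma_A=0.0, gamma_B=0.0,
            mu=mu, alpha=0.1, beta=15.0, delta=0.05, epsilon=0.001,
        )
        reduced = reduce_params(full)
        assert reduced.phi == pytest.approx(150.0)
        assert reduced.psi == pytest.approx(0.1)
        assert reduced.theta == pytest.approx(6.0)

        env = Environment(G_e=7.5, W_e=48.0)
        A0, B0, W0 = 0.3, 0.3, 100.0
        t_end_full = 2000.0  # 20 dimensionless time units

        from scipy.integrate import solve_ivp

        sol = solve_ivp(
            lambda t, y: rhs_full(tuple(y), env, full, params),
            (0.0, t_end_full), (A0, B0, W0),
            rtol=1e-10, atol=1e-12, dense_output=True, method="LSODA",
        )
        t_red = np.linspace(0.0, mu * t_end_full, 200)
        t_red_times, y_red = integrate(
            (A0 * mu / full.k_A, W0 * mu / full.alpha), env, reduced,
            t_end=mu * t_end_full, dt=t_red[1] - t_red[0],
            rtol=1e-10, atol=1e-12,
        )
        full_vals = sol.sol(t_red_times / mu)
        p_full = full_vals[0] * mu / full.k_A
        w_full = full_vals[2] * mu / full.alpha
        assert np.max(np.abs(p_full - y_red[:, 0])) < 1e-6
        assert np.max(np.abs(w_full - y_red[:, 1])) < 1e-6 * max(1.0, np.max(w_full))

    def test_full_steady_state_approaches_reduced_as_gamma_vanishes(self, params):
        mu = 0.01
        env = Environment(G_e=30.0, W_e=48.0)
        target = find_steady_states(env, params).states[0]
        from scipy.integrate import solve_ivp

        dists = []
        for gamma in (1e-3 * mu, 1e-5 * mu):
            full = FullModelParams(
                k_A=mu, k_B=mu, gamma_A=gamma, gamma_B=gamma,
                mu=mu, alpha=0.1, beta=15.0, delta=0.05, epsilon=0.001,
            )
            sol = solve_ivp(
                lambda t, y: rhs_full(tuple(y), env, full, params),
                (0.0, 5e4), (0.0, 0.0, 0.0), rtol=1e-10, atol=1e-12,
                method="LSODA",
            )
            w_end = sol.y[2, -1] * mu / full.alpha
            dists.append(abs(w_end - target.w_star))
        assert dists[1] < dists[0] + 1e-9
        assert dists[1] < 1e-3 * max(1.0, target.w_star)


class TestIntegrate:
    def test_collapses_to_origin_without_tryptophan(self, params):
        env = Environment(G_e=2.0, W_e=0.0)
        _, y = integrate((0.8, 55.0), env, params, t_end=60.0)
        assert y[-1, 0] == pytest.approx(0.0, abs=1e-6)
        assert y[-1, 1] == pytest.approx(0.0, abs=1e-4)

    def test_converges_to_unique_root_when_monostable(self, params):
        env = Environment(G_e=30.0, W_e=48.0)
        root = find_steady_states(env, params).states[0]
        for start in [(0.0, 0.0), (1.0, 500.0)]:
            _, y = integrate(start, env, params, t_end=200.0)
            assert y[-1, 1] == pytest.approx(root.w_star, rel=1e-4)

    def test_bistable_condition_splits_between_stable_roots(self, params):
        env = Environment(G_e=7.5, W_e=48.0)
        ss = find_steady_states(env, params)
        assert len(ss) == 3
        lo, mid, hi = ss.states
        _, y_lo = integrate((0.0, 0.9 * mid.w_star), env, params, t_end=400.0)
        _, y_hi = integrate((mid.p_star, 1.1 * mid.w_star), env, params, t_end=400.0)
        assert y_lo[-1, 1] == pytest.approx(lo.w_star, rel=1e-3)
        assert y_hi[-1, 1] == pytest.approx(hi.w_star, rel=1e-3)

    def test_rejects_nonpositive_horizon(self, params):
        with pytest.raises(DomainError):
            integrate((0.0, 0.0), Environment(G_e=0, W_e=0), params, t_end=0.0)


class TestSerialization:
    def test_params_json_round_trip(self, tmp_path, params):
        path = tmp_path / "params.json"
        params.to_json(path)
        obj = json.loads(path.read_text())
        assert set(obj) == {
            "phi", "psi", "theta", "K_W", "n_W", "K_G", "n_G", "K1", "K2", "lam"
        }
        assert ReducedParams.from_json(path) == params

    def test_trajectory_csv_header(self, tmp_path, params):
        t, y = integrate((0.1, 1.0), Environment(G_e=0, W_e=6), params, 1.0, dt=0.5)
        path = tmp_path / "traj.csv"
        trajectory_to_csv(t, y, path)
        assert path.read_text().splitlines()[0] == "t,p,w"

    def test_state_invariants(self):
        with pytest.raises(DomainError):
            ReducedState(p=-0.1, w=0.0)
        with pytest.raises(DomainError):
            Environment(G_e=float("nan"), W_e=0.0)
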