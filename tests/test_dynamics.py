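"""Neural dynamics: kernels, input integrators, activation, phase, learning,
reward capture."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cogswarm.dynamics as dyn


def _random_coupling(rng, n, n_c=3, n_r=2):
    """Random but structurally valid state for oracle comparisons."""
    V = (rng.random((n, n)) < 0.7).astype(float)
    V = np.triu(V, 1)
    V = V + V.T
    D = rng.uniform(1, 100, (n, n))
    D = np.triu(D, 1)
    D = D + D.T
    theta = rng.uniform(0, 2 * np.pi, n)
    c = rng.random((n, n_c))
    r = rng.random((n, n_r))
    q = rng.uniform(-1, 1, (n, n))
    V_c = (rng.random((n, n_c)) < 0.8).astype(float)
    V_r = (rng.random((n, n_r)) < 0.8).astype(float)
    D_r = rng.uniform(1, 100, (n, n_r))
    p = rng.random(n)
    return dict(V=V, D=D, theta=theta, c=c, r=r, q=q, V_c=V_c, V_r=V_r, D_r=D_r, p=p)


class TestKernels:
    def test_swarm_kernel_closed_forms(self):
        V = np.ones((2, 2)) - np.eye(2)
        D = np.array([[0.0, 5.0], [5.0, 0.0]])
        W = dyn.swarm_kernel(V, D, sigma_eff=5.0)
        assert W[0, 1] == pytest.approx(np.exp(-1))
        assert W[0, 0] == 0.0  # no self-connection
        assert dyn.swarm_kernel(np.ones((1, 1)), np.zeros((1, 1)), 5.0)[0, 0] == 1.0

    def test_reward_kernel_closed_forms(self):
        assert dyn.reward_kernel(np.ones((1, 1)), np.zeros((1, 1)), 3.0)[0, 0] == 1.0
        W = dyn.reward_kernel(np.ones((1, 1)), np.array([[3.0]]), 3.0)
        assert W[0, 0] == pytest.approx(np.exp(-1))

    def test_exponential_tail_heavier_than_gaussian(self):
        scale = 7.0
        d = np.array([[2 * scale]])
        one = np.ones((1, 1))
        assert dyn.reward_kernel(one, d, scale) > dyn.swarm_kernel(one, d, scale)[0, 0]


class TestInputIntegrators:
    def test_cue_fixed_point(self):
        c = np.array([[0.7]])
        out = dyn.step_cue_inputs(c, np.array([[1.0]]) * 0.7, np.ones((1, 1)), 0.5, 0.01)
        assert out == pytest.approx(0.7)

    def test_cue_one_step_growth(self):
        out = dyn.step_cue_inputs(
            np.zeros((1, 1)), np.ones((1, 1)), np.ones((1, 1)), tau_c=0.5, dt=0.01
        )
        assert out[0, 0] == pytest.approx(0.02)

    def test_cue_decay_when_invisible(self):
        c = np.array([[0.5]])
        out = dyn.step_cue_inputs(c, np.zeros((1, 1)), np.ones((1, 1)), 0.5, 0.01)
        assert out[0, 0] == pytest.approx(0.98 * 0.5)

    def test_reward_fixed_point_and_decay(self):
        r = np.array([[1.0]])
        assert dyn.step_reward_inputs(r, np.ones((1, 1)), 0.5, 0.01) == pytest.approx(1.0)
        out = dyn.step_reward_inputs(np.array([[0.5]]), np.zeros((1, 1)), 0.5, 0.01)
        assert out[0, 0] == pytest.approx(0.49)

    @pytest.mark.parametrize(
        "dphase,expect", [(0.0, 1.0), (np.pi, -1.0), (np.pi / 2, 0.0)]
    )
    def test_recurrent_fixed_points(self, dphase, expect):
        theta = np.array([0.0, dphase])
        V = np.ones((2, 2)) - np.eye(2)
        q = V * np.cos(theta[None, :] - theta[:, None])
        out = dyn.step_recurrent_inputs(q, V, theta, tau_q=0.1, dt=0.01)
        assert out[0, 1] == pytest.approx(expect, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000), st.floats(0.01, 0.99))
    def test_euler_updates_stay_in_range(self, seed, ratio):
        """With dt/tau < 1 the convex Euler steps keep c, r in [0, 1] and q
        in [-1, 1]."""
        rng = np.random.default_rng(seed)
        s = _random_coupling(rng, 4)
        dt, tau = ratio, 1.0
        c = s["c"]
        q = s["q"]
        for _ in range(50):
            c = dyn.step_cue_inputs(c, s["V_c"], np.ones_like(s["V_c"]), tau, dt)
            q = dyn.step_recurrent_inputs(q, s["V"], s["theta"], tau, dt)
        assert np.all((c >= 0) & (c <= 1))
        assert np.all((q >= -1) & (q <= 1))


class TestNetInputsActivation:
    def test_cue_input_attains_gain_bound(self):
        c = np.ones((1, 2))
        V_c = np.ones((1, 2))
        I_c, I_r, I_q = dyn.net_inputs(
            c, np.zeros((1, 0)), np.zeros((1, 1)), np.zeros((1, 1)),
            np.zeros((1, 0)), V_c, np.zeros((1, 0)), np.zeros((1, 1)),
            (0.4, 0.2, 0.4),
        )
        assert I_c[0] == pytest.approx(0.4)
        assert I_r[0] == 0.0  # zero-visibility convention
        assert I_q[0] == 0.0

    def test_single_antiphase_neighbor_gives_negative_gain(self):
        V = np.array([[0.0, 1.0], [1.0, 0.0]])
        W = V.copy()
        q = -V
        _, _, I_q = dyn.net_inputs(
            np.zeros((2, 0)), np.zeros((2, 0)), q, W, np.zeros((2, 0)),
            np.zeros((2, 0)), np.zeros((2, 0)), V, (0.4, 0.2, 0.4),
        )
        assert I_q[0] == pytest.approx(-0.4)

    def test_activation_rectifies_and_sums(self):
        p = dyn.activation(np.array([-0.1]), np.array([-0.05]), np.array([-0.05]))
        assert p[0] == 0.0
        p = dyn.activation(np.array([0.4]), np.array([0.2]), np.array([0.4]))
        assert p[0] == pytest.approx(1.0)

    def test_activation_bounded_over_random_states(self, rng):
        """p stays in [0, 1] for any admissible couplings when gains sum to 1."""
        for _ in range(200):
            s = _random_coupling(rng, 5)
            W = dyn.swarm_kernel(s["V"], s["D"], 50.0)
            W_r = dyn.reward_kernel(s["V_r"], s["D_r"], 50.0)
            I = dyn.net_inputs(
                s["c"], s["r"], s["q"], W, W_r, s["V_c"], s["V_r"], s["V"],
                (0.4, 0.2, 0.4),
            )
            p = dyn.activation(*I)
            assert np.all(p >= 0.0) and np.all(p <= 1.0 + 1e-12)


class TestPhase:
    def test_quiescent_phase_is_static(self):
        theta = np.array([1.0, 2.0])
        out = dyn.advance_phase(theta, np.zeros(2), omega0=0.0, omegaI=1.0, dt=0.01)
        assert np.array_equal(out, theta)

    def test_full_activation_advance(self):
        out = dyn.advance_phase(np.zeros(1), np.ones(1), 0.0, 1.0, 0.01)
        assert out[0] == pytest.approx(0.02 * np.pi)

    def test_wraps_into_range(self):
        out = dyn.advance_phase(np.array([2 * np.pi - 1e-3]), np.ones(1), 0.0, 1.0, 0.01)
        assert 0.0 <= out[0] < 2 * np.pi


class TestOjaUpdates:
    def test_zero_activation_is_identity(self, rng):
        s = _random_coupling(rng, 4)
        W = dyn.swarm_kernel(s["V"], s["D"], 50.0)
        out = dyn.oja_update_swarm(W, np.zeros(4), s["q"], s["V"], 1.0, 0.01)
        assert np.array_equal(out, W)

    def test_fixed_point_w_equals_q_over_p(self):
        p = np.array([0.5])
        q = np.array([[0.4]])
        W = q / p
        out = dyn.oja_update_swarm(W, p, q, np.ones((1, 1)), 1.0, 0.01)
        assert out == pytest.approx(W)

    def test_scalar_iteration_converges_geometrically(self):
        """Frozen p, q: W converges to q/p and the error ratio equals
        1 - dt*eta*p^2 each step."""
        p = np.array([0.6])
        q = np.array([[0.3]])
        V = np.ones((1, 1))
        W = np.array([[0.9]])
        target = q[0, 0] / p[0]
        rho = 1 - 0.01 * 1.0 * p[0] ** 2
        errs = []
        for _ in range(6000):
            errs.append(abs(W[0, 0] - target))
            W = dyn.oja_update_swarm(W, p, q, V, 1.0, 0.01)
        errs = np.array(errs)
        assert abs(W[0, 0] - target) < 1e-6
        ratios = errs[1:50] / errs[0:49]
        assert np.allclose(ratios, rho, atol=1e-9)

    def test_mask_gates_rows(self, rng):
        s = _random_coupling(rng, 4)
        W = dyn.swarm_kernel(s["V"], s["D"], 50.0)
        mask = np.array([1.0, 0.0, 1.0, 0.0])
        out = dyn.oja_update_swarm(W, s["p"], s["q"], s["V"], 1.0, 0.01, mask)
        assert np.array_equal(out[1], W[1])
        assert np.array_equal(out[3], W[3])

    def test_reward_update_fixed_point(self):
        p = np.array([0.5])
        r = np.array([[0.2]])
        W_r = r / p
        out = dyn.oja_update_reward(W_r, p, r, np.ones((1, 1)), 1.0, 0.01)
        assert out == pytest.approx(W_r)

    def test_clamp_bounds(self):
        W = np.array([[0.0, 0.5, 2.0]])
        out = dyn.clamp_weights(W, 1e-6)
        assert np.array_equal(out, [[1e-6, 0.5, 1.0]])


class TestRewardCapture:
    def test_zero_radius_never_captures(self):
        captured = np.zeros((3, 2), dtype=bool)
        dist = np.zeros((3, 2))
        newly = dyn.apply_reward_capture(captured, dist, 0.0, "multi")
        assert not newly.any() and not captured.any()

    def test_contact_within_radius_captures(self):
        captured = np.zeros((1, 1), dtype=bool)
        newly = dyn.apply_reward_capture(captured, np.array([[11.0]]), 12.0, "multi")
        assert newly[0, 0] and captured[0, 0]

    def test_single_mode_zeroes_column_permanently(self, square_arena):
        from cogswarm.dynamics import CouplingState, refresh_geometry_couplings

        arena = square_arena
        coup = CouplingState.zeros(3, 0, 0)
        coup.V_r = np.zeros((3, 1))
        pts = np.array([[50.0, 50.0], [60.0, 60.0], [70.0, 70.0]])
        captured = np.array([True])
        # a captured reward stays invisible after a geometry refresh
        arena2 = type(arena)(
            outer_ring=arena.outer_ring, rewards=[("R", 100.0, 100.0)]
        )
        refresh_geometry_couplings(coup, pts, arena2, 1e9, captured, "single",
                                   agent_pos=pts[0])
        assert np.all(coup.V_r[:, 0] == 0.0)

    def test_captured_set_is_monotone(self, rng):
        captured = np.zeros((4, 3), dtype=bool)
        sets = []
        for _ in range(30):
            dist = rng.uniform(0, 30, (4, 3))
            dyn.apply_reward_capture(captured, dist, 10.0, "multi")
            sets.append(captured.copy())
        for a, b in zip(sets, sets[1:]):
            assert np.all(b[a])  # once captured, always captured
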