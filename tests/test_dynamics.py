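import numpy as np
import pytest
from scipy.optimize import brentq

from adaptnet import _kernels
from adaptnet.connectivity import WeightMatrix
from adaptnet.dynamics import (
    ModelParams,
    NetworkState,
    phi,
    phi_prime,
    relax_to_fixed_point,
    rhs,
    simulate,
)
from adaptnet.exceptions import DivergenceError, ParameterError
from adaptnet.stimuli import StimulusSpec, constant_stimulus, zero_stimulus


def zero_network(N=4):
    return WeightMatrix(np.zeros((N, N)), np.full(N, "E"))


class TestActivation:
    def test_linear_branch(self):
        assert phi(0.5) == 0.5
        assert phi_prime(0.5) == 1.0

    def test_saturation(self):
        w = 0.1
        assert phi(-w, w) == 0.0
        assert phi(1 + w, w) == 1.0
        assert phi_prime(-w, w) == 0.0
        assert phi_prime(1 + w, w) == 0.0

    def test_corner_value(self):
        assert phi(0.0, 0.1) == pytest.approx(0.025)

    def test_range_and_monotonicity(self):
        h = np.linspace(-2, 3, 2001)
        y = phi(h)
        assert np.all((y >= 0) & (y <= 1))
        assert np.all(np.diff(y) >= 0)
        dp = phi_prime(h)
        assert np.all((dp >= 0) & (dp <= 1))

    def test_derivative_matches_finite_difference(self):
        h = np.linspace(-0.5, 1.5, 401)
        eps = 1e-7
        fd = (phi(h + eps) - phi(h - eps)) / (2 * eps)
        # C^1: exact away from the four breakpoints, O(eps) at them
        np.testing.assert_allclose(phi_prime(h), fd, atol=1e-5)

    def test_kernel_scalar_matches_vectorized(self):
        h = np.linspace(-1.0, 2.0, 301)
        for w in (0.05, 0.1, 0.5):
            kv = np.array([_kernels.phi_scalar(x, w) for x in h])
            kd = np.array([_kernels.phi_prime_scalar(x, w) for x in h])
            np.testing.assert_array_equal(kv, phi(h, w))
            np.testing.assert_array_equal(kd, phi_prime(h, w))


class TestRHS:
    def test_rest_state_derivatives(self):
        # at x=0, a=0, b=1 with a0=0: r = phi(0) = w/4 = 0.025
        p = ModelParams(a0=0.0)
        W = zero_network()
        st = NetworkState(np.zeros(4), np.zeros((4, 3)), np.ones(4))
        d = rhs(st, np.zeros(4), W, p)
        np.testing.assert_allclose(d.x, 0.0)
        for k, tau in enumerate(p.tau_k):
            np.testing.assert_allclose(d.a[:, k], 0.025 / tau)
        np.testing.assert_allclose(d.b, -0.025 / p.tau_rel)

    def test_depleted_synapses_silence_recurrence(self):
        rng = np.random.default_rng(0)
        W = WeightMatrix(rng.normal(size=(4, 4)), np.full(4, "E"))
        p = ModelParams(a0=0.0)
        st = NetworkState(np.zeros(4), np.zeros((4, 3)), np.zeros(4))
        d = rhs(st, np.zeros(4), W, p)
        np.testing.assert_allclose(d.x, 0.0)  # W @ (b*r) = 0 at b = 0
        np.testing.assert_allclose(d.b, 1.0 / p.tau_rec)

    def test_reduces_to_hopfield_form_without_adaptation(self):
        rng = np.random.default_rng(1)
        N = 6
        W = WeightMatrix(rng.normal(0, 0.3, (N, N)), np.full(N, "E"))
        p = ModelParams(a0=0.0, sfa_enabled=False, std_enabled=False)
        x = rng.normal(0, 0.5, N)
        u = rng.uniform(0, 0.3, N)
        st = NetworkState(x, rng.uniform(0, 1, (N, 3)), rng.uniform(0, 1, N))
        d = rhs(st, u, W, p)
        np.testing.assert_allclose(
            d.x, (-x + u + W.values @ phi(x)) / p.tau_d, atol=1e-12
        )
        np.testing.assert_allclose(d.a, 0.0)
        np.testing.assert_allclose(d.b, 0.0)

    def test_dimension_mismatch(self):
        p = ModelParams()
        st = NetworkState(np.zeros(4), np.zeros((4, 3)), np.ones(4))
        with pytest.raises(ParameterError):
            rhs(st, np.zeros(5), zero_network(4), p)
        with pytest.raises(ParameterError):
            rhs(st, np.zeros(4), zero_network(5), p)


class TestSimulate:
    def test_leak_decay(self):
        W = zero_network(8)
        p = ModelParams(sfa_enabled=False, std_enabled=False)
        traj = simulate(W, p, zero_stimulus(8), T=5 * p.tau_d, dt=0.005,
                        seed=1)
        assert np.linalg.norm(traj.x[-1]) < 0.01 * np.linalg.norm(traj.x[0])

    def test_constant_input_fixed_point(self):
        W = zero_network(5)
        p = ModelParams(sfa_enabled=False, std_enabled=False)
        u = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        traj = simulate(W, p, constant_stimulus(u), T=2.0, seed=2)
        np.testing.assert_allclose(traj.x[-1], u, atol=1e-6)

    def test_rk4_convergence_order(self):
        # smooth segment (states stay inside one polynomial branch of phi)
        rng = np.random.default_rng(3)
        N = 10
        W = WeightMatrix(rng.normal(0, 0.1, (N, N)), np.full(N, "E"))
        p = ModelParams()
        x0 = NetworkState(rng.normal(0, 0.01, N), np.zeros((N, 3)), np.ones(N))
        stim = zero_stimulus(N)

        def final(dt):
            traj = simulate(W, p, stim, T=0.4, dt=dt, x0=x0, sample_every=1)
            return np.concatenate([traj.x[-1], traj.b[-1]])

        e1 = np.linalg.norm(final(0.02) - final(0.0025))
        e2 = np.linalg.norm(final(0.01) - final(0.0025))
        order = np.log2(e1 / e2)
        assert order >= 3.5

    def test_disabled_mechanisms_bit_frozen(self, small_dale):
        p = ModelParams(sfa_enabled=False, std_enabled=False)
        traj = simulate(small_dale, p, zero_stimulus(small_dale.n), T=1.0,
                        seed=4)
        assert np.all(traj.a == 0.0)
        assert np.all(traj.b == 1.0)

    def test_seed_determinism(self, small_dale, default_params):
        stim = zero_stimulus(small_dale.n)
        t1 = simulate(small_dale, default_params, stim, T=1.0, seed=5)
        t2 = simulate(small_dale, default_params, stim, T=1.0, seed=5)
        np.testing.assert_array_equal(t1.x, t2.x)
        np.testing.assert_array_equal(t1.b, t2.b)

    def test_divergence_reported_with_time(self):
        W = zero_network(3)
        p = ModelParams(sfa_enabled=False, std_enabled=False)
        stim = StimulusSpec(0.0, 1e30, np.full(3, 5e6))
        with pytest.raises(DivergenceError) as err:
            simulate(W, p, stim, T=10.0, seed=0)
        assert err.value.t_blowup > 0

    def test_dt_guard(self, small_dale, default_params):
        with pytest.raises(ParameterError):
            simulate(small_dale, default_params, zero_stimulus(small_dale.n),
                     T=1.0, dt=0.05)


class TestFixedPoint:
    def test_isolated_neurons_closed_form(self):
        # W = 0, u = 0, a0 = 0: steady state solves r = phi(-c K r),
        # a_k = r, b = 1 / (1 + r tau_rec / tau_rel)
        p = ModelParams(a0=0.0)
        W = zero_network(3)
        res = relax_to_fixed_point(W, p, np.zeros(3), tol=1e-12, T_max=900.0)
        assert res.converged
        r_star = brentq(lambda r: phi(-p.c * p.K * r, p.w_corner) - r, 0.0, 1.0)
        np.testing.assert_allclose(res.state.x, 0.0, atol=1e-9)
        np.testing.assert_allclose(res.state.a,
                                   np.full((3, 3), r_star), atol=1e-6)
        b_star = 1.0 / (1.0 + r_star * p.tau_rec / p.tau_rel)
        np.testing.assert_allclose(res.state.b, b_star, atol=1e-6)

    def test_stable_network_converges(self, weak_network):
        p = ModelParams(sfa_enabled=False, std_enabled=False)
        u = np.full(weak_network.n, 0.05)
        res = relax_to_fixed_point(weak_network, p, u, T_max=50.0)
        assert res.converged
        assert res.residual_norm < 1e-10

    def test_chaotic_regime_does_not_converge(self):
        # the no-adaptation default ensemble under a sustained random
        # excitatory step wanders chaotically instead of settling
        from adaptnet.connectivity import NetworkSpec, generate_dale
        from adaptnet.stimuli import random_step

        W = generate_dale(NetworkSpec(seed=6))
        p = ModelParams(sfa_enabled=False, std_enabled=False)
        u = random_step(W.n, W.labels, seed=106).amplitudes
        res = relax_to_fixed_point(W, p, u, T_max=20.0)
        assert not res.converged


class TestFlowClosure:
    def test_state_bounds_preserved(self, small_dale, default_params):
        from adaptnet.stimuli import random_step

        stim = random_step(small_dale.n, small_dale.labels, t_on=1.0,
                           t_off=3.0, amp_max=0.8, seed=2)
        traj = simulate(small_dale, default_params, stim, T=5.0, seed=3)
        assert np.all((traj.b >= 0.0) & (traj.b <= 1.0))
        assert np.all((traj.a >= 0.0) & (traj.a <= 1.0))
        assert np.all((traj.rates >= 0.0) & (traj.rates <= 1.0))
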