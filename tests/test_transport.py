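import numpy as np
import pytest
from scipy.integrate import solve_ivp

from sushibelt import (
    TransportSystem,
    assemble_generator,
    build_cable,
    build_tree,
    convergence_timescale,
    delivered_distribution,
    evolve,
    log_times,
    per_compartment_delay,
    steady_state,
)
from sushibelt.demand import three_compartment_bottleneck

from conftest import random_system


def two_comp(a=1.0, b=2.0, **kw):
    tree = build_cable(2, 2.0)
    return TransportSystem(tree, [a], [b], **kw)


class TestAssembleGenerator:
    def test_two_compartment_symmetric(self):
        A = assemble_generator(two_comp(0.5, 0.5)).toarray()
        assert np.allclose(A, [[-0.5, 0.5], [0.5, -0.5]])

    def test_column_sums_vanish_on_random_systems(self, rng):
        for reversible in (False, True):
            for _ in range(5):
                sys_ = random_system(rng, int(rng.integers(3, 40)), reversible=reversible)
                A = assemble_generator(sys_)
                assert np.abs(np.asarray(A.sum(axis=0))).max() < 1e-12

    def test_unbranched_cable_is_tridiagonal(self):
        tree = build_cable(5, 5.0)
        sys_ = TransportSystem(tree, np.full(4, 0.3), np.full(4, 0.7))
        A = assemble_generator(sys_).toarray()
        assert A.shape == (5, 5)  # bound block only when no detachment
        off = np.abs(np.triu(A, 2)) + np.abs(np.tril(A, -2))
        assert off.max() == 0

    def test_full_size_with_detachment(self, rng):
        sys_ = random_system(rng, 7, reversible=True)
        assert assemble_generator(sys_).shape == (14, 14)


class TestEvolve:
    def test_time_zero_returns_initial_state(self, rng):
        sys_ = random_system(rng, 10, reversible=True)
        traj = evolve(sys_, [0.0, 1.0])
        assert np.allclose(traj.u[:, 0], sys_.u0)
        assert np.allclose(traj.ustar[:, 0], sys_.ustar0)

    def test_uniform_detachment_exponential_decay(self, rng):
        # trafficking conserves bound mass, so uniform irreversible
        # detachment empties the bound pool as exp(-c t) exactly
        sys_ = random_system(rng, 15)
        c = 0.07
        sys_ = TransportSystem(sys_.tree, sys_.a, sys_.b, c=np.full(15, c), u0=sys_.u0)
        times = np.array([1.0, 5.0, 20.0])
        traj = evolve(sys_, times)
        total0 = sys_.u0.sum()
        assert np.allclose(traj.u.sum(axis=0), total0 * np.exp(-c * times), rtol=1e-8)

    def test_two_compartment_ratio_approaches_b_over_a(self):
        traj = evolve(two_comp(a=1.0, b=2.0), [200.0])
        assert traj.u[0, -1] / traj.u[1, -1] == pytest.approx(2.0, rel=1e-6)

    def test_mass_conserved_along_trajectories(self, rng):
        for reversible in (False, True):
            sys_ = random_system(rng, 20, reversible=reversible)
            traj = evolve(sys_, log_times(0.1, 1e4, 20))
            assert np.allclose(traj.total_mass, sys_.total_mass, rtol=1e-8)

    def test_matches_explicit_integration_oracle(self, rng):
        # independent route: generic non-stiff ODE integration at tight tol
        for reversible in (False, True):
            sys_ = random_system(rng, int(rng.integers(5, 50)), reversible=reversible)
            A = assemble_generator(sys_).toarray()
            s0 = np.concatenate([sys_.u0, sys_.ustar0])[: A.shape[0]]
            times = [0.5, 2.0, 10.0]
            sol = solve_ivp(
                lambda t, y: A @ y, (0, times[-1]), s0, t_eval=times,
                rtol=1e-10, atol=1e-12, method="DOP853",
            )
            traj = evolve(sys_, times)
            n = sys_.n
            got = np.vstack([traj.u, traj.ustar])[: A.shape[0]]
            scale = np.abs(sol.y).max()
            assert np.abs(got - sol.y).max() < 1e-6 * scale

    def test_rejects_bad_times(self, rng):
        sys_ = random_system(rng, 5)
        with pytest.raises(ValueError):
            evolve(sys_, [2.0, 1.0])
        with pytest.raises(ValueError):
            evolve(sys_, [-1.0, 1.0])


class TestSteadyState:
    def test_uniform_rates_give_uniform_distribution(self, rng):
        sys_ = random_system(rng, 12)
        sys_ = TransportSystem(sys_.tree, np.full(11, 0.4), np.full(11, 0.4), u0=sys_.u0)
        u, _ = steady_state(sys_)
        assert np.allclose(u, u[0])

    def test_parent_child_ratio_on_random_trees(self, rng):
        # steady-state flux balance: u_parent / u_child = b / a on every edge
        for _ in range(8):
            sys_ = random_system(rng, int(rng.integers(3, 50)))
            u, _ = steady_state(sys_)
            p, c = sys_.tree.edges.T
            assert np.allclose(u[p] / u[c], sys_.b / sys_.a, rtol=1e-8)

    def test_linear_gradient_from_index_ratio_rates(self):
        # b_i / a_i = i / (i+1) produces u_i proportional to i (1-based)
        n = 60
        tree = build_cable(n, float(n))
        i = np.arange(1, n)
        b_over_a = i / (i + 1)
        a = 1.0 / (1.0 + b_over_a)
        sys_ = TransportSystem(tree, a, 1.0 - a)
        u, _ = steady_state(sys_)
        expected = np.arange(1, n + 1) / np.arange(1, n + 1).sum()
        assert np.allclose(u, expected, rtol=1e-8)

    def test_reversible_pool_ratio(self, rng):
        tree = build_cable(10, 10.0)
        sys_ = TransportSystem(tree, np.full(9, 0.5), np.full(9, 0.5),
                               c=np.full(10, 2.0), d=np.full(10, 1.0))
        u, ustar = steady_state(sys_)
        assert np.allclose(ustar / u, 2.0)
        assert u.sum() / (u.sum() + ustar.sum()) == pytest.approx(1 / 3)

    def test_reversible_ratio_on_random_systems(self, rng):
        for _ in range(5):
            sys_ = random_system(rng, 15, reversible=True)
            u, ustar = steady_state(sys_)
            assert np.allclose(ustar / u, sys_.c / sys_.d, rtol=1e-8)
            assert u.sum() + ustar.sum() == pytest.approx(sys_.total_mass)

    def test_scales_linearly_with_total_cargo(self, rng):
        sys_ = random_system(rng, 8)
        u1, _ = steady_state(sys_)
        u2, _ = steady_state(sys_.with_initial(u0=2 * sys_.u0))
        assert np.allclose(u2, 2 * u1)

    def test_matches_long_time_evolution(self, rng):
        sys_ = random_system(rng, 12, reversible=True)
        u, ustar = steady_state(sys_)
        traj = evolve(sys_, [5e4])
        assert np.allclose(traj.u[:, -1], u, rtol=1e-6, atol=1e-12)
        assert np.allclose(traj.ustar[:, -1], ustar, rtol=1e-6, atol=1e-12)

    def test_nullspace_oracle(self, rng):
        # independent route: dense nullspace of the assembled generator
        import scipy.linalg

        sys_ = random_system(rng, 20)
        u, _ = steady_state(sys_)
        A = assemble_generator(sys_).toarray()
        null = scipy.linalg.null_space(A)
        assert null.shape[1] == 1
        v = null[:, 0] * np.sign(null[:, 0].sum())
        v *= sys_.total_mass / v.sum()
        assert np.allclose(u, v, rtol=1e-8)

    def test_zero_rate_edge_is_informative_error(self):
        sys_ = two_comp(a=0.0, b=1.0)
        with pytest.raises(ValueError, match="edge 0->1"):
            steady_state(sys_)

    def test_absorbing_system_redirects(self, rng):
        sys_ = random_system(rng, 6, absorbing=True)
        with pytest.raises(ValueError, match="delivered_distribution"):
            steady_state(sys_)


class TestDeliveredDistribution:
    def test_single_compartment_collects_everything(self):
        tree = build_tree([-1], [1.0])
        sys_ = TransportSystem(tree, [], [], c=[0.3], u0=[2.0])
        assert delivered_distribution(sys_) == pytest.approx([2.0])

    def test_matches_long_time_evolution(self, rng):
        import scipy.linalg

        from sushibelt.transport import _bound_generator

        for _ in range(4):
            sys_ = random_system(rng, 20, absorbing=True)
            dlv = delivered_distribution(sys_)
            # horizon: 20 e-foldings of the slowest absorption mode
            M = _bound_generator(sys_, include_detachment=True).toarray()
            rate = np.abs(scipy.linalg.eigvals(M).real).min()
            traj = evolve(sys_, [20.0 / rate])
            assert np.abs(dlv - traj.ustar[:, -1]).max() < 1e-4 * sys_.total_mass

    def test_sums_to_total_mass(self, rng):
        sys_ = random_system(rng, 25, absorbing=True)
        assert delivered_distribution(sys_).sum() == pytest.approx(sys_.total_mass, rel=1e-8)

    def test_no_absorber_is_error(self, rng):
        sys_ = random_system(rng, 5)
        with pytest.raises(ValueError, match="absorbing"):
            delivered_distribution(sys_)


class TestConvergenceTimescale:
    def test_two_compartment_hand_eigendecomposition(self):
        # generator [[-.5,.5],[.5,-.5]] has eigenvalues {0, -1}
        assert convergence_timescale(two_comp(0.5, 0.5)) == pytest.approx(1.0)

    def test_bottleneck_scaling(self):
        tau1 = convergence_timescale(three_compartment_bottleneck(0.01))
        tau2 = convergence_timescale(three_compartment_bottleneck(0.005))
        assert tau2 / tau1 == pytest.approx(2.0, rel=0.02)
        assert convergence_timescale(three_compartment_bottleneck(1e-6)) > 1e5

    def test_matches_simulated_relaxation(self, rng):
        # e-folding of the worst-compartment deviation tracks 1/|lambda_2|
        for _ in range(4):
            n = int(rng.integers(5, 25))
            tree = build_cable(n, float(n))
            sys_ = TransportSystem(
                tree, rng.uniform(0.2, 1.5, n - 1), rng.uniform(0.2, 1.5, n - 1),
                u0=rng.uniform(0.0, 1.0, n),
            )
            tau = convergence_timescale(sys_)
            u_ss, _ = steady_state(sys_)
            times = np.linspace(tau, 6 * tau, 60)
            traj = evolve(sys_, times)
            dev = np.abs(traj.u - u_ss[:, None]).max(axis=0)
            keep = dev > 1e-12
            slope = np.polyfit(times[keep], np.log(dev[keep]), 1)[0]
            assert -1.0 / slope == pytest.approx(tau, rel=0.2)

    def test_rejects_detachment(self, rng):
        with pytest.raises(ValueError):
            convergence_timescale(random_system(rng, 5, reversible=True))


class TestPerCompartmentDelay:
    def test_soma_above_threshold_at_time_zero(self):
        sys_ = two_comp()
        traj = evolve(sys_, [0.0, 1.0, 2.0])
        delays = per_compartment_delay(traj, 0.5)
        assert delays[0] == 0.0

    def test_nondecreasing_in_threshold(self, rng):
        sys_ = random_system(rng, 10)
        traj = evolve(sys_, log_times(0.1, 100, 30))
        d1 = per_compartment_delay(traj, 0.01)
        d2 = per_compartment_delay(traj, 0.05)
        assert np.all(d2 >= d1)

    def test_unreachable_threshold_is_inf(self):
        traj = evolve(two_comp(), [1.0, 2.0])
        assert np.all(np.isinf(per_compartment_delay(traj, 100.0)))

    def test_bottleneck_shifts_delays(self):
        # a mid-cable bottleneck speeds up proximal accumulation and slows
        # distal accumulation relative to the uniform-demand cable
        from sushibelt import StrategyConfig, ddt
        from sushibelt.demand import bottleneck_profile
        from sushibelt.strategies import DemandProfile

        n = 30
        tree = build_cable(n, float(n))
        cfg = StrategyConfig(normalization="unit")
        uniform = ddt(DemandProfile(np.ones(n)), tree, cfg)
        bneck = ddt(bottleneck_profile(n, (10, 20), 10.0), tree, cfg)
        times = log_times(0.1, 1e6, 200)
        thr = 1e-3
        d_uni = per_compartment_delay(evolve(uniform, times), thr)
        d_bot = per_compartment_delay(evolve(bneck, times), thr)
        assert np.all(d_bot[1:10] <= d_uni[1:10])
        assert np.all(d_bot[20:] >= d_uni[20:])


def test_invalid_rates_rejected():
    with pytest.raises(ValueError):
        two_comp(a=-1.0)
    with pytest.raises(ValueError):
        two_comp(a=np.nan)
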