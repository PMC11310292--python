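import numpy as np
import pytest

import endoctrl as ec
from endoctrl.ocp import _backward_rk4, _forward_rk4


def small_problem(params, weights=(1.0, 1.0, 1.0), tf=5.0, dt=0.05,
                  init=(500.0, 20.0, 300.0, 100.0), bounds=(0.0, 0.99)):
    return ec.OCPProblem(params=params, init=init, t0=0.0, tf=tf,
                         weights=weights, bounds=bounds, grid_dt=dt)


class TestCost:
    def test_zero_state_zero_control(self, ia):
        _, params = ia
        prob = small_problem(params, tf=25.0, dt=0.5)
        n = prob.grid.size
        assert ec.cost(prob, np.zeros((n, 4)), np.zeros(n)) == 0.0

    def test_closed_form_quadratic_term(self, ia):
        # with S=R=0 and u=u_b=0.99 over 25 days, J = 25*u_b^2/2
        _, params = ia
        prob = small_problem(params, tf=25.0, dt=0.05)
        n = prob.grid.size
        J = ec.cost(prob, np.zeros((n, 4)), np.full(n, 0.99))
        assert J == pytest.approx(12.25125, rel=1e-12)

    def test_linearity_in_weights(self, ia):
        _, params = ia
        rng = np.random.default_rng(0)
        prob1 = small_problem(params, weights=(1.0, 2.0, 3.0), tf=5.0, dt=0.5)
        prob2 = small_problem(params, weights=(2.0, 4.0, 6.0), tf=5.0, dt=0.5)
        n = prob1.grid.size
        X = rng.uniform(0, 100, (n, 4))
        u = rng.uniform(0, 0.9, n)
        assert ec.cost(prob2, X, u) == pytest.approx(2 * ec.cost(prob1, X, u))

    def test_grid_mismatch_rejected(self, ia):
        _, params = ia
        prob = small_problem(params, tf=5.0, dt=0.5)
        with pytest.raises(ValueError):
            ec.cost(prob, np.zeros((3, 4)), np.zeros(3))


class TestProjectControl:
    @pytest.mark.parametrize("raw, expected", [
        (1.5, 0.99),     # upper clip
        (-0.2, 0.0),     # lower clip
        (0.5, 0.5),      # interior
    ])
    def test_clipping(self, ia, raw, expected):
        _, params = ia
        prob = small_problem(params)
        lam3 = raw / (params.r * 100.0)   # so r*F*lam3/wu == raw at F=100
        assert ec.project_control(lam3, 100.0, prob) == pytest.approx(expected)


class TestAdjointRhs:
    def test_terminal_derivative(self, ia):
        # at lambda = 0 the costate equations reduce to the running-cost
        # gradients
        _, params = ia
        prob = small_problem(params, weights=(2.0, 3.0, 1.0))
        d = ec.adjoint_rhs(5.0, np.zeros(4), [100.0, 10.0, 15.0, 120.0], 0.3,
                           prob)
        np.testing.assert_allclose(d, [-2.0, -3.0, 0.0, 0.0])

    def test_zero_fixed_point_without_tumor_weights(self, ia):
        _, params = ia
        prob = small_problem(params, weights=(0.0, 0.0, 1.0))
        d = ec.adjoint_rhs(0.0, np.zeros(4), [0.0, 0.0, 15.0, 120.0], 0.0, prob)
        np.testing.assert_allclose(d, 0.0, atol=1e-15)

    def test_gradient_consistency(self, ia):
        # adjoint-based gradient of the discrete cost w.r.t. a control node
        # equals the central finite difference (interior nodes)
        _, params = ia
        prob = ec.OCPProblem(params=params, init=(500.0, 20.0, 300.0, 100.0),
                             t0=14.0, tf=19.0, grid_dt=0.02)
        grid = prob.grid
        u = np.full(grid.size, 0.5)
        sub = 4
        X = _forward_rk4(prob, u, sub)
        lam = _backward_rk4(prob, X, u, sub)
        w = np.gradient(grid).astype(float)
        w[0] /= 2; w[-1] /= 2
        g_adj = w * (1.0 * u - params.r * X[:, 3] * lam[:, 2])
        h = 1e-5
        for i in (30, 120, 200):
            up = u.copy(); up[i] += h
            um = u.copy(); um[i] -= h
            fd = (ec.cost(prob, _forward_rk4(prob, up, sub), up)
                  - ec.cost(prob, _forward_rk4(prob, um, sub), um)) / (2 * h)
            assert g_adj[i] == pytest.approx(fd, rel=1e-3)


class TestForwardSolver:
    def test_matches_adaptive_solver(self, ia):
        # the fixed-step RK4 used inside the sweep agrees with the adaptive
        # stiff integrator under a constant dose
        sc, params = ia
        prob = ec.OCPProblem(params=params, init=(500.0, 0.0, 300.0, 100.0),
                             t0=14.0, tf=25.0, grid_dt=0.05)
        u = np.full(prob.grid.size, 0.9)
        X = _forward_rk4(prob, u, substeps=2)
        ref = ec.integrate("extended", params, [500.0, 0.0, 300.0, 100.0],
                           (14.0, 25.0),
                           schedule=ec.ControlSchedule.constant(0.9),
                           grid_dt=0.05)
        scale = np.maximum(np.abs(ref.states), 1e-3)
        assert np.max(np.abs(X - ref.states) / scale) < 1e-4


class TestFBS:
    def test_huge_control_weight_gives_no_treatment(self, ia):
        _, params = ia
        prob = small_problem(params, weights=(1.0, 1.0, 1e9), tf=5.0)
        sol = ec.fbs_solve(prob)
        assert np.max(sol.control) < 1e-3
        untreated = _forward_rk4(prob, np.zeros(prob.grid.size), 2)
        np.testing.assert_allclose(sol.states, untreated, rtol=1e-3, atol=1e-6)

    def test_bound_feasibility_and_terminal_control(self, ia, untreated_ia):
        sc, params = ia
        traj, t_tr = untreated_ia["CD"]
        state = np.maximum(traj.state_at(t_tr), 0.0)
        prob = ec.OCPProblem(params=params, init=tuple(state), t0=t_tr,
                             tf=sc.t_f, grid_dt=0.05)
        sol = ec.fbs_solve(prob)
        ua, ub = prob.bounds
        assert np.all(sol.control >= ua - 1e-12)
        assert np.all(sol.control <= ub + 1e-12)
        # zero terminal adjoint forces the control to the lower bound at tf
        assert sol.control[-1] == pytest.approx(ua, abs=1e-9)
        # near-maximum dosing over most of the window, decreasing at the end
        assert np.mean(sol.control[: sol.control.size // 2] > 0.9 * ub) > 0.8
        assert sol.control[-10] < sol.control[sol.control.size // 2]
        # accepted costs never increase beyond round-off
        costs = [rec["cost"] for rec in sol.iterations]
        diffs = np.diff(costs)
        assert np.all(diffs <= np.abs(costs[:-1]) * 1e-6 + 1e-9)
        # first-order stationarity: the control matches the projected
        # optimality relation clip(r*F*lambda3/omega_u) pointwise, except
        # for a lag of at most a couple of nodes where the relation kinks
        # at the bound-to-interior switch
        lam3 = sol.adjoint[:, 2]
        F = sol.states[:, 3]
        raw = params.r * F * lam3 / prob.weights[2]
        gap = np.abs(sol.control - np.clip(raw, ua, ub))
        assert np.mean(gap < 1e-2) > 0.95
        assert np.max(gap) < 0.2
        # at the upper bound the unconstrained optimum must push past it
        at_ub = sol.control > ub - 1e-6
        if at_ub.any():
            assert np.all(raw[at_ub] >= ub - 1e-3)

    def test_weight_ordering_total_dose(self, ia, untreated_ia):
        # penalizing tumor burden more than dosing prolongs treatment
        sc, params = ia
        traj, t_tr = untreated_ia["CD"]
        state = tuple(np.maximum(traj.state_at(t_tr), 0.0))
        totals = {}
        for w in ((100.0, 100.0, 1.0), (1.0, 1.0, 1.0), (1.0, 1.0, 100.0)):
            prob = ec.OCPProblem(params=params, init=state, t0=t_tr,
                                 tf=sc.t_f, weights=w, grid_dt=0.1)
            totals[w] = ec.fbs_solve(prob).total_control()
        assert totals[(100.0, 100.0, 1.0)] > totals[(1.0, 1.0, 1.0)] \
            > totals[(1.0, 1.0, 100.0)]

    def test_u_init_validation(self, ia):
        _, params = ia
        prob = small_problem(params, tf=2.0)
        with pytest.raises(ValueError):
            ec.fbs_solve(prob, u_init=np.ones(3))
        with pytest.raises(ValueError):
            ec.fbs_solve(prob, u_init=np.full(prob.grid.size, 0.999))

    def test_problem_validation(self, ia):
        _, params = ia
        with pytest.raises(ValueError):
            ec.OCPProblem(params=params, init=(1, 0, 1, 1), t0=5.0, tf=5.0)
        with pytest.raises(ValueError):
            ec.OCPProblem(params=params, init=(1, 0, 1, 1), t0=0.0, tf=5.0,
                          weights=(1.0, 1.0, 0.0))
        with pytest.raises(ValueError):
            ec.OCPProblem(params=params, init=(1, 0, 1, 1), t0=0.0, tf=5.0,
                          bounds=(0.5, 0.2))
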