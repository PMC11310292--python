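"""Quadratic optimal control of aromatase-inhibitor dosing.

The problem: over the treatment window ``[t_tr, t_f]``, choose a dose curve
``u(t)`` in ``[u_a, u_b]`` minimizing::

    J(u) = int ( omega_S*S + omega_R*R + omega_u/2 * u^2 ) dt

subject to the extended sensitive/resistant model with estrogen production
scaled by ``(1-u)``.  Pontryagin's principle yields a four-component
adjoint system terminating at zero, and the projected optimality condition

    u* = min(u_b, max(u_a, r*F*lambda3 / omega_u)).

The solver is a forward-backward sweep (FBS): repeat a forward state solve,
a backward adjoint solve and a pointwise control update, damping the update
by a "greedy" convex combination ``u_s = (1-s)*u_prev + s*u_new`` whose
step ``s`` is chosen each iteration to minimize the cost, until state,
adjoint and control all change by less than a relative tolerance.

State and adjoint solves use fixed-step classical Runge-Kutta on the
control grid (the standard discretization for FBS), with the control
interpolated linearly inside a step; this keeps the many line-search
solves cheap while agreeing with the adaptive stiff solver to well below
the sweep tolerance at the default step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .models import _ext_rhs_scalar, _hill, growth_rate
from .params import ExtParams, ExtState
from .simulate import Trajectory

__all__ = [
    "OCPProblem",
    "OCPSolution",
    "cost",
    "adjoint_rhs",
    "project_control",
    "fbs_solve",
    "solve_direct",
]


@dataclass(frozen=True)
class OCPProblem:
    """Optimal-dosing problem on the window ``[t0, tf]``.

    weights : ``(omega_S, omega_R, omega_u)`` — running costs of sensitive
        burden, resistant burden and (squared) dose; ``omega_u`` must be
        positive because the control law divides by it.
    bounds : ``(u_a, u_b)`` admissible dose interval, ``0 <= u_a < u_b < 1``.
    grid_dt : control discretization step (days).
    """

    params: ExtParams
    init: ExtState | tuple[float, float, float, float]
    t0: float
    tf: float
    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    bounds: tuple[float, float] = (0.0, 0.99)
    grid_dt: float = 0.05

    def __post_init__(self) -> None:
        if not self.t0 < self.tf:
            raise ValueError("need t0 < tf")
        wS, wR, wu = self.weights
        if wS < 0 or wR < 0:
            raise ValueError("state weights must be non-negative")
        if wu <= 0:
            raise ValueError("control weight omega_u must be positive")
        ua, ub = self.bounds
        if not 0.0 <= ua < ub < 1.0:
            raise ValueError("bounds must satisfy 0 <= u_a < u_b < 1")

    @property
    def grid(self) -> np.ndarray:
        n = max(int(round((self.tf - self.t0) / self.grid_dt)), 1)
        return np.linspace(self.t0, self.tf, n + 1)

    def init_array(self) -> np.ndarray:
        if hasattr(self.init, "as_array"):
            return self.init.as_array()
        return np.asarray(self.init, dtype=float)


@dataclass
class OCPSolution:
    """Converged (or best-found) dose schedule with its state and adjoint."""

    times: np.ndarray
    control: np.ndarray
    states: np.ndarray
    adjoint: np.ndarray
    cost: float
    iterations: list[dict] = field(default_factory=list)
    converged: bool = False

    def trajectory(self) -> Trajectory:
        u = np.clip(self.control, 0.0, np.nextafter(1.0, 0.0))
        return Trajectory(times=self.times, states=self.states,
                          columns=("S", "R", "E", "F"), control=u)

    def total_control(self) -> float:
        """Cumulative administered dose ``int u dt``."""
        return float(np.trapezoid(self.control, self.times))


def cost(problem: OCPProblem, states: np.ndarray, u: np.ndarray,
         times: np.ndarray | None = None) -> float:
    """Running cost by composite trapezoidal quadrature on the grid."""
    times = problem.grid if times is None else times
    if states.shape[0] != times.size or u.size != times.size:
        raise ValueError("states/control must share the time grid")
    wS, wR, wu = problem.weights
    integrand = wS * states[:, 0] + wR * states[:, 1] + 0.5 * wu * u**2
    return float(np.trapezoid(integrand, times))


def project_control(lambda3, F, problem: OCPProblem):
    """Pointwise optimal dose ``clip(r*F*lambda3/omega_u, u_a, u_b)``."""
    wu = problem.weights[2]
    raw = problem.params.r * np.asarray(F, float) * np.asarray(lambda3, float) / wu
    ua, ub = problem.bounds
    out = np.clip(raw, ua, ub)
    return float(out) if out.ndim == 0 else out


def _adjoint_rhs_scalar(lam, state, u, p: ExtParams, wS, wR):
    """Costate derivative; steep-Hill derivatives via (l/E)*h*(1-h)."""
    l1, l2, l3, l4 = lam
    S, R, E, F = (x if x > 0.0 else 0.0 for x in state)
    g = growth_rate(E, p.k1, p.a1)
    gp = p.k1 * p.a1 / (p.a1 + E) ** 2
    h2 = _hill(E, p.a2, p.l)
    h3 = _hill(E, p.a3, p.l)
    if E > 0.0:
        dh2 = (p.l / E) * h2 * (1.0 - h2)   # = l*a2^l*E^(l-1)/(a2^l+E^l)^2
        dh3 = (p.l / E) * h3 * (1.0 - h3)
    else:
        dh2 = dh3 = 0.0                     # E^(l-1) -> 0 for l > 1
    crowd = 1.0 - p.m1 * (S + p.eta * R)
    dl1 = (-wS
           - l1 * (g * (1.0 - p.m1 * (2.0 * S + p.eta * R)) - p.c * h2 - p.c * h3)
           + l2 * (p.m1 * p.k3 * R - p.c * h3)
           + l4 * p.alpha * F)
    dl2 = (-wR
           + l1 * g * p.m1 * p.eta * S
           - l2 * p.k3 * (1.0 - p.m1 * (S + 2.0 * p.eta * R))
           + l4 * p.alpha * F)
    dl3 = (-l1 * (S * crowd * gp + p.c * (dh2 + dh3) * S)
           + l2 * p.c * dh3 * S
           + l3 * p.mu)
    dl4 = (-l3 * (1.0 - u) * p.r
           - l4 * (p.k2 - 2.0 * p.k2 * p.m2 * F - p.alpha * (S + R)))
    return dl1, dl2, dl3, dl4


def adjoint_rhs(t: float, lam, state, u: float, problem: OCPProblem):
    """Time derivative of the adjoint (costate) variables.

    ``state`` is the forward solution interpolated at ``t``; terminal
    condition is ``lambda(tf) = 0``.
    """
    wS, wR, _ = problem.weights
    out = _adjoint_rhs_scalar(tuple(float(x) for x in lam),
                              tuple(float(x) for x in state),
                              float(u), problem.params, wS, wR)
    return np.array(out)


def _forward_rk4(problem: OCPProblem, u: np.ndarray, substeps: int) -> np.ndarray:
    """Fixed-step RK4 forward solve; control linear between grid nodes."""
    grid = problem.grid
    p = problem.params
    n = grid.size
    X = np.empty((n, 4))
    X[0] = problem.init_array()
    y = tuple(float(v) for v in X[0])
    for i in range(n - 1):
        dt = grid[i + 1] - grid[i]
        h = dt / substeps
        u0, u1 = u[i], u[i + 1]
        for k in range(substeps):
            f0 = (k * h) / dt
            fm = ((k + 0.5) * h) / dt
            f1 = ((k + 1.0) * h) / dt
            ua_ = u0 + (u1 - u0) * f0
            um_ = u0 + (u1 - u0) * fm
            ub_ = u0 + (u1 - u0) * f1
            k1 = _ext_rhs_scalar(*y, ua_, p)
            y2 = tuple(y[j] + 0.5 * h * k1[j] for j in range(4))
            k2 = _ext_rhs_scalar(*y2, um_, p)
            y3 = tuple(y[j] + 0.5 * h * k2[j] for j in range(4))
            k3 = _ext_rhs_scalar(*y3, um_, p)
            y4 = tuple(y[j] + h * k3[j] for j in range(4))
            k4 = _ext_rhs_scalar(*y4, ub_, p)
            y = tuple(y[j] + h / 6.0 * (k1[j] + 2 * k2[j] + 2 * k3[j] + k4[j])
                      for j in range(4))
        X[i + 1] = y
    return X


def _backward_rk4(problem: OCPProblem, states: np.ndarray, u: np.ndarray,
                  substeps: int) -> np.ndarray:
    """Fixed-step RK4 backward adjoint solve with terminal condition zero.

    The forward state and the control are interpolated linearly between
    grid nodes when the integrator needs off-grid values.
    """
    grid = problem.grid
    p = problem.params
    wS, wR, _ = problem.weights
    n = grid.size
    lam = np.empty((n, 4))
    lam[-1] = 0.0
    y = (0.0, 0.0, 0.0, 0.0)

    def interp(i: int, frac: float):
        """State/control at fraction ``frac`` of interval [i, i+1]."""
        x = states[i] + (states[i + 1] - states[i]) * frac
        uu = u[i] + (u[i + 1] - u[i]) * frac
        return tuple(float(v) for v in x), float(uu)

    for i in range(n - 1, 0, -1):
        dt = grid[i] - grid[i - 1]
        h = dt / substeps
        for k in range(substeps):
            # integrating backward from node i toward node i-1
            f0 = 1.0 - (k * h) / dt
            fm = 1.0 - ((k + 0.5) * h) / dt
            f1 = 1.0 - ((k + 1.0) * h) / dt
            x0, u0 = interp(i - 1, f0)
            xm, um = interp(i - 1, max(fm, 0.0))
            x1, u1 = interp(i - 1, max(f1, 0.0))
            k1 = _adjoint_rhs_scalar(y, x0, u0, p, wS, wR)
            y2 = tuple(y[j] - 0.5 * h * k1[j] for j in range(4))
            k2 = _adjoint_rhs_scalar(y2, xm, um, p, wS, wR)
            y3 = tuple(y[j] - 0.5 * h * k2[j] for j in range(4))
            k3 = _adjoint_rhs_scalar(y3, xm, um, p, wS, wR)
            y4 = tuple(y[j] - h * k3[j] for j in range(4))
            k4 = _adjoint_rhs_scalar(y4, x1, u1, p, wS, wR)
            y = tuple(y[j] - h / 6.0 * (k1[j] + 2 * k2[j] + 2 * k3[j] + k4[j])
                      for j in range(4))
        lam[i - 1] = y
    return lam


def _rel_err(cur: np.ndarray, prev: np.ndarray, eps: float = 1e-12) -> float:
    """L1 relative change ``|cur - prev|_1 / max(|cur|_1, eps)``."""
    return float(np.abs(cur - prev).sum() / max(np.abs(cur).sum(), eps))


_DEFAULT_S_GRID = (0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5,
                   0.6, 0.7, 0.8, 0.9, 0.95, 0.99)


def fbs_solve(problem: OCPProblem, u_init: np.ndarray | None = None,
              tol: float = 1e-5, max_iter: int = 200,
              s_grid: tuple[float, ...] = _DEFAULT_S_GRID,
              substeps: int = 2) -> OCPSolution:
    """Forward-backward sweep with greedy convex-combination damping.

    Each iteration: (i) forward state solve with the previous control,
    (ii) backward adjoint solve, (iii) pointwise projected-control update,
    (iv) line search over ``s_grid`` for the convex combination
    ``u_s = (1-s)*u_prev + s*u_new`` minimizing the cost (the small-``s``
    candidates act as a near-no-move fallback, keeping accepted costs from
    increasing).  Stops when the L1 relative changes of control, state and
    adjoint all drop below ``tol``; otherwise returns the best-cost iterate
    with ``converged=False`` and a warning.
    """
    grid = problem.grid
    ua, ub = problem.bounds
    if u_init is None:
        u = np.full(grid.size, ua, dtype=float)
    else:
        u = np.asarray(u_init, dtype=float)
        if u.size != grid.size:
            raise ValueError("u_init must live on the problem grid")
        if np.any((u < ua - 1e-12) | (u > ub + 1e-12)):
            raise ValueError("u_init violates the control bounds")

    X = _forward_rk4(problem, u, substeps)
    lam = _backward_rk4(problem, X, u, substeps)
    J = cost(problem, X, u)
    best = {"J": J, "u": u.copy(), "X": X.copy(), "lam": lam.copy()}
    log: list[dict] = []
    converged = False

    for it in range(max_iter):
        u_cand = project_control(lam[:, 2], X[:, 3], problem)
        # greedy line search over the convex-combination step
        best_s, best_J, best_u, best_X = None, np.inf, None, None
        for s in s_grid:
            u_s = (1.0 - s) * u + s * u_cand
            X_s = _forward_rk4(problem, u_s, substeps)
            J_s = cost(problem, X_s, u_s)
            if J_s < best_J:
                best_s, best_J, best_u, best_X = s, J_s, u_s, X_s
        lam_new = _backward_rk4(problem, best_X, best_u, substeps)
        errs = {"control": _rel_err(best_u, u),
                "state": _rel_err(best_X, X),
                "adjoint": _rel_err(lam_new, lam)}
        log.append({"iteration": it, "s": best_s, "cost": best_J, **errs})
        u, X, lam, J = best_u, best_X, lam_new, best_J
        if J < best["J"]:
            best = {"J": J, "u": u.copy(), "X": X.copy(), "lam": lam.copy()}
        if max(errs.values()) < tol:
            converged = True
            break

    if not converged:
        warnings.warn("FBS did not reach the relative-error tolerance "
                      f"{tol:g} in {max_iter} iterations; returning the "
                      "best-cost iterate", RuntimeWarning, stacklevel=2)
    return OCPSolution(times=grid, control=best["u"], states=best["X"],
                       adjoint=best["lam"], cost=best["J"],
                       iterations=log, converged=converged)


def solve_direct(problem: OCPProblem, u0: np.ndarray | None = None,
                 substeps: int = 8, maxiter: int = 500) -> OCPSolution:
    """Direct transcription: bounded quasi-Newton optimization over the
    discretized control vector.

    Independent of the sweep iteration (no adjoint involved; gradients by
    finite differences inside L-BFGS-B), hence useful as a cross-check of
    :func:`fbs_solve` on coarse grids.  Cost grows quickly with grid size.
    """
    from scipy.optimize import minimize

    grid = problem.grid
    ua, ub = problem.bounds
    x0 = np.full(grid.size, 0.5 * (ua + ub)) if u0 is None \
        else np.asarray(u0, dtype=float)

    def J(uvec: np.ndarray) -> float:
        X = _forward_rk4(problem, uvec, substeps)
        return cost(problem, X, uvec)

    res = minimize(J, x0, method="L-BFGS-B",
                   bounds=[(ua, ub)] * grid.size,
                   options={"maxiter": maxiter})
    u = np.asarray(res.x, dtype=float)
    X = _forward_rk4(problem, u, substeps)
    lam = _backward_rk4(problem, X, u, substeps)
    return OCPSolution(times=grid, control=u, states=X, adjoint=lam,
                       cost=float(res.fun), iterations=[],
                       converged=bool(res.success))
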