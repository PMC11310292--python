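"""Time integration of the tumor models with optional dosing schedules.

A :class:`ControlSchedule` describes the aromatase-inhibitor control signal
``u(t)``: none, constant, an alternating (square-wave) schedule of on/off
phases, or an arbitrary tabulated curve.  :func:`integrate` solves either
model over a time window with a stiff-capable solver, segmenting the
integration at schedule discontinuities so jumps are never smoothed over,
and samples the solution on a uniform grid.

:func:`detect_treatment_start` implements the detectable-size rule used in
the treatment study: therapy begins the first time the composite tumor
burden ``S + eta*R`` grows through one quarter of the carrying capacity,
``1/(4*m1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .models import base_rhs, ext_rhs
from .params import BaseParams, BaseState, ExtParams, ExtState

__all__ = [
    "ControlSchedule",
    "Trajectory",
    "IntegrationError",
    "integrate",
    "detect_treatment_start",
    "steady_state_estrogen",
]

BASE_COLUMNS = ("T", "E", "F")
EXT_COLUMNS = ("S", "R", "E", "F")


class IntegrationError(RuntimeError):
    """Raised when the ODE solver fails (e.g. step-size collapse)."""


@dataclass(frozen=True)
class ControlSchedule:
    """Dosing schedule for the control ``u(t)`` in [0, 1).

    kind : {"none", "constant", "alternating", "tabulated"}
    u_b : on-level of the constant / alternating schedule
    phase_on, phase_off : lengths (days) of the alternating on/off phases
    start : day the schedule is switched on (before it, ``u = 0``)
    table : ``(times, values)`` arrays for a tabulated (piecewise-linear) control
    """

    kind: str = "none"
    u_b: float = 0.0
    phase_on: float = 1.0
    phase_off: float = 1.0
    start: float = 0.0
    table: tuple | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"none", "constant", "alternating", "tabulated"}:
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if not 0.0 <= self.u_b < 1.0:
            raise ValueError("u_b must lie in [0, 1)")
        if self.kind == "alternating" and (self.phase_on <= 0 or self.phase_off <= 0):
            raise ValueError("alternating phases must be positive")
        if self.kind == "tabulated":
            if self.table is None:
                raise ValueError("tabulated schedule requires a table")
            t, v = self.table
            if len(t) != len(v):
                raise ValueError("table times and values differ in length")
            if np.any((np.asarray(v) < 0) | (np.asarray(v) >= 1)):
                raise ValueError("tabulated control values must lie in [0, 1)")

    @classmethod
    def none(cls) -> "ControlSchedule":
        return cls(kind="none")

    @classmethod
    def constant(cls, u: float, start: float = 0.0) -> "ControlSchedule":
        return cls(kind="constant", u_b=u, start=start)

    @classmethod
    def alternating(cls, u_b: float = 0.99, phase_on: float = 1.0,
                    phase_off: float = 1.0, start: float = 0.0) -> "ControlSchedule":
        return cls(kind="alternating", u_b=u_b, phase_on=phase_on,
                   phase_off=phase_off, start=start)

    @classmethod
    def tabulated(cls, times, values) -> "ControlSchedule":
        return cls(kind="tabulated",
                   table=(np.asarray(times, float), np.asarray(values, float)))

    def u_of(self, t) -> np.ndarray | float:
        """Control value(s) at time(s) ``t``."""
        t = np.asarray(t, dtype=float)
        if self.kind == "none":
            u = np.zeros_like(t)
        elif self.kind == "constant":
            u = np.where(t >= self.start, self.u_b, 0.0)
        elif self.kind == "alternating":
            tau = t - self.start
            period = self.phase_on + self.phase_off
            phase = np.mod(tau, period)
            u = np.where((tau >= 0) & (phase < self.phase_on), self.u_b, 0.0)
        else:
            tt, vv = self.table
            u = np.interp(t, tt, vv, left=vv[0], right=vv[-1])
        return float(u) if u.ndim == 0 else u

    def switch_times(self, t0: float, t1: float) -> list[float]:
        """Discontinuity instants of ``u(t)`` strictly inside ``(t0, t1)``."""
        pts: list[float] = []
        if self.kind == "constant":
            pts = [self.start]
        elif self.kind == "alternating":
            period = self.phase_on + self.phase_off
            k = 0
            while True:
                on = self.start + k * period
                off = on + self.phase_on
                if on > t1:
                    break
                pts.extend([on, off])
                k += 1
        return sorted(p for p in pts if t0 < p < t1)


@dataclass
class Trajectory:
    """Dense, uniformly sampled solution of either model.

    ``states`` has one row per time point; ``columns`` names the state
    components ("T","E","F" or "S","R","E","F").  ``control`` carries the
    applied ``u(t)`` on the same grid (None for the basic model) and
    ``t_tr`` the treatment-start day, once detected.
    """

    times: np.ndarray
    states: np.ndarray
    columns: tuple[str, ...]
    control: np.ndarray | None = None
    t_tr: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.states.shape[0] != self.times.size:
            raise ValueError("states row count must equal times count")
        if self.control is not None:
            self.control = np.asarray(self.control, dtype=float)
            if self.control.size != self.times.size:
                raise ValueError("control length must equal times count")
            if np.any((self.control < 0) | (self.control >= 1)):
                raise ValueError("control values must lie in [0, 1)")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.states[:, self.columns.index(name)]

    @property
    def tumor_burden(self) -> np.ndarray:
        """T for the basic model; S + R for the extended model."""
        if "T" in self.columns:
            return self["T"]
        return self["S"] + self["R"]

    def state_at(self, t: float) -> np.ndarray:
        """Linear interpolation of the state at time ``t``."""
        return np.array([np.interp(t, self.times, self.states[:, j])
                         for j in range(self.states.shape[1])])

    def final_state(self) -> np.ndarray:
        return self.states[-1].copy()

    def to_frame(self, **labels: str) -> pd.DataFrame:
        """Tidy long-format frame with columns (time, variable, value, ...labels)."""
        parts = []
        for j, name in enumerate(self.columns):
            parts.append(pd.DataFrame({
                "time": self.times, "variable": name, "value": self.states[:, j]}))
        if self.control is not None:
            parts.append(pd.DataFrame({
                "time": self.times, "variable": "u", "value": self.control}))
        frame = pd.concat(parts, ignore_index=True)
        for key, val in labels.items():
            frame[key] = val
        return frame

    def write_csv(self, path: str | Path, **labels: str) -> None:
        self.to_frame(**labels).to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path) -> "Trajectory":
        frame = pd.read_csv(path)
        wide = frame.pivot_table(index="time", columns="variable", values="value")
        control = wide.pop("u").to_numpy() if "u" in wide else None
        order = [c for c in ("T", "S", "R", "E", "F") if c in wide.columns]
        return cls(times=wide.index.to_numpy(), states=wide[order].to_numpy(),
                   columns=tuple(order), control=control)


def steady_state_estrogen(F: float, r: float, mu: float) -> float:
    """Equilibrium estrogen level ``r*F/mu`` sustained by fat volume ``F``."""
    if mu <= 0:
        raise ValueError("washout rate mu must be positive")
    return r * F / mu


def _make_grid(t0: float, t1: float, grid_dt: float) -> np.ndarray:
    n = max(int(round((t1 - t0) / grid_dt)), 1)
    return np.linspace(t0, t1, n + 1)


def integrate(model: str, params: BaseParams | ExtParams, init,
              t_span: Sequence[float], schedule: ControlSchedule | None = None,
              grid_dt: float = 0.05, rtol: float = 1e-8, atol: float = 1e-10,
              method: str = "LSODA") -> Trajectory:
    """Integrate the basic or extended model over ``t_span``.

    Parameters
    ----------
    model : {"basic", "extended"}
    init : initial state (BaseState/ExtState or array-like)
    schedule : control schedule, extended model only (``None`` means untreated)
    grid_dt : sampling step of the returned trajectory (days)

    The integration is segmented at every schedule discontinuity; within a
    segment the control is smooth (constant or piecewise linear) and a
    stiff-capable solver (default LSODA) is used with tight tolerances,
    since the steep Hill switches make the treated system locally stiff.
    """
    from scipy.integrate import solve_ivp

    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t0 < t1:
        raise ValueError("t_span must satisfy t_span[0] < t_span[1]")
    if hasattr(init, "as_array"):
        y0 = init.as_array()
    else:
        y0 = np.asarray(init, dtype=float)
    if np.any(y0 < 0):
        raise ValueError("initial state must be non-negative")

    grid = _make_grid(t0, t1, grid_dt)

    if model == "basic":
        if schedule is not None and schedule.kind != "none":
            raise ValueError("the basic model takes no control schedule")
        expected = 3
        columns = BASE_COLUMNS
    elif model == "extended":
        expected = 4
        columns = EXT_COLUMNS
    else:
        raise ValueError(f"unknown model {model!r}")
    if y0.size != expected:
        raise ValueError(f"{model} model expects a state of length {expected}")

    schedule = schedule or ControlSchedule.none()
    breaks = [t0] + schedule.switch_times(t0, t1) + [t1]

    times_out: list[np.ndarray] = []
    states_out: list[np.ndarray] = []
    y = y0
    for a, b in zip(breaks[:-1], breaks[1:]):
        if model == "basic":
            rhs = lambda t, x: base_rhs(t, x, params)
        else:
            # evaluate u inside the open segment; at a switch instant the
            # right-limit value applies
            mid = 0.5 * (a + b)
            if schedule.kind == "tabulated":
                rhs = lambda t, x: ext_rhs(t, x, params,
                                           float(schedule.u_of(t)))
            else:
                u_seg = float(schedule.u_of(mid))
                rhs = lambda t, x, u=u_seg: ext_rhs(t, x, params, u)
        mask = (grid >= a - 1e-12) & (grid <= b + 1e-12)
        t_eval = np.unique(np.concatenate([[a], grid[mask], [b]]))
        sol = solve_ivp(rhs, (a, b), y, method=method, t_eval=t_eval,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise IntegrationError(
                f"solver failed on [{a:g}, {b:g}]: {sol.message}")
        keep = np.isin(sol.t, grid)
        if times_out:
            # drop duplicate of the previous segment's right endpoint
            prev_end = times_out[-1][-1]
            keep &= sol.t > prev_end + 1e-12
        times_out.append(sol.t[keep])
        states_out.append(sol.y[:, keep].T)
        y = sol.y[:, -1]

    times = np.concatenate(times_out)
    states = np.vstack(states_out)
    control = None
    if model == "extended":
        control = np.asarray(schedule.u_of(times), dtype=float)
    return Trajectory(times=times, states=states, columns=columns,
                      control=control)


def detect_treatment_start(traj: Trajectory, eta: float, m1: float,
                           threshold: float | None = None,
                           direction: str = "up") -> float | None:
    """First time the composite tumor size crosses the detection threshold.

    The composite size is ``S + eta*R`` (or ``T``); the threshold defaults
    to ``1/(4*m1)``.  ``direction="up"`` (default) returns the first upward
    crossing — a tumor growing from 1 mm^3 becomes *detectable* when it
    reaches a quarter of its carrying capacity.  ``direction="down"`` is
    the literal below-threshold reading and returns the first time the
    composite size is under the threshold.  Crossings are located by linear
    interpolation between grid points.  Returns ``None`` when the window
    never satisfies the condition.
    """
    if direction not in {"up", "down"}:
        raise ValueError("direction must be 'up' or 'down'")
    thr = 1.0 / (4.0 * m1) if threshold is None else float(threshold)
    if "T" in traj.columns:
        comp = traj["T"]
    else:
        comp = traj["S"] + eta * traj["R"]
    t = traj.times
    if direction == "down":
        below = comp < thr
        if below[0]:
            return float(t[0])
        idx = np.flatnonzero(below)
        if idx.size == 0:
            return None
        i = idx[0]
    else:
        above = comp >= thr
        if above[0]:
            return float(t[0])
        idx = np.flatnonzero(above)
        if idx.size == 0:
            return None
        i = idx[0]
    # linear interpolation on [i-1, i]
    c0, c1 = comp[i - 1], comp[i]
    if c1 == c0:
        return float(t[i])
    frac = (thr - c0) / (c1 - c0)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))
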