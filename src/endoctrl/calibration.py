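"""Weighted least-squares calibration of the basic model and its
practical-identifiability diagnostics.

The experimental design only supports estimating a subset of the model
parameters.  Following the fixing strategy that makes the problem
identifiable, ``m1`` (carrying capacity), ``mu`` (estrogen washout, from
the 2.8 h half-life) and ``r`` (estrogen production, from the steady-state
estrogen/fat ratio) are held fixed by default, while ``k1``, ``a1`` and
``alpha`` are fitted in log10 space with box bounds, multistart.  Initial
estrogen per arm is never fitted: it is tied to the arm's initial fat
volume by the steady state ``E0 = r*F0/mu``.

Identifiability is assessed by profile likelihood: one parameter is scanned
over a log-spaced grid while the others are re-optimized; the parameter is
practically identifiable when the profile rises above the minimum by the
chi-square threshold on both sides within the bounds.

The module also carries the small analytic derivations used to fix
parameters: washout rate from a half-life, spherical tumor volume from a
caliper diameter, and the admissible range for the estrogen production
rate implied by observed estrogen levels.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares
from scipy.stats import qmc

from .datagen import MeasurementSet
from .models import base_rhs
from .params import BaseParams

__all__ = [
    "CalibrationSpec",
    "FitResult",
    "ProfileResult",
    "objective",
    "fit",
    "profile_likelihood",
    "washout_from_halflife",
    "sphere_volume",
    "admissible_r_range",
]

_ALL_PARAMS = ("k1", "a1", "m1", "r", "mu", "alpha")
#: finite penalty returned when the ODE solve fails at proposed parameters,
#: so bounded optimizers can back out rather than crash
FAILURE_PENALTY = 1e12
_FAILURE_RESIDUAL = 1e6


# ---------------------------------------------------------------------------
# analytic derivations


def washout_from_halflife(t_half_hours: float) -> float:
    """Washout rate (1/day) from a tissue half-life in hours: ``ln2/t_half * 24``."""
    if t_half_hours <= 0:
        raise ValueError("half-life must be positive")
    return math.log(2.0) / t_half_hours * 24.0


def sphere_volume(diameter_mm: float) -> float:
    """Volume (mm^3) of a spherical tumor of the given caliper diameter: ``pi/6 d^3``."""
    if diameter_mm < 0:
        raise ValueError("diameter must be non-negative")
    return math.pi / 6.0 * diameter_mm**3


def admissible_r_range(E_low: float, E_high: float, mu: float,
                       F0_list: Sequence[float]) -> tuple[float, float] | None:
    """Intersection of the per-arm ranges for the estrogen production rate.

    If estrogen starts at its steady state ``E = r*F0/mu`` and plausibly
    lies in ``[E_low, E_high]``, each initial fat volume ``F0`` confines
    ``r`` to ``[E_low*mu/F0, E_high*mu/F0]``.  Returns the intersection over
    all arms, or ``None`` when it is empty.
    """
    if not 0 < E_low < E_high:
        raise ValueError("need 0 < E_low < E_high")
    if any(f <= 0 for f in F0_list) or not F0_list:
        raise ValueError("F0 values must be positive and non-empty")
    lo = max(E_low * mu / f for f in F0_list)
    hi = min(E_high * mu / f for f in F0_list)
    if lo > hi:
        return None
    return (lo, hi)


# ---------------------------------------------------------------------------
# calibration problem


@dataclass(frozen=True)
class CalibrationSpec:
    """What to fit, what to hold fixed, and the optimization bounds.

    ``bounds`` maps a parameter name to ``(lower, upper)``; the default
    window spans eleven decades, 1e-7 to 1e4, for every free parameter.
    ``F0`` fixes the initial fat volume per arm (E0 follows from the
    steady-state relation; T0 is the implanted 1 mm^3 pellet).
    """

    free: tuple[str, ...] = ("k1", "a1", "alpha")
    fixed: Mapping[str, float] = field(
        default_factory=lambda: {"m1": 1.0 / 2000.0, "mu": 5.94, "r": 20.0})
    bounds: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    T0: float = 1.0
    F0: Mapping[str, float] = field(
        default_factory=lambda: {"CD": 50.0, "HFD": 360.0})

    def __post_init__(self) -> None:
        overlap = set(self.free) & set(self.fixed)
        if overlap:
            raise ValueError(f"parameters both free and fixed: {sorted(overlap)}")
        unknown = (set(self.free) | set(self.fixed)) - set(_ALL_PARAMS)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        for name, (lo, hi) in self.bounds.items():
            if not 0 < lo < hi:
                raise ValueError(f"bounds for {name} must be 0 < lower < upper")

    def bounds_for(self, name: str) -> tuple[float, float]:
        return tuple(self.bounds.get(name, (1e-7, 1e4)))

    def full_params(self, free_values: Mapping[str, float]) -> BaseParams:
        values = dict(BaseParams().to_dict())
        values.update(self.fixed)
        values.update(free_values)
        return BaseParams(**values)


@dataclass
class FitResult:
    """Best multistart fit: point estimates and the weighted residual sum of
    squares (chi-square-style objective)."""

    estimates: dict[str, float]
    objective: float
    n_obs: int
    converged: bool
    spec: CalibrationSpec
    starts: list[dict] = field(default_factory=list)

    def params(self) -> BaseParams:
        return self.spec.full_params(self.estimates)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "estimates": self.estimates,
            "objective": self.objective,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "free": list(self.spec.free),
            "fixed": dict(self.spec.fixed),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


@dataclass
class ProfileResult:
    """Profile-likelihood scan of one parameter.

    ``verdict`` is "identifiable" when the re-optimized objective exceeds
    ``min + threshold`` on both sides of the estimate within the bounds,
    else "lower-open", "upper-open" or "both-open".
    """

    parameter: str
    values: np.ndarray
    objectives: np.ndarray
    threshold: float
    verdict: str
    estimate: float
    min_objective: float

    def interval(self) -> tuple[float, float]:
        """Approximate confidence interval where the profile stays below
        ``min + threshold`` (bound-clipped when open)."""
        ok = self.objectives <= self.min_objective + self.threshold
        if not ok.any():
            return (self.estimate, self.estimate)
        vals = self.values[ok]
        return (float(vals.min()), float(vals.max()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.values, "objective": self.objectives,
                             "parameter": self.parameter})


def _simulate_predictions(params: BaseParams, data: MeasurementSet,
                          spec: CalibrationSpec) -> dict | None:
    """Model predictions for every (arm, variable, day) in the data.

    Returns None on solver failure.
    """
    need: dict[str, dict] = {}
    for (arm, variable, day), _ in data.records.groupby(["arm", "variable", "day"]):
        need.setdefault(arm, {}).setdefault(variable, set()).add(float(day))
    out: dict = {}
    for arm, variables in need.items():
        days = sorted(set().union(*variables.values()))
        F0 = float(spec.F0[arm])
        E0 = params.r * F0 / params.mu
        y0 = np.array([spec.T0, E0, F0])
        t_end = max(days)
        try:
            sol = solve_ivp(lambda t, y: base_rhs(t, y, params), (0.0, t_end),
                            y0, method="LSODA", t_eval=days,
                            rtol=1e-8, atol=1e-10)
        except Exception:
            return None
        if not sol.success:
            return None
        lookup = {d: j for j, d in enumerate(sol.t)}
        by_day_T = {d: sol.y[0][lookup[d]] for d in days}
        by_day_F = {d: sol.y[2][lookup[d]] for d in days}
        out[arm] = {"tumor_volume": by_day_T, "fat_volume": by_day_F}
    return out


def _effective_sd(data: MeasurementSet) -> np.ndarray:
    """Per-record residual weights.

    Recorded ``sd`` where positive; otherwise a per-(arm, variable, day)
    constant estimated from the replicate spread, with unit weight as the
    last resort (e.g. noiseless data).
    """
    rec = data.records
    sd = rec["sd"].to_numpy(dtype=float).copy()
    spread = rec.groupby(["arm", "variable", "day"])["value"].transform("std")
    spread = spread.fillna(0.0).to_numpy(dtype=float)
    bad = ~(sd > 0)
    sd[bad] = spread[bad]
    sd[~(sd > 0)] = 1.0
    return sd


def _residuals(params: BaseParams, data: MeasurementSet,
               spec: CalibrationSpec, sd: np.ndarray) -> np.ndarray:
    pred = _simulate_predictions(params, data, spec)
    if pred is None:
        return np.full(len(data.records), _FAILURE_RESIDUAL)
    rec = data.records
    model = np.array([
        pred[arm][variable][float(day)]
        for arm, variable, day in zip(rec["arm"], rec["variable"], rec["day"])
    ])
    return (rec["value"].to_numpy(dtype=float) - model) / sd


def objective(params: BaseParams | Mapping[str, float],
              data: MeasurementSet,
              spec: CalibrationSpec | None = None) -> float:
    """Weighted residual sum of squares of the basic model against ``data``.

    Both arms are simulated from their initial conditions with shared
    parameters and all tumor- and fat-volume records enter jointly.  A
    solver failure yields the large finite :data:`FAILURE_PENALTY` rather
    than an exception, so optimizers can recover.
    """
    spec = spec or CalibrationSpec()
    if isinstance(params, Mapping):
        params = spec.full_params(params)
    sd = _effective_sd(data)
    res = _residuals(params, data, spec, sd)
    if np.any(res >= _FAILURE_RESIDUAL):
        return FAILURE_PENALTY
    return float(np.dot(res, res))


class CalibrationError(RuntimeError):
    """Raised when no multistart succeeds."""


def _local_fit(x0_log: np.ndarray, data: MeasurementSet, spec: CalibrationSpec,
               free: tuple[str, ...], sd: np.ndarray):
    lo = np.log10([spec.bounds_for(n)[0] for n in free])
    hi = np.log10([spec.bounds_for(n)[1] for n in free])

    def fun(x_log: np.ndarray) -> np.ndarray:
        values = {n: 10.0**v for n, v in zip(free, x_log)}
        return _residuals(spec.full_params(values), data, spec, sd)

    return least_squares(fun, np.clip(x0_log, lo, hi), bounds=(lo, hi),
                         method="trf", xtol=1e-10, ftol=1e-10, gtol=1e-10)


def fit(data: MeasurementSet, spec: CalibrationSpec | None = None,
        n_starts: int = 25, seed: int | None = None) -> FitResult:
    """Multistart bounded least-squares fit of the free parameters.

    Optimization runs in log10 space (the bounds span eleven decades);
    start points are a Latin-hypercube sample of the log-space box,
    deterministic for a fixed ``seed``.
    """
    spec = spec or CalibrationSpec()
    free = tuple(spec.free)
    sd = _effective_sd(data)
    lo = np.log10([spec.bounds_for(n)[0] for n in free])
    hi = np.log10([spec.bounds_for(n)[1] for n in free])
    sampler = qmc.LatinHypercube(d=len(free), seed=seed)
    starts = lo + sampler.random(n_starts) * (hi - lo)

    best = None
    log: list[dict] = []
    for x0 in starts:
        try:
            res = _local_fit(x0, data, spec, free, sd)
        except Exception as exc:  # pragma: no cover - defensive
            log.append({"start": dict(zip(free, 10.0**x0)), "error": str(exc)})
            continue
        obj = float(2.0 * res.cost)
        log.append({"start": dict(zip(free, 10.0**x0)), "objective": obj,
                    "success": bool(res.success)})
        if res.success and (best is None or obj < best[0]):
            best = (obj, res)
    if best is None:
        raise CalibrationError("all multistart optimizations failed")
    obj, res = best
    estimates = {n: float(10.0**v) for n, v in zip(free, res.x)}
    return FitResult(estimates=estimates, objective=obj, n_obs=data.n_obs(),
                     converged=True, spec=spec, starts=log)


def profile_likelihood(data: MeasurementSet, spec: CalibrationSpec,
                       best: FitResult, parameter: str,
                       n_grid: int = 21, span_decades: float = 1.5,
                       threshold: float = 3.84,
                       max_extensions: int = 3) -> ProfileResult:
    """Profile the objective along one free parameter.

    A log-spaced grid of ``n_grid`` points spanning ``span_decades`` on
    each side of the estimate is scanned; at each grid value the remaining
    free parameters are re-optimized (warm-started from the best fit).
    Whenever the profile fails to cross ``min + threshold`` before the end
    of the grid, the grid is extended by the same half-span until the
    crossing happens, a bound is reached, or ``max_extensions`` is spent.
    """
    if not best.converged:
        raise ValueError("profile requires a converged fit")
    if parameter not in spec.free:
        raise ValueError(f"{parameter!r} is not a free parameter")
    others = tuple(n for n in spec.free if n != parameter)
    sd = _effective_sd(data)
    lo_b, hi_b = spec.bounds_for(parameter)
    est = best.estimates[parameter]

    def profiled_objective(value: float) -> float:
        sub = CalibrationSpec(
            free=others,
            fixed={**dict(spec.fixed), parameter: value},
            bounds=dict(spec.bounds), T0=spec.T0, F0=dict(spec.F0))
        x0 = np.log10([best.estimates[n] for n in others])
        try:
            res = _local_fit(x0, data, sub, others, sd)
        except Exception:
            return FAILURE_PENALTY
        return float(2.0 * res.cost) if res.success else FAILURE_PENALTY

    half = max((n_grid - 1) // 2, 1)
    lo_grid = np.log10(max(est * 10.0**-span_decades, lo_b))
    hi_grid = np.log10(min(est * 10.0**span_decades, hi_b))
    values = list(np.logspace(lo_grid, hi_grid, n_grid))
    objs = [profiled_objective(v) for v in values]
    min_obj = min(min(objs), best.objective)
    level = min_obj + threshold

    def crossed(side: str) -> bool:
        seq = objs if side == "hi" else objs[::-1]
        vals = values if side == "hi" else values[::-1]
        for v, o in zip(vals, seq):
            on_side = v > est if side == "hi" else v < est
            if on_side and o > level:
                return True
        return False

    for side, bound, sign in (("lo", lo_b, -1), ("hi", hi_b, +1)):
        ext = 0
        while not crossed(side) and ext < max_extensions:
            edge = values[0] if side == "lo" else values[-1]
            if math.isclose(edge, bound, rel_tol=1e-9) or \
               (side == "lo" and edge <= bound) or (side == "hi" and edge >= bound):
                break
            new_edge = max(edge * 10.0**(sign * span_decades), bound) if sign < 0 \
                else min(edge * 10.0**(sign * span_decades), bound)
            extra = np.logspace(np.log10(min(edge, new_edge)),
                                np.log10(max(edge, new_edge)), half + 1)
            extra = [v for v in extra if not math.isclose(v, edge, rel_tol=1e-12)]
            extra_obj = [profiled_objective(v) for v in extra]
            if side == "lo":
                values = sorted(extra) + values
                objs = [o for _, o in sorted(zip(extra, extra_obj))] + objs
            else:
                values = values + sorted(extra)
                objs = objs + [o for _, o in sorted(zip(extra, extra_obj))]
            min_obj = min(min_obj, min(extra_obj))
            level = min_obj + threshold
            ext += 1

    lo_ok, hi_ok = crossed("lo"), crossed("hi")
    if lo_ok and hi_ok:
        verdict = "identifiable"
    elif hi_ok:
        verdict = "lower-open"
    elif lo_ok:
        verdict = "upper-open"
    else:
        verdict = "both-open"
    return ProfileResult(parameter=parameter, values=np.asarray(values),
                         objectives=np.asarray(objs), threshold=threshold,
                         verdict=verdict, estimate=est,
                         min_objective=float(min_obj))
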