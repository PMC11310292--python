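"""Treatment-scenario study: presets, treatment modes and outcome summaries.

Four presets describe hypothetical tumors with different estrogen
thresholds for death (``a2``) and for conversion to resistance (``a3``):

======== ===== ===== ========= ============ =============================
preset   a2    a3    k3        R0 fraction  interpretation
======== ===== ===== ========= ============ =============================
Ia       20    1     k1/2      0            adaptive resistance only
Ib       20    1     k1/2      0.25         preexisting (de novo) resistance
II       10    1     k1/2      0            narrow death window
III      10    10    k1/4      0            death and adaptation coincide
======== ===== ===== ========= ============ =============================

A run simulates the chosen diet untreated from the implanted 1 mm^3 tumor
until the composite burden ``S + eta*R`` reaches the detectable size
``1/(4*m1)`` (treatment start ``t_tr``), then applies one of three modes
on ``[t_tr, 25]``: constant dose (multiplier ``p``), alternating on/off
square wave, or the optimal schedule from the forward-backward sweep.
Outcomes are classified from the end-of-window composition of the tumor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .ocp import OCPProblem, OCPSolution, fbs_solve
from .params import ExtParams, ExtState, load_default_base, load_default_extended
from .simulate import ControlSchedule, Trajectory, detect_treatment_start, integrate

__all__ = [
    "ScenarioPreset",
    "OutcomeSummary",
    "Constant",
    "Alternating",
    "Optimal",
    "PRESETS",
    "preset",
    "initial_state",
    "run_scenario",
    "outcome_classify",
    "scenario_matrix",
]

T_FINAL = 25.0
#: constant-dose multipliers explored in the study (p = 1 is no treatment)
CONSTANT_P_SET = (1.0, 0.025, 0.0125, 0.01, 0.001)


@dataclass(frozen=True)
class ScenarioPreset:
    """Named threshold configuration of the extended model."""

    name: str
    a2: float
    a3: float
    k3: float
    R0_fraction: float
    t_f: float = T_FINAL

    def params(self, **overrides: float) -> ExtParams:
        base = load_default_extended()
        return base.replace(a2=self.a2, a3=self.a3, k3=self.k3, **overrides)


def _build_presets() -> dict[str, ScenarioPreset]:
    k1 = load_default_extended().k1
    return {
        "Ia": ScenarioPreset("Ia", a2=20.0, a3=1.0, k3=k1 / 2, R0_fraction=0.0),
        "Ib": ScenarioPreset("Ib", a2=20.0, a3=1.0, k3=k1 / 2, R0_fraction=0.25),
        "II": ScenarioPreset("II", a2=10.0, a3=1.0, k3=k1 / 2, R0_fraction=0.0),
        "III": ScenarioPreset("III", a2=10.0, a3=10.0, k3=k1 / 4, R0_fraction=0.0),
    }


PRESETS: dict[str, ScenarioPreset] = _build_presets()


def preset(name: str) -> ScenarioPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")


def initial_state(diet: str, scenario: ScenarioPreset) -> ExtState:
    """Per-diet initial state: the diet sets F0 and E0 only; the implanted
    1 mm^3 tumor is split S0/R0 by the preset's resistant fraction."""
    _, init = load_default_base()
    if diet not in init:
        raise ValueError(f"unknown diet {diet!r}")
    ic = init[diet]
    f = scenario.R0_fraction
    return ExtState(S=(1.0 - f) * ic["T0"], R=f * ic["T0"],
                    E=ic["E0"], F=ic["F0"])


# --------------------------------------------------------------------------
# treatment modes


@dataclass(frozen=True)
class Constant:
    """Constant dose: estrogen production scaled by ``p`` for the whole
    treatment window (``p = 1`` is no treatment)."""

    p: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.p <= 1.0:
            raise ValueError("p must satisfy 0 < p <= 1")

    def label(self) -> str:
        return f"constant(p={self.p:g})"


@dataclass(frozen=True)
class Alternating:
    """Square-wave schedule anchored at ``t_tr``: on at ``u_b`` for
    ``phase_on`` days, off for ``phase_off`` days, starting with on."""

    phase_on: float = 1.0
    phase_off: float = 1.0
    u_b: float = 0.99

    def label(self) -> str:
        return f"alternating({self.phase_on:g}on/{self.phase_off:g}off)"


@dataclass(frozen=True)
class Optimal:
    """Optimal schedule from the forward-backward sweep."""

    weights: tuple[float, float, float] = (1.0, 1.0, 1.0)
    grid_dt: float = 0.05
    bounds: tuple[float, float] = (0.0, 0.99)

    def label(self) -> str:
        w = ",".join(f"{x:g}" for x in self.weights)
        return f"optimal(w=({w}))"


Mode = Constant | Alternating | Optimal


@dataclass
class OutcomeSummary:
    """End-of-study summary of one scenario run.

    classification:
      * ``eradicated`` — final burden below ``eps_erad`` (default: the
        1 mm^3 implanted size)
      * ``resistant-regrowth`` — resistant cells dominate (> 50%) and the
        burden is rising at the end
      * ``contained`` — final burden no larger than at treatment start
      * ``uncontrolled`` — otherwise
    """

    final_volume: float
    resistant_fraction: float
    classification: str
    t_tr: float | None
    total_control: float


def outcome_classify(traj: Trajectory, t_tr: float | None = None,
                     eps_erad: float = 1.0,
                     rise_lookback: float = 2.0) -> OutcomeSummary:
    """Classify the end state of a (stitched) scenario trajectory.

    "Rising" is judged against the burden ``rise_lookback`` days before the
    end (long enough to bridge one on/off cycle of an alternating schedule,
    so a momentary dip inside an on-phase does not mask regrowth).
    """
    burden = traj.tumor_burden
    final = float(burden[-1])
    if "R" in traj.columns:
        resist = float(traj["R"][-1])
        frac = resist / final if final > 0 else 0.0
    else:
        frac = 0.0
    t_back = max(traj.times[-1] - rise_lookback, traj.times[0])
    rising = final > float(np.interp(t_back, traj.times, burden))
    t_tr = traj.t_tr if t_tr is None else t_tr
    total_u = float(np.trapezoid(traj.control, traj.times)) \
        if traj.control is not None else 0.0

    if final < eps_erad:
        label = "eradicated"
    elif frac > 0.5 and rising:
        label = "resistant-regrowth"
    elif t_tr is not None and final <= float(np.interp(t_tr, traj.times, burden)):
        label = "contained"
    else:
        label = "uncontrolled"
    return OutcomeSummary(final_volume=final, resistant_fraction=frac,
                          classification=label, t_tr=t_tr,
                          total_control=total_u)


def _stitch(pre: Trajectory, post: Trajectory) -> Trajectory:
    keep = pre.times < post.times[0] - 1e-12
    times = np.concatenate([pre.times[keep], post.times])
    states = np.vstack([pre.states[keep], post.states])
    ctrl_pre = pre.control if pre.control is not None \
        else np.zeros(pre.times.size)
    ctrl_post = post.control if post.control is not None \
        else np.zeros(post.times.size)
    control = np.concatenate([ctrl_pre[keep], ctrl_post])
    return Trajectory(times=times, states=states, columns=post.columns,
                      control=control)


def run_scenario(scenario: ScenarioPreset | str, diet: str, mode: Mode,
                 grid_dt: float = 0.05,
                 eps_erad: float = 1.0) -> tuple[Trajectory, OutcomeSummary]:
    """Simulate one (preset, diet, mode) cell of the study.

    The untreated extended model runs from day 0; once the burden reaches
    the detectable size, the mode is applied until day 25.  When the
    detection threshold is never reached, the untreated trajectory itself
    is classified (no treatment to apply).
    """
    if isinstance(scenario, str):
        scenario = preset(scenario)
    params = scenario.params()
    init = initial_state(diet, scenario)
    untreated = integrate("extended", params, init, (0.0, scenario.t_f),
                          grid_dt=grid_dt)
    t_tr = detect_treatment_start(untreated, params.eta, params.m1)
    no_treatment = isinstance(mode, Constant) and mode.p == 1.0
    if t_tr is None or no_treatment:
        traj = untreated
        traj.t_tr = t_tr
        return traj, outcome_classify(traj, t_tr, eps_erad)

    pre = integrate("extended", params, init, (0.0, t_tr), grid_dt=grid_dt)
    state_tr = pre.final_state()

    if isinstance(mode, Constant):
        schedule = ControlSchedule.constant(1.0 - mode.p, start=t_tr)
        post = integrate("extended", params, state_tr, (t_tr, scenario.t_f),
                         schedule=schedule, grid_dt=grid_dt)
    elif isinstance(mode, Alternating):
        schedule = ControlSchedule.alternating(mode.u_b, mode.phase_on,
                                               mode.phase_off, start=t_tr)
        post = integrate("extended", params, state_tr, (t_tr, scenario.t_f),
                         schedule=schedule, grid_dt=grid_dt)
    elif isinstance(mode, Optimal):
        problem = OCPProblem(params=params,
                             init=tuple(np.maximum(state_tr, 0.0)),
                             t0=t_tr, tf=scenario.t_f, weights=mode.weights,
                             bounds=mode.bounds, grid_dt=mode.grid_dt)
        sol = fbs_solve(problem)
        post = sol.trajectory()
    else:
        raise TypeError(f"unknown treatment mode {mode!r}")

    traj = _stitch(pre, post)
    traj.t_tr = t_tr
    return traj, outcome_classify(traj, t_tr, eps_erad)


def scenario_matrix(presets: Iterable[str | ScenarioPreset] = ("Ia", "Ib", "II", "III"),
                    diets: Sequence[str] = ("CD", "HFD"),
                    modes: Sequence[Mode] | None = None,
                    grid_dt: float = 0.05) -> pd.DataFrame:
    """Cross-product run; one tidy row per (preset, diet, mode) cell.

    Individual failures are recorded in the ``error`` column and the run
    continues.
    """
    if modes is None:
        modes = tuple(Constant(p) for p in CONSTANT_P_SET) + \
            (Alternating(), Optimal())
    rows = []
    for sc in presets:
        sc = preset(sc) if isinstance(sc, str) else sc
        for diet in diets:
            for mode in modes:
                row = {"scenario": sc.name, "diet": diet, "mode": mode.label()}
                try:
                    _, summary = run_scenario(sc, diet, mode, grid_dt=grid_dt)
                    row.update({
                        "classification": summary.classification,
                        "final_volume": summary.final_volume,
                        "resistant_fraction": summary.resistant_fraction,
                        "t_tr": summary.t_tr,
                        "total_control": summary.total_control,
                        "error": "",
                    })
                except Exception as exc:
                    row.update({"classification": "failed", "error": str(exc)})
                rows.append(row)
    return pd.DataFrame(rows)
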