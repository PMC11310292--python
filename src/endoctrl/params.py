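"""Parameter and state containers for the tumor-estrogen-fat models.

Two model families are supported:

* the *basic* model tracks tumor volume ``T`` (mm^3), local estrogen
  concentration ``E`` (pg/g) and fat volume ``F`` (mm^3) in the tumor
  micro-environment of an untreated mouse;
* the *extended* model splits the tumor into treatment-sensitive ``S`` and
  resistant ``R`` compartments (mm^3), lets fat grow logistically, and
  exposes the aromatase-inhibitor dose as a multiplicative reduction of
  fat-driven estrogen production.

Default parameter values for the calibrated mouse experiment (control diet,
CD, versus high-fat diet, HFD) are bundled as YAML files under
``endoctrl/data`` and accessible through :func:`load_default_base` and
:func:`load_default_extended`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "BaseParams",
    "BaseState",
    "ExtParams",
    "ExtState",
    "load_params",
    "save_params",
    "load_default_base",
    "load_default_extended",
    "default_initial_state",
]


@dataclass(frozen=True)
class BaseParams:
    """Rate constants of the untreated tumor-estrogen-fat model.

    Attributes
    ----------
    k1 : float
        Maximum tumor growth rate at saturating estrogen (1/day).
    a1 : float
        Estrogen concentration of half-maximum growth (pg/g).
    m1 : float
        Inverse tumor carrying capacity (1/mm^3).
    r : float
        Estrogen production rate per unit fat (pg/g per mm^3 per day).
    mu : float
        Estrogen washout rate (1/day).
    alpha : float
        Fat consumption rate per unit tumor (1/day per mm^3).
    """

    k1: float = 0.55
    a1: float = 43.0
    m1: float = 1.0 / 2000.0
    r: float = 20.0
    mu: float = 5.94
    alpha: float = 1.7e-6

    def __post_init__(self) -> None:
        for name in ("k1", "a1", "m1", "r", "mu", "alpha"):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name!r} must be non-negative")
        if self.m1 <= 0:
            raise ValueError("m1 must be positive (finite carrying capacity)")
        if self.mu <= 0:
            raise ValueError("mu must be positive (estrogen is washed out)")

    def replace(self, **changes: float) -> "BaseParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class BaseState:
    """State of the basic model: tumor T (mm^3), estrogen E (pg/g), fat F (mm^3)."""

    T: float
    E: float
    F: float

    def __post_init__(self) -> None:
        if self.T < 0 or self.E < 0 or self.F < 0:
            raise ValueError("state components must be non-negative")

    def as_array(self):
        import numpy as np

        return np.array([self.T, self.E, self.F], dtype=float)


@dataclass(frozen=True)
class ExtParams:
    """Rate constants of the sensitive/resistant treatment model.

    In addition to the :class:`BaseParams` fields:

    eta : competition intensity of resistant on sensitive cells (dimensionless)
    c : maximum estrogen-deprivation death rate (1/day)
    l : Hill coefficient of the low-estrogen switches (dimensionless, >= 1)
    a2 : estrogen threshold below which sensitive cells die (pg/g)
    a3 : estrogen threshold below which sensitive cells turn resistant (pg/g)
    k3 : resistant-cell growth rate (1/day)
    k2 : fat logistic growth rate (1/day)
    m2 : inverse fat carrying capacity (1/mm^3)
    p : constant treatment multiplier on estrogen production, 0 < p <= 1
        (p = 1 means no treatment; equivalent to control u = 1 - p)
    """

    k1: float = 0.55
    a1: float = 43.0
    m1: float = 1.0 / 2000.0
    r: float = 20.0
    mu: float = 5.94
    alpha: float = 1.7e-6
    eta: float = 1.0
    c: float = 1.0
    l: float = 10.0
    a2: float = 20.0
    a3: float = 1.0
    k3: float = 0.275
    k2: float = 0.05
    m2: float = 0.002711
    p: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "k1", "a1", "m1", "r", "mu", "alpha",
            "eta", "c", "l", "a2", "a3", "k3", "k2", "m2",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name!r} must be non-negative")
        if self.m1 <= 0 or self.mu <= 0:
            raise ValueError("m1 and mu must be positive")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("treatment multiplier p must satisfy 0 < p <= 1")
        if self.l < 1:
            raise ValueError("Hill coefficient l must be >= 1")

    def replace(self, **changes: float) -> "ExtParams":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def base(self) -> BaseParams:
        """Project onto the shared basic-model parameters."""
        return BaseParams(
            k1=self.k1, a1=self.a1, m1=self.m1,
            r=self.r, mu=self.mu, alpha=self.alpha,
        )


@dataclass(frozen=True)
class ExtState:
    """State of the extended model: sensitive S, resistant R (mm^3), E (pg/g), F (mm^3)."""

    S: float
    R: float
    E: float
    F: float

    def __post_init__(self) -> None:
        if min(self.S, self.R, self.E, self.F) < 0:
            raise ValueError("state components must be non-negative")

    def as_array(self):
        import numpy as np

        return np.array([self.S, self.R, self.E, self.F], dtype=float)


# ---------------------------------------------------------------------------
# serialization


def load_params(path: str | Path, kind: str = "auto") -> BaseParams | ExtParams:
    """Load parameters from a YAML or JSON mapping with field-named keys.

    ``kind`` is ``"base"``, ``"extended"`` or ``"auto"`` (extended iff any
    extended-only key is present).
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path} does not contain a parameter mapping")
    return params_from_dict(data, kind=kind)


def params_from_dict(data: Mapping[str, float], kind: str = "auto") -> BaseParams | ExtParams:
    extended_only = {"eta", "c", "l", "a2", "a3", "k3", "k2", "m2", "p"}
    if kind == "auto":
        kind = "extended" if extended_only & set(data) else "base"
    cls = ExtParams if kind == "extended" else BaseParams
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return cls(**{k: float(v) for k, v in data.items()})


def save_params(params: BaseParams | ExtParams, path: str | Path) -> None:
    path = Path(path)
    data = params.to_dict()
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def _bundled(name: str) -> dict:
    with resources.files("endoctrl").joinpath("data", name).open() as fh:
        return yaml.safe_load(fh)


def load_default_base() -> tuple[BaseParams, dict[str, dict[str, float]]]:
    """Bundled calibrated basic-model parameters and per-diet initial conditions.

    Returns ``(params, init)`` where ``init`` maps diet ("CD"/"HFD") to a dict
    with keys ``T0``, ``E0``, ``F0``.
    """
    data = _bundled("basic_model.yaml")
    params = params_from_dict(data["parameters"], kind="base")
    return params, data["initial_conditions"]


def load_default_extended(preset: str | None = None) -> ExtParams:
    """Bundled extended-model parameters; scenario-specific fields filled from
    the named preset (Ia, Ib, II, III) when given, else left at defaults."""
    data = _bundled("extended_model.yaml")
    common = dict(data["parameters"])
    if preset is not None:
        common.update(data["presets"][preset])
        common.pop("R0_fraction", None)
    return params_from_dict(common, kind="extended")  # type: ignore[return-value]


def default_initial_state(diet: str, kind: str = "base",
                          r0_fraction: float = 0.0) -> BaseState | ExtState:
    """Table of per-diet initial conditions.

    For the extended model the initial 1 mm^3 tumor is split into
    ``S0 = (1 - r0_fraction) * T0`` and ``R0 = r0_fraction * T0``.
    """
    _, init = load_default_base()
    if diet not in init:
        raise ValueError(f"unknown diet {diet!r}; expected one of {sorted(init)}")
    ic = init[diet]
    if kind == "base":
        return BaseState(T=ic["T0"], E=ic["E0"], F=ic["F0"])
    return ExtState(
        S=(1.0 - r0_fraction) * ic["T0"],
        R=r0_fraction * ic["T0"],
        E=ic["E0"],
        F=ic["F0"],
    )
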