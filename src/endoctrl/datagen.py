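"""Synthetic measurement sets emulating the two-diet mouse experiment.

The emulated design: two arms (CD and HFD) that differ only in their
initial fat volume and the estrogen level it sustains, tumor volume
measured in ``n_replicates`` independent tumors per arm at days 10, 13
and 15, and a single fat-volume measurement per arm at the final day.
Ground-truth trajectories come from the basic model; measurement noise is
configurable (additive or proportional Gaussian), with negative draws
truncated at zero.

Because every record stores the generating parameters and RNG seed, the
calibration and identifiability machinery can be exercised end-to-end with
a known answer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .params import BaseParams, BaseState
from .simulate import integrate, steady_state_estrogen

__all__ = ["NoiseModel", "MeasurementSet", "generate_experiment", "default_experiment"]

MEASUREMENT_COLUMNS = ("arm", "variable", "day", "replicate", "value", "sd")


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement-noise model.

    kind : {"additive_gaussian", "proportional_gaussian"}
    sigma_abs : standard deviation in measurement units (additive kind)
    sigma_rel : standard deviation as a fraction of the true value
        (proportional kind)
    """

    kind: str = "proportional_gaussian"
    sigma_abs: float = 0.0
    sigma_rel: float = 0.15

    def __post_init__(self) -> None:
        if self.kind not in {"additive_gaussian", "proportional_gaussian"}:
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.sigma_abs < 0 or self.sigma_rel < 0:
            raise ValueError("noise sigmas must be non-negative")

    def sd_for(self, true_value: np.ndarray | float) -> np.ndarray | float:
        if self.kind == "additive_gaussian":
            return np.full_like(np.asarray(true_value, float), self.sigma_abs) \
                if np.ndim(true_value) else self.sigma_abs
        return self.sigma_rel * np.asarray(true_value, float) \
            if np.ndim(true_value) else self.sigma_rel * float(true_value)

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(kind="additive_gaussian", sigma_abs=0.0, sigma_rel=0.0)


@dataclass
class MeasurementSet:
    """Arm-labelled replicate observations plus generating ground truth.

    ``records`` is a tidy frame with columns
    (arm, variable, day, replicate, value, sd).
    """

    records: pd.DataFrame
    truth: dict
    seed: int | None = None

    def __post_init__(self) -> None:
        missing = set(MEASUREMENT_COLUMNS) - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns {sorted(missing)}")
        if (self.records["value"] < 0).any():
            raise ValueError("measured values must be non-negative")
        fat = self.records[self.records["variable"] == "fat_volume"]
        for arm, grp in fat.groupby("arm"):
            if grp["day"].nunique() != 1:
                raise ValueError(f"arm {arm}: expected one fat-volume day")

    @property
    def arms(self) -> list[str]:
        return sorted(self.records["arm"].unique())

    def n_obs(self) -> int:
        return len(self.records)

    def write(self, csv_path: str | Path, sidecar: str | Path | None = None) -> None:
        """CSV of the records plus a JSON sidecar with truth and seed."""
        csv_path = Path(csv_path)
        self.records.to_csv(csv_path, index=False)
        sidecar = Path(sidecar) if sidecar else csv_path.with_suffix(".json")
        sidecar.write_text(json.dumps({"truth": self.truth, "seed": self.seed},
                                      indent=2) + "\n")

    @classmethod
    def read(cls, csv_path: str | Path,
             sidecar: str | Path | None = None) -> "MeasurementSet":
        csv_path = Path(csv_path)
        records = pd.read_csv(csv_path)
        truth, seed = {}, None
        sidecar = Path(sidecar) if sidecar else csv_path.with_suffix(".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            truth, seed = meta.get("truth", {}), meta.get("seed")
        return cls(records=records, truth=truth, seed=seed)


def generate_experiment(truth: BaseParams,
                        init_CD: BaseState,
                        init_HFD: BaseState,
                        days: Sequence[float] = (10.0, 13.0, 15.0),
                        n_replicates: int = 6,
                        noise: NoiseModel | None = None,
                        seed: int | None = None) -> MeasurementSet:
    """Simulate both diet arms and sample noisy measurements.

    Tumor volume is sampled per replicate at each of ``days``; fat volume
    once per arm at the final day.  Replicates are independent tumors, not
    repeated measures of one animal.  Fixed ``seed`` gives a reproducible
    data set.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    days = sorted(float(d) for d in days)
    if not days:
        raise ValueError("days must be non-empty")
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)

    rows = []
    inits = {"CD": init_CD, "HFD": init_HFD}
    for arm, init in inits.items():
        traj = integrate("basic", truth, init, (0.0, days[-1]), grid_dt=0.05)
        for day in days:
            true_T = float(np.interp(day, traj.times, traj["T"]))
            sd = float(noise.sd_for(true_T))
            draws = np.maximum(true_T + sd * rng.standard_normal(n_replicates), 0.0)
            for rep, val in enumerate(draws):
                rows.append((arm, "tumor_volume", day, rep, float(val), sd))
        true_F = float(traj["F"][-1])
        sd = float(noise.sd_for(true_F))
        val = max(true_F + sd * rng.standard_normal(), 0.0)
        rows.append((arm, "fat_volume", days[-1], 0, float(val), sd))

    records = pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)
    truth_dict = {
        "params": truth.to_dict(),
        "init": {arm: {"T0": s.T, "E0": s.E, "F0": s.F} for arm, s in inits.items()},
        "noise": {"kind": noise.kind, "sigma_abs": noise.sigma_abs,
                  "sigma_rel": noise.sigma_rel},
        "days": days,
        "n_replicates": n_replicates,
    }
    return MeasurementSet(records=records, truth=truth_dict, seed=seed)


def default_experiment(seed: int | None = None,
                       noise: NoiseModel | None = None,
                       n_replicates: int = 6) -> MeasurementSet:
    """The default emulated experiment: calibrated truth parameters, per-diet
    fat volumes 50/360 mm^3, and initial estrogen at its fat-sustained steady
    state ``r*F0/mu`` (the estrogen-to-fat ratio of about 3.4)."""
    truth = BaseParams()
    init = {}
    for arm, F0 in (("CD", 50.0), ("HFD", 360.0)):
        E0 = steady_state_estrogen(F0, truth.r, truth.mu)
        init[arm] = BaseState(T=1.0, E=E0, F=F0)
    return generate_experiment(truth, init["CD"], init["HFD"],
                               noise=noise, n_replicates=n_replicates, seed=seed)
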