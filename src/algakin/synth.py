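"""Synthetic hydrolysis experiments following the study design.

The source study reports its time courses only as figures, so every stage
of this pipeline is exercised against generated experiments instead: 500 mg
biomass in 100 mL buffer, samples every 10 min for 60 min, triplicate
measurements, and additive Gaussian noise on the yield-fraction scale
(truncated at 0, default sd 0.02 — the magnitude of the study's reported
standard errors).

The spectrophotometric calibration that turns an optical density into a
glucose concentration,

    X (g/L) = slope * OD + intercept,

is modelled by :class:`Calibration` (defaults slope 2.1086, intercept
0.0058, read at 540 nm), with exact forward/inverse round-tripping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fitting import GLUCOSE_ONLY, FULL_STATE, ObservationSet
from .simulate import SimulationConfig, Trajectory, integrate

__all__ = ["Calibration", "ExperimentDesign", "generate_experiment",
           "od_from_glucose", "glucose_from_od", "write_experiment"]


@dataclass(frozen=True)
class Calibration:
    """Linear glucose calibration of the spectrophotometric assay."""

    slope: float = 2.1086      # g/L per OD unit
    intercept: float = 0.0058  # g/L
    wavelength: str = "540 nm"

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError("calibration slope must be > 0")


def glucose_from_od(od, cal: Calibration = Calibration()) -> np.ndarray | float:
    """Forward calibration: glucose (g/L) from optical density."""
    return cal.slope * np.asarray(od, dtype=float) + cal.intercept


def od_from_glucose(x, cal: Calibration = Calibration()) -> np.ndarray | float:
    """Inverse calibration: OD = (X - intercept) / slope; X must be >= 0."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("glucose concentration must be >= 0")
    return (x - cal.intercept) / cal.slope


@dataclass(frozen=True)
class ExperimentDesign:
    """One synthetic experiment: a run config plus a measurement model."""

    config: SimulationConfig
    replicates: int = 3
    noise_sd: float = 0.02       # additive Gaussian on yield fraction
    seed: int | None = None
    mode: str = GLUCOSE_ONLY     # or FULL_STATE
    average_replicates: bool = False
    sampling_times: np.ndarray | None = None  # default: config.t_grid

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.mode not in (GLUCOSE_ONLY, FULL_STATE):
            raise ValueError(f"unknown observation mode {self.mode!r}")
        times = self.config.t_grid if self.sampling_times is None \
            else np.asarray(self.sampling_times, dtype=float)
        if times[-1] > self.config.t_grid[-1]:
            raise ValueError("sampling time beyond the integration span")
        object.__setattr__(self, "sampling_times", times)


def generate_experiment(design: ExperimentDesign) -> tuple[ObservationSet, Trajectory]:
    """Simulate the design and overlay measurement noise.

    Returns the noisy observations together with the ground-truth
    trajectory, so parameter-recovery tests can compare against the
    generating model. Bit-reproducible for a fixed seed.
    """
    from dataclasses import replace

    cfg = design.config
    times = design.sampling_times
    if not np.array_equal(times, cfg.t_grid):
        grid = np.unique(np.concatenate([[0.0], times]))
        cfg = replace(cfg, t_grid=grid)
    truth = integrate(cfg)
    tidx = {t: i for i, t in enumerate(cfg.t_grid)}
    rows = [tidx[t] for t in times]
    rng = np.random.default_rng(design.seed)

    records: list[dict] = []
    if design.mode == GLUCOSE_ONLY:
        clean = truth.yield_pct[rows] / 100.0
        for rep in range(1, design.replicates + 1):
            noisy = clean + rng.normal(0.0, design.noise_sd, size=len(clean))
            noisy = np.maximum(noisy, 0.0)
            for t, v in zip(times, noisy):
                records.append({"time_min": t, "replicate": rep,
                                "variable": "yield", "value": v})
    else:
        clean = truth.states[rows]
        for rep in range(1, design.replicates + 1):
            noisy = clean + rng.normal(0.0, design.noise_sd, size=clean.shape)
            noisy = np.maximum(noisy, 0.0)
            for i, t in enumerate(times):
                for j, sp in enumerate(truth.species):
                    records.append({"time_min": t, "replicate": rep,
                                    "variable": sp, "value": noisy[i, j]})
    df = pd.DataFrame.from_records(records)
    if design.average_replicates:
        df = (df.groupby(["time_min", "variable"], as_index=False)["value"]
                .mean())
        df["replicate"] = 1
        df = df[["time_min", "replicate", "variable", "value"]]
    obs = ObservationSet(data=df, mode=design.mode, scale="yield-fraction")
    return obs, truth


def write_experiment(design: ExperimentDesign, obs_path, truth_path) -> None:
    """Write observations plus a ground-truth sidecar (constants, seed)."""
    obs, truth = generate_experiment(design)
    obs.to_file(obs_path, extra_header={
        "model": design.config.model,
        "seed": design.seed,
        "noise_sd": design.noise_sd,
        "replicates": design.replicates,
    })
    k = design.config.rate_array()
    from .mechanisms import get_mechanism
    names = get_mechanism(design.config.model).constant_names
    with open(Path(truth_path), "w") as fh:
        fh.write(f"# model: {design.config.model}\n")
        fh.write(f"# seed: {design.seed}\n")
        fh.write(f"# noise_sd: {design.noise_sd}\n")
        fh.write(f"# replicates: {design.replicates}\n")
        fh.write("constant\tvalue_per_min\n")
        for name, val in zip(names, k):
            fh.write(f"{name}\t{val:.10g}\n")
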