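"""Integration of the hydrolysis mechanisms and conversion to yield curves.

A :class:`SimulationConfig` captures one in-silico run of the study design:
500 mg biomass in 100 mL buffer, a composition (percent dry weight), enzyme
doses in % w/w of biomass, a time grid in minutes, and the rate constants.
Species are integrated on the dimensionless scale (fractions of the
process's convertible substrate) with an adaptive Dormand–Prince
Runge–Kutta solver and read out through dense output on the experimental
sampling grid, so reported values do not depend on the grid spacing.

Two enzyme normalizations are available:

* ``mass-ratio`` — enzyme pool = dose mass / convertible substrate mass.
  Natural for the pretreatment stage, where doses (10–30% w/w) are of the
  same order as the substrate.
* ``unit-pool`` — enzyme pool = dose / reference dose, so the study's
  standard dose gives a pool of 1. Used for saccharification, where doses
  are quoted in units of catalytic activity rather than comparable mass
  (10^-4 % w/w) and the reported O(0.1–1)/min constants already absorb the
  loading.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .mechanisms import (
    PRETREATMENT,
    SACCHARIFICATION,
    conservation_residuals,
    get_mechanism,
)

__all__ = [
    "DEFAULT_COMPOSITION_PCT",
    "DEFAULT_DOSES_PCT",
    "SimulationConfig",
    "YieldDefinition",
    "Trajectory",
    "build_initial_state",
    "integrate",
    "integrate_pssa",
    "yield_curve",
    "glucose_concentration",
    "write_trajectory",
]

# Proximate composition of the Tetraselmis chuii biomass (percent dry weight).
DEFAULT_COMPOSITION_PCT = {
    "fat": 1.07,
    "protein": 19.57,
    "hemicellulose": 49.54,
    "cellulose": 10.2,
    "starch": 19.62,
}

# Study doses, % w/w of biomass.
DEFAULT_DOSES_PCT = {
    PRETREATMENT: {"cellulase": 30.0, "xylanase": 30.0},
    SACCHARIFICATION: {"alpha_amylase": 0.0006, "glucoamylase": 0.01},
}

# Doses at which a "unit-pool" enzyme normalization equals 1.
REFERENCE_DOSES_PCT = {
    PRETREATMENT: {"cellulase": 30.0, "xylanase": 30.0},
    SACCHARIFICATION: {"alpha_amylase": 0.0006, "glucoamylase": 0.01},
}

_SUBSTRATES = {
    PRETREATMENT: ("cellulose", "hemicellulose"),
    SACCHARIFICATION: ("starch",),
}

_ENZYMES = {
    PRETREATMENT: ("cellulase", "xylanase"),
    SACCHARIFICATION: ("alpha_amylase", "glucoamylase"),
}

_DEFAULT_SCALE = {PRETREATMENT: "mass-ratio", SACCHARIFICATION: "unit-pool"}


@dataclass(frozen=True)
class YieldDefinition:
    """How dimensionless glucose is reported as a percent yield.

    basis:
      * ``total-carbohydrate`` — percent of the process's convertible
        carbohydrate (the normalizing mass), the study's own scale;
      * ``per-substrate`` — percent of one named substrate's initial mass;
      * ``total-biomass`` — percent of total biomass loaded.
    factor is an optional mass-correction multiplier (e.g. a hydration
    factor), applied on top of the basis.
    """

    basis: str = "total-carbohydrate"
    factor: float = 1.0
    substrate: str | None = None

    def __post_init__(self) -> None:
        if self.basis not in ("total-carbohydrate", "per-substrate",
                              "total-biomass"):
            raise ValueError(f"unknown yield basis {self.basis!r}")
        if not self.factor > 0:
            raise ValueError("yield factor must be > 0")
        if self.basis == "per-substrate" and self.substrate is None:
            raise ValueError("per-substrate basis requires a substrate name")


@dataclass(frozen=True)
class SimulationConfig:
    """One simulated hydrolysis run (study design defaults)."""

    model: str
    rate_constants: object  # PretreatmentRateConstants | SaccharificationRateConstants | array
    biomass_mg: float = 500.0
    volume_ml: float = 100.0
    composition_pct: dict = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION_PCT))
    enzyme_doses_pct: dict | None = None
    enzyme_scale: str | None = None  # "mass-ratio" | "unit-pool"
    t_grid: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 61.0, 10.0))
    rtol: float = 1e-8
    atol: float = 1e-10
    yield_def: YieldDefinition = field(default_factory=YieldDefinition)

    def __post_init__(self) -> None:
        get_mechanism(self.model)  # validates the id
        object.__setattr__(self, "t_grid",
                           np.asarray(self.t_grid, dtype=float))
        t = self.t_grid
        if t.ndim != 1 or len(t) < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("time grid must be strictly increasing and "
                             "start at 0")
        if not (self.rtol > 0 and self.atol > 0):
            raise ValueError("solver tolerances must be > 0")
        if not (self.biomass_mg > 0 and self.volume_ml > 0):
            raise ValueError("biomass and volume must be > 0")
        for name, pct in self.composition_pct.items():
            if not 0 <= pct <= 100:
                raise ValueError(
                    f"composition percentage {name}={pct} outside [0, 100]")
        if self.enzyme_doses_pct is None:
            object.__setattr__(self, "enzyme_doses_pct",
                               dict(DEFAULT_DOSES_PCT[self.model]))
        for enz in _ENZYMES[self.model]:
            if enz not in self.enzyme_doses_pct:
                raise ValueError(f"missing enzyme dose for {enz!r}")
            if self.enzyme_doses_pct[enz] < 0:
                raise ValueError(f"enzyme dose for {enz!r} must be >= 0")
        if self.enzyme_scale is None:
            object.__setattr__(self, "enzyme_scale",
                               _DEFAULT_SCALE[self.model])
        if self.enzyme_scale not in ("mass-ratio", "unit-pool"):
            raise ValueError(f"unknown enzyme scale {self.enzyme_scale!r}")
        for sub in _SUBSTRATES[self.model]:
            if sub not in self.composition_pct:
                raise ValueError(f"composition is missing substrate {sub!r}")

    @property
    def substrate_pct(self) -> float:
        """Convertible substrate, percent of biomass."""
        return sum(self.composition_pct[s] for s in _SUBSTRATES[self.model])

    @property
    def substrate_mass_mg(self) -> float:
        """Convertible substrate mass — the normalizing mass of the run."""
        return self.substrate_pct / 100.0 * self.biomass_mg

    def rate_array(self) -> np.ndarray:
        k = self.rate_constants
        return k.as_array() if hasattr(k, "as_array") \
            else np.asarray(k, dtype=float)

    def with_constants(self, k) -> "SimulationConfig":
        return replace(self, rate_constants=k)


@dataclass(frozen=True)
class Trajectory:
    """Integrated time course plus derived observables."""

    model: str
    time_min: np.ndarray          # (n,)
    states: np.ndarray            # (n, n_species), dimensionless
    species: tuple[str, ...]
    glucose_g_per_l: np.ndarray   # (n,)
    yield_pct: np.ndarray         # (n,)
    config: SimulationConfig

    @property
    def initial_state(self) -> np.ndarray:
        return self.states[0]

    def glucose_fraction(self) -> np.ndarray:
        """Dimensionless product (glucose) series."""
        return self.states[:, self.species.index(_product_name(self.model))]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(self.species))
        df.insert(0, "time_min", self.time_min)
        df["glucose_g_per_L"] = self.glucose_g_per_l
        df["yield_pct"] = self.yield_pct
        return df


def _product_name(model: str) -> str:
    return "P" if model == PRETREATMENT else "G"


def build_initial_state(config: SimulationConfig) -> np.ndarray:
    """Initial dimensionless state from the run configuration.

    Substrates sum to 1 on the normalizing scale; complexes and product
    start at 0; enzyme pools follow the configured normalization.
    """
    mech = get_mechanism(config.model)
    y0 = np.zeros(len(mech.species))
    if config.model == PRETREATMENT:
        total = config.substrate_pct
        y0[mech.index("S_cel")] = config.composition_pct["cellulose"] / total
        y0[mech.index("S_hem")] = config.composition_pct["hemicellulose"] / total
        enz_state = {"cellulase": "E_cel", "xylanase": "E_xyl"}
    else:
        y0[mech.index("S")] = 1.0
        enz_state = {"alpha_amylase": "E_a", "glucoamylase": "E_g"}
    for enz, sp in enz_state.items():
        dose = config.enzyme_doses_pct[enz]
        if config.enzyme_scale == "mass-ratio":
            pool = dose / config.substrate_pct
        else:
            pool = dose / REFERENCE_DOSES_PCT[config.model][enz]
        y0[mech.index(sp)] = pool
    return y0


def _fast_rhs(model: str, k: np.ndarray):
    """Closure RHS with constants unpacked once (hot path of the solver).

    Semantically identical to the public per-model RHS functions, which
    remain the validated API surface (and are tested against both this
    closure and the generic mass-action oracle).
    """
    if model == PRETREATMENT:
        k1, k2, k3, k4, k5, k6, k7, k8 = (float(v) for v in k)

        def f(t, y):
            S_cel, S_hem, E_cel, E_xyl, ES_cel, ES_hem, P = y
            dES_cel = k1 * E_cel * S_cel - (k2 + k3) * ES_cel + k4 * E_cel * P
            dES_hem = k5 * E_xyl * S_hem - (k6 + k7) * ES_hem + k8 * E_xyl * P
            return (-k1 * E_cel * S_cel + k2 * ES_cel,
                    -k5 * E_xyl * S_hem + k6 * ES_hem,
                    -dES_cel, -dES_hem, dES_cel, dES_hem,
                    k3 * ES_cel - k4 * E_cel * P
                    + k7 * ES_hem - k8 * E_xyl * P)
        return f

    k9, k10, k11, k12, k13, k14, k15, k16 = (float(v) for v in k)

    def g(t, y):
        S, E_a, ES1, D, E_g, ES2, G = y
        dES1 = k9 * E_a * S - (k10 + k11) * ES1 + k12 * E_a * D
        dES2 = k13 * E_g * D - (k14 + k15) * ES2 + k16 * E_g * G
        return (-k9 * E_a * S + k10 * ES1, -dES1, dES1,
                k11 * ES1 - k12 * E_a * D - k13 * E_g * D + k14 * ES2,
                -dES2, dES2, k15 * ES2 - k16 * E_g * G)
    return g


def _solve(config: SimulationConfig, rhs, y0) -> np.ndarray:
    sol = solve_ivp(rhs, (config.t_grid[0], config.t_grid[-1]), y0,
                    method="RK45", dense_output=True,
                    rtol=config.rtol, atol=config.atol)
    if not sol.success:
        raise RuntimeError(
            f"ODE integration failed at t = {sol.t[-1]:.4g} min "
            f"(last valid state {sol.y[:, -1]}): {sol.message}")
    return sol.sol(config.t_grid).T


def integrate(config: SimulationConfig) -> Trajectory:
    """Integrate the full mechanism on the configured time grid."""
    y0 = build_initial_state(config)
    states = _solve(config, _fast_rhs(config.model, config.rate_array()), y0)
    states[0] = y0  # dense output is exact at t0; pin it bitwise
    return _finish(config, states)


def _finish(config: SimulationConfig, states: np.ndarray) -> Trajectory:
    mech = get_mechanism(config.model)
    traj = Trajectory(
        model=config.model, time_min=config.t_grid.copy(), states=states,
        species=mech.species,
        glucose_g_per_l=np.zeros(len(config.t_grid)),
        yield_pct=np.zeros(len(config.t_grid)),
        config=config)
    g = glucose_concentration(traj, config)
    y = yield_curve(traj, config.yield_def)
    object.__setattr__(traj, "glucose_g_per_l", g)
    object.__setattr__(traj, "yield_pct", y)
    return traj


# ---------------------------------------------------------------------------
# Pseudo-steady-state (reduced) integration
# ---------------------------------------------------------------------------

def _pssa_rhs_pretreat(y, k, Ec_tot, Ex_tot):
    k1, k2, k3, k4, k5, k6, k7, k8 = k
    S_cel, S_hem, P = y
    q1 = (k1 * S_cel + k4 * P) / (k2 + k3)
    ES_cel = Ec_tot * q1 / (1.0 + q1)
    E_cel = Ec_tot - ES_cel
    q2 = (k5 * S_hem + k8 * P) / (k6 + k7)
    ES_hem = Ex_tot * q2 / (1.0 + q2)
    E_xyl = Ex_tot - ES_hem
    dS_cel = -k1 * E_cel * S_cel + k2 * ES_cel
    dS_hem = -k5 * E_xyl * S_hem + k6 * ES_hem
    dP = k3 * ES_cel - k4 * E_cel * P + k7 * ES_hem - k8 * E_xyl * P
    return np.array([dS_cel, dS_hem, dP])


def _pssa_rhs_sacc(y, k, Ea_tot, Eg_tot):
    k9, k10, k11, k12, k13, k14, k15, k16 = k
    S, D, G = y
    q1 = (k9 * S + k12 * D) / (k10 + k11)
    ES1 = Ea_tot * q1 / (1.0 + q1)
    E_a = Ea_tot - ES1
    q2 = (k13 * D + k16 * G) / (k14 + k15)
    ES2 = Eg_tot * q2 / (1.0 + q2)
    E_g = Eg_tot - ES2
    dS = -k9 * E_a * S + k10 * ES1
    dD = k11 * ES1 - k12 * E_a * D - k13 * E_g * D + k14 * ES2
    dG = k15 * ES2 - k16 * E_g * G
    return np.array([dS, dD, dG])


def integrate_pssa(config: SimulationConfig) -> Trajectory:
    """Integrate the quasi-steady-state reduction of the mechanism.

    Complexes are algebraic functions of the slow species (enzyme balance
    closed through total-enzyme conservation); the returned trajectory
    reconstructs the full species layout from the reduced states. Valid
    when the enzyme pool is small relative to substrate and binding/
    unbinding is fast relative to product formation.
    """
    k = config.rate_array()
    for pair, lo in ((k[1] + k[2], "unbinding+catalytic (first enzyme)"),
                     (k[5] + k[6], "unbinding+catalytic (second enzyme)")):
        if pair <= 0:
            raise ZeroDivisionError(
                f"PSSA reduction degenerate: {lo} constants sum to 0")
    mech = get_mechanism(config.model)
    y0_full = build_initial_state(config)
    if config.model == PRETREATMENT:
        Ec = y0_full[mech.index("E_cel")] + y0_full[mech.index("ES_cel")]
        Ex = y0_full[mech.index("E_xyl")] + y0_full[mech.index("ES_hem")]
        rhs = lambda t, y: _pssa_rhs_pretreat(y, k, Ec, Ex)
        slow = ("S_cel", "S_hem", "P")
    else:
        Ea = y0_full[mech.index("E_a")] + y0_full[mech.index("ES1")]
        Eg = y0_full[mech.index("E_g")] + y0_full[mech.index("ES2")]
        rhs = lambda t, y: _pssa_rhs_sacc(y, k, Ea, Eg)
        slow = ("S", "D", "G")
    y0_red = np.array([y0_full[mech.index(s)] for s in slow])
    red = _solve(config, rhs, y0_red)

    states = np.zeros((len(config.t_grid), len(mech.species)))
    for j, s in enumerate(slow):
        states[:, mech.index(s)] = red[:, j]
    kvec = k
    if config.model == PRETREATMENT:
        q1 = (kvec[0] * red[:, 0] + kvec[3] * red[:, 2]) / (kvec[1] + kvec[2])
        es1 = Ec * q1 / (1 + q1)
        q2 = (kvec[4] * red[:, 1] + kvec[7] * red[:, 2]) / (kvec[5] + kvec[6])
        es2 = Ex * q2 / (1 + q2)
        states[:, mech.index("ES_cel")] = es1
        states[:, mech.index("E_cel")] = Ec - es1
        states[:, mech.index("ES_hem")] = es2
        states[:, mech.index("E_xyl")] = Ex - es2
    else:
        q1 = (kvec[0] * red[:, 0] + kvec[3] * red[:, 1]) / (kvec[1] + kvec[2])
        es1 = Ea * q1 / (1 + q1)
        q2 = (kvec[4] * red[:, 1] + kvec[7] * red[:, 2]) / (kvec[5] + kvec[6])
        es2 = Eg * q2 / (1 + q2)
        states[:, mech.index("ES1")] = es1
        states[:, mech.index("E_a")] = Ea - es1
        states[:, mech.index("ES2")] = es2
        states[:, mech.index("E_g")] = Eg - es2
    return _finish(config, states)


# ---------------------------------------------------------------------------
# Derived observables
# ---------------------------------------------------------------------------

def yield_curve(traj: Trajectory, ydef: YieldDefinition) -> np.ndarray:
    """Glucose yield (%) series: 100 * factor * P(t) / basis denominator.

    On the ``total-carbohydrate`` basis with factor 1 the denominator is
    the normalizing mass itself, so yield(t) = 100 * P(t).
    """
    cfg = traj.config
    if ydef.basis == "total-carbohydrate":
        denom = 1.0
    elif ydef.basis == "per-substrate":
        if ydef.substrate not in cfg.composition_pct:
            raise ValueError(f"unknown substrate {ydef.substrate!r}")
        denom = cfg.composition_pct[ydef.substrate] / cfg.substrate_pct
    else:  # total-biomass
        denom = cfg.biomass_mg / cfg.substrate_mass_mg
    if denom == 0:
        raise ZeroDivisionError("yield denominator is zero")
    return 100.0 * ydef.factor * traj.glucose_fraction() / denom


def glucose_concentration(traj: Trajectory, config: SimulationConfig) -> np.ndarray:
    """Glucose in g/L: undoes the normalization by the convertible mass."""
    mass_g = config.substrate_mass_mg / 1000.0
    vol_l = config.volume_ml / 1000.0
    return traj.glucose_fraction() * mass_g / vol_l


def write_trajectory(traj: Trajectory, path, header_lines: tuple[str, ...] = ()) -> None:
    """Write a trajectory as tab-delimited text with a mandatory header row."""
    path = Path(path)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        traj.to_frame().to_csv(fh, sep="\t", index=False)
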