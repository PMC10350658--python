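"""Reaction mechanisms for the two-stage enzymatic hydrolysis of microalgal biomass.

Two mechanisms are defined, both built from reversible single-substrate
enzyme steps of the form

    E + S  <=>  ES  <=>  E + P

so that each enzymatic conversion carries four rate constants: forward
binding, unbinding, catalytic release of product, and re-binding of product
into the complex.

* **Pretreatment** — cellulase attacks cellulose and xylanase attacks
  hemicellulose; both release glucose into one shared product pool
  (constants ``k1``–``k8``).
* **Saccharification** — alpha-amylase liquefies starch to dextrin, and
  glucoamylase hydrolyses dextrin to glucose, giving a two-step cascade
  with two distinct enzyme–substrate complexes (constants ``k9``–``k16``).

All species are dimensionless fractions of the initial convertible
substrate of the process, which is what makes every rate constant —
including the bimolecular ones — carry units of 1/min.

The module exposes both hand-coded right-hand sides (:func:`pretreat_rhs`,
:func:`sacc_rhs`) and a generic mass-action evaluator over an explicit
edge list (:class:`MechanismSpec`, :func:`mass_action_rhs`); the latter is
the independent oracle the hand-coded forms are tested against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import yaml

__all__ = [
    "PRETREATMENT",
    "SACCHARIFICATION",
    "PretreatmentRateConstants",
    "SaccharificationRateConstants",
    "PretreatmentState",
    "SaccharificationState",
    "MechanismSpec",
    "Reaction",
    "get_mechanism",
    "mass_action_rhs",
    "pretreat_rhs",
    "sacc_rhs",
    "pssa_complex",
    "conservation_residuals",
]

PRETREATMENT = "pretreatment"
SACCHARIFICATION = "saccharification"


# ---------------------------------------------------------------------------
# Rate constants
# ---------------------------------------------------------------------------

def _validate_constants(obj) -> None:
    for f in dc_fields(obj):
        v = getattr(obj, f.name)
        if not math.isfinite(v):
            raise ValueError(f"rate constant {f.name} is not finite: {v!r}")
        if v < 0:
            raise ValueError(f"rate constant {f.name} must be >= 0, got {v}")


@dataclass(frozen=True)
class PretreatmentRateConstants:
    """Rate constants (1/min) of the cellulase + xylanase mechanism.

    k1/k2: cellulase–cellulose binding/unbinding; k3: complex -> glucose +
    free cellulase; k4: glucose re-binding into the complex; k5–k8 the same
    four roles for xylanase/hemicellulose.
    """

    k1: float
    k2: float
    k3: float
    k4: float
    k5: float
    k6: float
    k7: float
    k8: float

    def __post_init__(self) -> None:
        _validate_constants(self)

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.k4,
                         self.k5, self.k6, self.k7, self.k8], dtype=float)

    @classmethod
    def from_array(cls, k) -> "PretreatmentRateConstants":
        return cls(*np.asarray(k, dtype=float))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in dc_fields(self))


@dataclass(frozen=True)
class SaccharificationRateConstants:
    """Rate constants (1/min) of the alpha-amylase + glucoamylase cascade.

    k9/k10: amylase–starch binding/unbinding (ES1); k11/k12: ES1 -> dextrin
    and its reverse; k13/k14: glucoamylase–dextrin binding/unbinding (ES2);
    k15/k16: ES2 -> glucose and its reverse.
    """

    k9: float
    k10: float
    k11: float
    k12: float
    k13: float
    k14: float
    k15: float
    k16: float

    def __post_init__(self) -> None:
        _validate_constants(self)

    def as_array(self) -> np.ndarray:
        return np.array([self.k9, self.k10, self.k11, self.k12,
                         self.k13, self.k14, self.k15, self.k16], dtype=float)

    @classmethod
    def from_array(cls, k) -> "SaccharificationRateConstants":
        return cls(*np.asarray(k, dtype=float))

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(f.name for f in dc_fields(self))


# ---------------------------------------------------------------------------
# States
# ---------------------------------------------------------------------------

def _validate_state(obj) -> None:
    for f in dc_fields(obj):
        v = getattr(obj, f.name)
        if math.isnan(v):
            raise ValueError(f"state component {f.name} is NaN")


@dataclass(frozen=True)
class PretreatmentState:
    """Dimensionless species of the pretreatment mechanism.

    Fractions of the total initial convertible substrate
    (cellulose + hemicellulose mass).
    """

    S_cel: float  # cellulose
    S_hem: float  # hemicellulose
    E_cel: float  # free cellulase
    E_xyl: float  # free xylanase
    ES_cel: float  # cellulase-cellulose complex
    ES_hem: float  # xylanase-hemicellulose complex
    P: float      # glucose (shared pool)

    def __post_init__(self) -> None:
        _validate_state(self)

    def as_array(self) -> np.ndarray:
        return np.array([self.S_cel, self.S_hem, self.E_cel, self.E_xyl,
                         self.ES_cel, self.ES_hem, self.P], dtype=float)

    @classmethod
    def from_array(cls, y) -> "PretreatmentState":
        return cls(*np.asarray(y, dtype=float))


@dataclass(frozen=True)
class SaccharificationState:
    """Dimensionless species of the saccharification cascade (starch basis)."""

    S: float    # starch
    E_a: float  # free alpha-amylase
    ES1: float  # amylase-starch complex
    D: float    # dextrin
    E_g: float  # free glucoamylase
    ES2: float  # glucoamylase-dextrin complex
    G: float    # glucose

    def __post_init__(self) -> None:
        _validate_state(self)

    def as_array(self) -> np.ndarray:
        return np.array([self.S, self.E_a, self.ES1, self.D,
                         self.E_g, self.ES2, self.G], dtype=float)

    @classmethod
    def from_array(cls, y) -> "SaccharificationState":
        return cls(*np.asarray(y, dtype=float))


# ---------------------------------------------------------------------------
# Mechanism as data: species + mass-action edge list
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action step: rate = k * prod(reactant concs)."""

    constant: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]


@dataclass(frozen=True)
class MechanismSpec:
    """Auditable description of a mechanism: species, edges, conservation laws.

    ``conserved`` maps a law name to the species whose concentrations sum
    to a constant along any trajectory.  Every edge must leave every law's
    sum unchanged (checked in :meth:`validate`).
    """

    name: str
    species: tuple[str, ...]
    reactions: tuple[Reaction, ...]
    conserved: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for r in self.reactions:
            if r.constant in seen:
                raise ValueError(f"rate constant {r.constant} appears on more "
                                 "than one edge")
            seen.add(r.constant)
            for sp in (*r.reactants, *r.products):
                if sp not in self.species:
                    raise ValueError(f"unknown species {sp} in edge {r.constant}")
        for law, members in self.conserved.items():
            for r in self.reactions:
                net = sum(r.products.count(sp) for sp in members) \
                    - sum(r.reactants.count(sp) for sp in members)
                if net != 0:
                    raise ValueError(
                        f"edge {r.constant} violates conservation law {law}")

    @property
    def constant_names(self) -> tuple[str, ...]:
        return tuple(r.constant for r in self.reactions)

    def index(self, sp: str) -> int:
        return self.species.index(sp)

    # -- plain-text round trip ------------------------------------------------
    def to_yaml(self) -> str:
        doc = {
            "mechanism": self.name,
            "species": list(self.species),
            "reactions": [
                {"constant": r.constant,
                 "reactants": list(r.reactants),
                 "products": list(r.products)}
                for r in self.reactions
            ],
            "conserved": {k: list(v) for k, v in self.conserved.items()},
        }
        return yaml.safe_dump(doc, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "MechanismSpec":
        doc = yaml.safe_load(text)
        return cls(
            name=doc["mechanism"],
            species=tuple(doc["species"]),
            reactions=tuple(
                Reaction(r["constant"], tuple(r["reactants"]),
                         tuple(r["products"]))
                for r in doc["reactions"]
            ),
            conserved={k: tuple(v) for k, v in doc.get("conserved", {}).items()},
        )


def _reversible_step(k_fwd, k_rev, k_cat, k_bind_p, enzyme, substrate,
                     complex_, product) -> tuple[Reaction, ...]:
    return (
        Reaction(k_fwd, (enzyme, substrate), (complex_,)),
        Reaction(k_rev, (complex_,), (enzyme, substrate)),
        Reaction(k_cat, (complex_,), (enzyme, product)),
        Reaction(k_bind_p, (enzyme, product), (complex_,)),
    )


PRETREATMENT_MECHANISM = MechanismSpec(
    name=PRETREATMENT,
    species=("S_cel", "S_hem", "E_cel", "E_xyl", "ES_cel", "ES_hem", "P"),
    reactions=(
        *_reversible_step("k1", "k2", "k3", "k4",
                          "E_cel", "S_cel", "ES_cel", "P"),
        *_reversible_step("k5", "k6", "k7", "k8",
                          "E_xyl", "S_hem", "ES_hem", "P"),
    ),
    conserved={
        "cellulase": ("E_cel", "ES_cel"),
        "xylanase": ("E_xyl", "ES_hem"),
        "substrate_carbon": ("S_cel", "S_hem", "ES_cel", "ES_hem", "P"),
    },
)

SACCHARIFICATION_MECHANISM = MechanismSpec(
    name=SACCHARIFICATION,
    species=("S", "E_a", "ES1", "D", "E_g", "ES2", "G"),
    reactions=(
        *_reversible_step("k9", "k10", "k11", "k12", "E_a", "S", "ES1", "D"),
        *_reversible_step("k13", "k14", "k15", "k16", "E_g", "D", "ES2", "G"),
    ),
    conserved={
        "alpha_amylase": ("E_a", "ES1"),
        "glucoamylase": ("E_g", "ES2"),
        "substrate_carbon": ("S", "ES1", "D", "ES2", "G"),
    },
)

_MECHANISMS = {
    PRETREATMENT: PRETREATMENT_MECHANISM,
    SACCHARIFICATION: SACCHARIFICATION_MECHANISM,
}


def get_mechanism(model: str) -> MechanismSpec:
    try:
        return _MECHANISMS[model]
    except KeyError:
        raise ValueError(
            f"unknown model {model!r}; expected one of {sorted(_MECHANISMS)}"
        ) from None


def mass_action_rhs(mech: MechanismSpec, k: dict[str, float] | np.ndarray,
                    y: np.ndarray) -> np.ndarray:
    """Generic mass-action derivative over the edge list.

    ``k`` is either a mapping constant-name -> value or an array ordered as
    ``mech.constant_names``.  This is the reference oracle for the
    hand-coded right-hand sides.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(k, dict):
        kvec = [k[name] for name in mech.constant_names]
    else:
        kvec = np.asarray(k, dtype=float)
    dy = np.zeros_like(y)
    for rate_k, r in zip(kvec, mech.reactions):
        rate = rate_k
        for sp in r.reactants:
            rate *= y[mech.index(sp)]
        for sp in r.reactants:
            dy[mech.index(sp)] -= rate
        for sp in r.products:
            dy[mech.index(sp)] += rate
    return dy


# ---------------------------------------------------------------------------
# Hand-coded right-hand sides (fast path used by the integrator)
# ---------------------------------------------------------------------------

def _check_state(y, species) -> None:
    y = np.asarray(y, dtype=float)
    bad = np.isnan(y)
    if bad.any():
        names = [species[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"NaN state component(s): {', '.join(names)}")


def pretreat_rhs(state, k) -> np.ndarray:
    """Time derivative of the pretreatment state (units 1/min).

    Accepts a :class:`PretreatmentState` or a plain array in the species
    order ``(S_cel, S_hem, E_cel, E_xyl, ES_cel, ES_hem, P)``.
    """
    if isinstance(state, PretreatmentState):
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
    _check_state(y, PRETREATMENT_MECHANISM.species)
    if isinstance(k, PretreatmentRateConstants):
        k1, k2, k3, k4, k5, k6, k7, k8 = k.as_array()
    else:
        k1, k2, k3, k4, k5, k6, k7, k8 = np.asarray(k, dtype=float)
    S_cel, S_hem, E_cel, E_xyl, ES_cel, ES_hem, P = y
    dES_cel = k1 * E_cel * S_cel - (k2 + k3) * ES_cel + k4 * E_cel * P
    dES_hem = k5 * E_xyl * S_hem - (k6 + k7) * ES_hem + k8 * E_xyl * P
    dS_cel = -k1 * E_cel * S_cel + k2 * ES_cel
    dS_hem = -k5 * E_xyl * S_hem + k6 * ES_hem
    dP = k3 * ES_cel - k4 * E_cel * P + k7 * ES_hem - k8 * E_xyl * P
    return np.array([dS_cel, dS_hem, -dES_cel, -dES_hem,
                     dES_cel, dES_hem, dP])


def sacc_rhs(state, k) -> np.ndarray:
    """Time derivative of the saccharification state (units 1/min).

    Species order ``(S, E_a, ES1, D, E_g, ES2, G)``.
    """
    if isinstance(state, SaccharificationState):
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
    _check_state(y, SACCHARIFICATION_MECHANISM.species)
    if isinstance(k, SaccharificationRateConstants):
        k9, k10, k11, k12, k13, k14, k15, k16 = k.as_array()
    else:
        k9, k10, k11, k12, k13, k14, k15, k16 = np.asarray(k, dtype=float)
    S, E_a, ES1, D, E_g, ES2, G = y
    dES1 = k9 * E_a * S - (k10 + k11) * ES1 + k12 * E_a * D
    dES2 = k13 * E_g * D - (k14 + k15) * ES2 + k16 * E_g * G
    dS = -k9 * E_a * S + k10 * ES1
    dD = k11 * ES1 - k12 * E_a * D - k13 * E_g * D + k14 * ES2
    dG = k15 * ES2 - k16 * E_g * G
    return np.array([dS, -dES1, dES1, dD, -dES2, dES2, dG])


def rhs_for(model: str):
    """Return the hand-coded RHS callable for a model id."""
    if model == PRETREATMENT:
        return pretreat_rhs
    if model == SACCHARIFICATION:
        return sacc_rhs
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# Pseudo-steady-state reduction
# ---------------------------------------------------------------------------

def pssa_complex(state, k, model: str) -> dict[str, float]:
    """Quasi-steady complex concentration(s) given free enzyme and substrates.

    Setting d(ES)/dt = 0 in the reversible step E + S <=> ES <=> E + P gives

        ES = E_free * (k_bind * S + k_bind_p * P) / (k_unbind + k_cat)

    Returns a mapping complex-name -> concentration; the denominator pair
    must be positive for every complex of the model.
    """
    mech = get_mechanism(model)
    if isinstance(state, (PretreatmentState, SaccharificationState)):
        y = state.as_array()
    else:
        y = np.asarray(state, dtype=float)
    if hasattr(k, "as_array"):
        kv = dict(zip(k.names, k.as_array()))
    else:
        kv = dict(zip(mech.constant_names, np.asarray(k, dtype=float)))

    if model == PRETREATMENT:
        steps = [("ES_cel", "E_cel", "S_cel", "P", "k1", "k2", "k3", "k4"),
                 ("ES_hem", "E_xyl", "S_hem", "P", "k5", "k6", "k7", "k8")]
    else:
        steps = [("ES1", "E_a", "S", "D", "k9", "k10", "k11", "k12"),
                 ("ES2", "E_g", "D", "G", "k13", "k14", "k15", "k16")]

    out: dict[str, float] = {}
    for cname, ename, sname, pname, kb, ku, kc, kp in steps:
        denom = kv[ku] + kv[kc]
        if denom <= 0:
            raise ZeroDivisionError(
                f"pseudo-steady-state reduction for {cname} is degenerate: "
                f"{ku} + {kc} = 0")
        E = y[mech.index(ename)]
        S = y[mech.index(sname)]
        P = y[mech.index(pname)]
        out[cname] = E * (kv[kb] * S + kv[kp] * P) / denom
    return out


# ---------------------------------------------------------------------------
# Conservation laws
# ---------------------------------------------------------------------------

def conservation_residuals(point, initial_state, model: str) -> dict[str, float]:
    """Signed drift of each conservation law relative to the initial state.

    For a law L with member species M, returns sum_M point - sum_M initial.
    An exactly integrated trajectory has all residuals 0.
    """
    mech = get_mechanism(model)
    y = point.as_array() if hasattr(point, "as_array") \
        else np.asarray(point, dtype=float)
    y0 = initial_state.as_array() if hasattr(initial_state, "as_array") \
        else np.asarray(initial_state, dtype=float)
    if y.shape != y0.shape or y.shape != (len(mech.species),):
        raise ValueError(
            f"state shape {y.shape} does not match the {model} species "
            f"layout ({len(mech.species)},)")
    return {
        law: float(sum(y[mech.index(sp)] for sp in members)
                   - sum(y0[mech.index(sp)] for sp in members))
        for law, members in mech.conserved.items()
    }
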