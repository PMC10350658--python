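"""Arrhenius analysis of temperature-dependent rate constants.

Fits ln k = ln A - Ea / (R T) by ordinary least squares on (1/T, ln k)
with T in kelvin, returning the activation energy Ea (kJ/mol), the
pre-exponential factor A (1/min) and the regression R^2.

Enzymes denature above their optimum: the fitted constants then *fall*
with temperature and no longer follow an Arrhenius law.
:func:`select_non_denatured` picks the pre-denaturation regime as the
longest run of strictly increasing k starting from the lowest
temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["GAS_CONSTANT", "ArrheniusInput", "ArrheniusFit",
           "fit_arrhenius", "select_non_denatured"]

GAS_CONSTANT = 8.314  # J / (mol K)


@dataclass(frozen=True)
class ArrheniusInput:
    """(temperature degC, rate constant 1/min) pairs, sorted by temperature."""

    temperatures_c: np.ndarray
    rate_constants: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures_c, dtype=float)
        k = np.asarray(self.rate_constants, dtype=float)
        if t.shape != k.shape or t.ndim != 1:
            raise ValueError("temperatures and constants must be matching "
                             "1-d arrays")
        if len(t) < 2:
            raise ValueError("need at least 2 temperature points")
        if len(np.unique(t)) != len(t):
            raise ValueError("duplicate temperatures")
        if np.any(k <= 0):
            raise ValueError("rate constants must be > 0 for an Arrhenius fit")
        order = np.argsort(t)
        object.__setattr__(self, "temperatures_c", t[order])
        object.__setattr__(self, "rate_constants", k[order])

    def subset(self, idx) -> "ArrheniusInput":
        idx = np.asarray(idx, dtype=int)
        return ArrheniusInput(self.temperatures_c[idx],
                              self.rate_constants[idx])


@dataclass(frozen=True)
class ArrheniusFit:
    ea_kj_mol: float
    a_per_min: float
    r_squared: float
    subset_indices: tuple[int, ...]
    temperatures_c: tuple[float, ...]


def fit_arrhenius(inp: ArrheniusInput,
                  subset: str | list | np.ndarray = "all") -> ArrheniusFit:
    """OLS of ln k on 1/T(K); exact through 2 points by construction.

    ``subset`` is "all", "auto" (pre-denaturation regime via
    :func:`select_non_denatured`), or explicit indices into the sorted
    input.
    """
    if isinstance(subset, str):
        if subset == "all":
            idx = np.arange(len(inp.temperatures_c))
        elif subset == "auto":
            idx = select_non_denatured(inp)
        else:
            raise ValueError(f"unknown subset selector {subset!r}")
    else:
        idx = np.asarray(subset, dtype=int)
        if len(idx) < 2:
            raise ValueError("subset must contain at least 2 points")
    use = inp.subset(idx)
    inv_t = 1.0 / (use.temperatures_c + 273.15)
    ln_k = np.log(use.rate_constants)
    res = stats.linregress(inv_t, ln_k)
    ea = -res.slope * GAS_CONSTANT / 1000.0  # kJ/mol
    return ArrheniusFit(
        ea_kj_mol=float(ea),
        a_per_min=float(np.exp(res.intercept)),
        r_squared=float(res.rvalue ** 2),
        subset_indices=tuple(int(i) for i in idx),
        temperatures_c=tuple(float(t) for t in use.temperatures_c),
    )


def select_non_denatured(inp: ArrheniusInput) -> np.ndarray:
    """Indices of the longest strictly-increasing prefix of k over T.

    This is the pre-denaturation regime: from the lowest temperature
    upward, keep points while k keeps rising. At least one rising step is
    required; a monotonically non-increasing series has no Arrhenius
    regime.
    """
    k = inp.rate_constants
    n = 1
    while n < len(k) and k[n] > k[n - 1]:
        n += 1
    if n < 2:
        raise ValueError("no pre-denaturation regime: rate constants never "
                         "increase with temperature")
    return np.arange(n)
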